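"""Deterministic synthetic genomes, annotations and training data.

Real targets for this tool are repetitive, A/T-rich, often polyploid crop
genomes; the generators emulate the features that matter to the pipeline —
a tunable GC fraction (A/T-rich regimes like 0.30), exact duplicated
segments standing in for homeologous gene copies, and a sparse gene
annotation — without attempting realistic repeat families or empirical
base composition.  Everything is a pure function of its spec: the same
seed gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from guideforge.scoring import TrainingSet, encode_matrix, flat_length
from guideforge.sequence_io import GenomeSequence, write_fasta


class FixtureSpecError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Recipe for a synthetic genome.

    duplication pastes an exact copy of a source interval at the end of the
    same chromosome `copy_count` times, emulating paleopolyploid gene copies;
    every guide falling inside source or copies must come out multi_hit.
    """

    seed: int = 0
    chrom_lengths: list[int] = field(default_factory=lambda: [20_000])
    gc_fraction: float = 0.30
    duplication: Optional[tuple[int, int, int]] = None  # (start, end, copy_count) on chrom 1
    gene_density: float = 2.0  # features per 10 kb


def make_genome(
    spec: FixtureSpec, fasta_path: Optional[str] = None
) -> tuple[dict[str, GenomeSequence], dict[str, list[tuple[int, int]]]]:
    """Random genome at the requested GC, with optional exact duplications.

    Returns (genome, truth) where truth maps chrom_id to the list of
    intervals (0-based half-open) whose guides must be tagged multi_hit.
    Writes FASTA when a path is given.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array(
        [(1 - spec.gc_fraction) / 2, spec.gc_fraction / 2, spec.gc_fraction / 2, (1 - spec.gc_fraction) / 2]
    )
    genome: dict[str, GenomeSequence] = {}
    truth: dict[str, list[tuple[int, int]]] = {}
    for i, length in enumerate(spec.chrom_lengths, start=1):
        chrom_id = f"chr{i}"
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
        if i == 1 and spec.duplication is not None:
            d_start, d_end, copies = spec.duplication
            if not (0 <= d_start < d_end <= length):
                raise FixtureSpecError(f"duplication interval [{d_start},{d_end}) outside chromosome")
            segment = seq[d_start:d_end]
            intervals = [(d_start, d_end)]
            for _ in range(copies):
                intervals.append((len(seq), len(seq) + len(segment)))
                seq = seq + segment
            truth[chrom_id] = intervals
        else:
            truth[chrom_id] = []
        genome[chrom_id] = GenomeSequence(chrom_id, seq)
    if fasta_path:
        write_fasta(genome, fasta_path)
    return genome, truth


def make_gff(
    spec: FixtureSpec,
    genome: dict[str, GenomeSequence],
    gff_path: str,
    with_sidecar: bool = False,
) -> list[tuple[str, int, int, str]]:
    """Non-overlapping gene features with planted Note annotations.

    Genes are placed on a regular grid at spec.gene_density per 10 kb, each
    spanning 60% of its grid cell.  When with_sidecar is set, a Phytozome
    style '<gff stem>.annotation_info.txt' is written next to the GFF with
    one extra annotation per gene.  Returns the planted (chrom, start, end,
    note) truth list (1-based inclusive coordinates, as written).
    """
    import os

    planted: list[tuple[str, int, int, str]] = []
    lines = ["##gff-version 3"]
    gene_no = 0
    for chrom in genome.values():
        n_genes = int(chrom.length / 10_000 * spec.gene_density)
        if n_genes == 0:
            continue
        cell = chrom.length // n_genes
        for j in range(n_genes):
            gene_no += 1
            start = j * cell + max(1, cell // 5)        # 1-based
            end = min(start + int(cell * 0.6), chrom.length)
            note = f"synthetic gene {gene_no} product"
            gid = f"g{gene_no}"
            lines.append(
                f"{chrom.chrom_id}\tguideforge\tgene\t{start}\t{end}\t.\t+\t.\tID={gid};Note={note}"
            )
            planted.append((chrom.chrom_id, start, end, note))
    with open(gff_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if with_sidecar:
        base, _ = os.path.splitext(gff_path)
        with open(base + ".annotation_info.txt", "w") as fh:
            fh.write("pacId\ttranscriptName\tGO\tdescription\n")
            for k, (_c, _s, _e, _n) in enumerate(planted, start=1):
                fh.write(f"{1000 + k}\tg{k}\tGO:{k:07d}\tsidecar function {k}\n")
    return planted


def make_training_set(
    n: int = 2000, seed: int = 0, noise_sigma: float = 0.05, n_groups: int = 20, context_length: int = 30
) -> tuple[TrainingSet, np.ndarray]:
    """Synthetic guide-efficacy ranks with known generating weights.

    Contexts are uniform random; the rank is a sigmoid of a sparse linear
    score on the one-hot features plus Gaussian noise, clipped to [0,1].
    The weight scale keeps the sigmoid argument moderate so ranks spread
    over most of [0,1] without saturating.  Returns (TrainingSet, weights).

    The one-hot encoding is redundant (first-order columns are marginal
    sums of second-order columns), so weights are identifiable only up to
    the encoding's null space; compare fitted and generating weights inside
    the identifiable subspace via scoring.feature_rowspace.
    """
    if n < n_groups:
        raise FixtureSpecError("need at least one row per group")
    rng = np.random.default_rng(seed)
    contexts = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, size=context_length)]) for _ in range(n)]
    d = flat_length(context_length)
    w = rng.normal(0.0, 0.18, size=d)
    mask = rng.random(d) < 0.3  # sparse signal: most positions uninformative
    w = w * mask
    X = encode_matrix(contexts)
    score = X @ w
    rank = 1.0 / (1.0 + np.exp(-score))
    if noise_sigma > 0:
        rank = rank + rng.normal(0.0, noise_sigma, size=n)
    rank = np.clip(rank, 0.0, 1.0)
    gene_ids = [f"gene{(i % n_groups) + 1}" for i in range(n)]
    return TrainingSet(contexts, gene_ids, rank), w
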