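"""PCR validation-primer design with nearest-neighbor thermodynamics.

For each guide a pair of Tm-matched primers is designed so the cut site
can be amplified and Sanger-verified.  Duplex stability is the
nearest-neighbor sum

    dG37(pred) = dG37(init) + sum_i n_i * dG37(i)          [kJ/mol]

over the ten canonical dinucleotide stacks plus one terminal-initiation
term per end (A/T terminus +4.31, C/G terminus +4.05).  A two-state
melting model turns the dissociation free energy into the matching
surrogate

    Tm = dG_dissociation / (R * T * ln 2),   R = 8.314 J/mol/K, T = 310.15 K.

As printed this expression is dimensionally a pure number scaled by the
fixed reference temperature, not an absolute melting temperature; it is
strictly monotone in duplex stability, which is all the pair-matching
step needs.  Candidate pairs are ranked by Tm agreement, then closeness
to the target amplicon length.  Pairs whose productive placement exists
at more than one genomic locus are tagged as homeologous (duplicated
regions in polyploids) and untagged pairs are preferred when available.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

from guideforge.design import GuideRecord
from guideforge.sequence_io import GenomeSequence
from guideforge.systems import revcomp

R_GAS = 8.314          # J / (mol K)
T_REF = 310.15         # K, the 37 degC reference of dG37
LN2 = math.log(2.0)

# Nearest-neighbor dG37 (kJ/mol) for the ten canonical stacks, keyed by the
# top-strand dinucleotide; the six missing dinucleotides are looked up via
# their reverse complement (same duplex read from the other strand).
STACK_DG = {
    "AA": -4.26,
    "AT": -3.67,
    "AC": -6.09,
    "AG": -5.40,
    "TA": -2.50,
    "TC": -5.51,
    "TG": -6.12,
    "CG": -9.07,
    "GC": -9.36,
    "CC": -7.66,
}
INIT_AT = 4.31
INIT_CG = 4.05


class PrimerUsageError(ValueError):
    pass


@dataclass(frozen=True)
class NNTable:
    stack_dg: dict[str, float] = field(default_factory=lambda: dict(STACK_DG))
    init_at: float = INIT_AT
    init_cg: float = INIT_CG


DEFAULT_NN = NNTable()


def nn_delta_g(sequence: str, table: NNTable = DEFAULT_NN) -> float:
    """Predicted duplex formation dG37 in kJ/mol (nearest-neighbor sum)."""
    if len(sequence) < 2:
        raise PrimerUsageError("nearest-neighbor sum needs at least 2 bases")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise PrimerUsageError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    total = 0.0
    for i in range(len(sequence) - 1):
        stack = sequence[i : i + 2]
        total += table.stack_dg.get(stack) if stack in table.stack_dg else table.stack_dg[revcomp(stack)]
    for terminus in (sequence[0], sequence[-1]):
        total += table.init_at if terminus in "AT" else table.init_cg
    return round(total, 10)


def melting_temperature(dg_formation: float) -> float:
    """Two-state melting surrogate from the formation dG37 (kJ/mol).

    Dissociation is the reverse of formation, so the sign flips; kJ are
    converted to J to match R.  Strictly decreasing in dg_formation.
    """
    return (-dg_formation * 1000.0) / (R_GAS * T_REF * LN2)


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    strand: str
    genomic_start: int  # 0-based forward-strand start of the primer's footprint
    dg_formation: float
    tm: float

    @property
    def genomic_end(self) -> int:
        return self.genomic_start + len(self.sequence)


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_start: Optional[int]
    amplicon_end: Optional[int]
    amplicon_length: int
    tm_delta: float
    homeolog_tag: bool = False


@dataclass(frozen=True)
class PrimerConfig:
    """Primer pattern and pairing thresholds.

    min_arm keeps both primers clear of the cut site so the amplicon reads
    through it; the amplicon window and target suit Sanger validation.
    """

    min_length: int = 18
    max_length: int = 24
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 4
    min_arm: int = 50
    min_amplicon: int = 150
    max_amplicon: int = 900
    target_amplicon: int = 400
    max_tm_delta: float = 3.0
    max_pool: int = 100


_HOMOPOLYMER = re.compile(r"(A{5,}|C{5,}|G{5,}|T{5,})")


def primer_pattern_ok(seq: str, cfg: PrimerConfig) -> bool:
    """The concrete primer filter: length, GC window, 3' G/C clamp, and no
    homopolymer run longer than cfg.max_homopolymer."""
    if not (cfg.min_length <= len(seq) <= cfg.max_length):
        return False
    if "N" in seq:
        return False
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if not (cfg.gc_min <= gc <= cfg.gc_max):
        return False
    if seq[-1] not in "GC":
        return False
    run_limit = cfg.max_homopolymer + 1
    for base in "ACGT":
        if base * run_limit in seq:
            return False
    return True


def _candidate(seq: str, strand: str, start: int, table: NNTable) -> PrimerCandidate:
    dg = nn_delta_g(seq, table)
    return PrimerCandidate(seq, strand, start, dg, melting_temperature(dg))


class TemplateCandidates:
    """Per-template cache of every pattern-valid primer window.

    Window validity does not depend on the cut position, so in genome-wide
    runs each chromosome is swept once and every guide's pools are served by
    bisection from the cached lists (forward candidates sorted by window end,
    reverse candidates sorted by window start).
    """

    def __init__(self, template: GenomeSequence, cfg: PrimerConfig, table: NNTable = DEFAULT_NN):
        self.template = template
        self.cfg = cfg
        s = template.sequence
        fwd: list[PrimerCandidate] = []
        rev: list[PrimerCandidate] = []
        for a in range(0, template.length - cfg.min_length + 1):
            for length in range(cfg.min_length, cfg.max_length + 1):
                b = a + length
                if b > template.length:
                    break
                window = s[a:b]
                if primer_pattern_ok(window, cfg):
                    fwd.append(_candidate(window, "+", a, table))
                rc = revcomp(window)
                if primer_pattern_ok(rc, cfg):
                    rev.append(_candidate(rc, "-", a, table))
        fwd.sort(key=lambda c: (c.genomic_end, c.genomic_start))
        rev.sort(key=lambda c: (c.genomic_start, c.genomic_end))
        self._fwd = fwd
        self._rev = rev
        self._fwd_ends = [c.genomic_end for c in fwd]
        self._rev_starts = [c.genomic_start for c in rev]

    def pools(self, cutsite: int) -> tuple[list[PrimerCandidate], list[PrimerCandidate]]:
        import bisect

        cfg = self.cfg
        lo = max(0, cutsite - cfg.max_amplicon)
        hi = min(self.template.length, cutsite + cfg.max_amplicon)
        # forward: end-1 at least min_arm 5' of the cut, footprint within range
        b_hi = bisect.bisect_right(self._fwd_ends, cutsite - cfg.min_arm + 1)
        fwd = [c for c in self._fwd[:b_hi] if c.genomic_start >= lo]
        # reverse: start at least min_arm 3' of the cut
        a_lo = bisect.bisect_left(self._rev_starts, cutsite + cfg.min_arm)
        rev = [c for c in self._rev[a_lo:] if c.genomic_end <= hi]
        fwd.sort(key=lambda c: (cutsite - c.genomic_end, c.genomic_start, c.sequence))
        rev.sort(key=lambda c: (c.genomic_start - cutsite, c.genomic_start, c.sequence))
        return fwd[: cfg.max_pool], rev[: cfg.max_pool]


def generate_pools(
    template: GenomeSequence,
    cutsite: int,
    cfg: PrimerConfig = PrimerConfig(),
    table: NNTable = DEFAULT_NN,
    cache: Optional[TemplateCandidates] = None,
) -> tuple[list[PrimerCandidate], list[PrimerCandidate]]:
    """Forward and reverse candidate pools flanking a cut position.

    Forward candidates are plus-strand windows ending at least min_arm bases
    5' of the cut; reverse candidates are minus-strand windows (sequences
    reverse-complemented) starting at least min_arm bases 3' of it; all
    candidates keep their footprint within max_amplicon of the cut.  Pools
    are capped at cfg.max_pool per side, keeping the candidates closest to
    the cut (deterministic ordering).  Logs a warning when a pool is empty.
    """
    if not (0 <= cutsite < template.length):
        raise PrimerUsageError(f"cutsite {cutsite} outside template {template.chrom_id}")
    if cache is None:
        cache = TemplateCandidates(template, cfg, table)
    fwd, rev = cache.pools(cutsite)
    if not fwd or not rev:
        import logging

        logging.getLogger(__name__).warning(
            "empty %s primer pool at %s:%d",
            "forward" if not fwd else "reverse",
            template.chrom_id,
            cutsite,
        )
    return fwd, rev


def match_pairs(
    fwd_pool: list[PrimerCandidate],
    rev_pool: list[PrimerCandidate],
    cutsite: int,
    cfg: PrimerConfig = PrimerConfig(),
) -> list[PrimerPair]:
    """All admissible cross pairs, ranked deterministically.

    Admissible: Tm difference within cfg.max_tm_delta, amplicon length in
    [min_amplicon, max_amplicon], cut site strictly inside the amplicon.
    Ranked by (tm_delta, |length - target|, amplicon_start, sequences).
    """
    pairs: list[PrimerPair] = []
    for f in fwd_pool:
        for r in rev_pool:
            start, end = f.genomic_start, r.genomic_end
            length = end - start
            if not (cfg.min_amplicon <= length <= cfg.max_amplicon):
                continue
            if not (start < cutsite < end - 1):
                continue
            delta = abs(f.tm - r.tm)
            if delta > cfg.max_tm_delta:
                continue
            pairs.append(PrimerPair(f, r, start, end, length, delta))
    pairs.sort(
        key=lambda p: (
            p.tm_delta,
            abs(p.amplicon_length - cfg.target_amplicon),
            p.amplicon_start,
            p.forward.sequence,
            p.reverse.sequence,
        )
    )
    return pairs


def _productive_placements(
    genome: dict[str, GenomeSequence], fwd_seq: str, rev_seq: str, max_span: int
) -> set[tuple[str, int, str]]:
    """All loci where the pair would amplify: forward primer followed by the
    reverse primer's reverse complement within max_span, on either strand."""
    placements: set[tuple[str, int, str]] = set()
    rev_rc = revcomp(rev_seq)
    fwd_rc = revcomp(fwd_seq)
    for chrom in genome.values():
        s = chrom.sequence
        # orientation 1: F ... revcomp(R) on the forward strand
        f_hits = [m.start() for m in re.finditer(f"(?={re.escape(fwd_seq)})", s)]
        r_hits = [m.start() for m in re.finditer(f"(?={re.escape(rev_rc)})", s)]
        for fp in f_hits:
            for rp in r_hits:
                end = rp + len(rev_rc)
                if fp < rp and end - fp <= max_span:
                    placements.add((chrom.chrom_id, fp, "+"))
        # orientation 2: the same amplicon on the other strand
        # (R ... revcomp(F) read forward)
        f2 = [m.start() for m in re.finditer(f"(?={re.escape(rev_seq)})", s)]
        r2 = [m.start() for m in re.finditer(f"(?={re.escape(fwd_rc)})", s)]
        for fp in f2:
            for rp in r2:
                end = rp + len(fwd_rc)
                if fp < rp and end - fp <= max_span:
                    placements.add((chrom.chrom_id, fp, "-"))
    return placements


def tag_homeologs(
    pair: PrimerPair, genome: dict[str, GenomeSequence], cfg: PrimerConfig = PrimerConfig()
) -> PrimerPair:
    """Tag the pair when its productive placement exists at >= 2 distinct loci.

    Distinctness is by forward-strand span start; the pair's own locus counts
    once, and a placement found on the opposite strand at the same start is
    the same physical amplicon.
    """
    placements = _productive_placements(genome, pair.forward.sequence, pair.reverse.sequence, cfg.max_amplicon)
    loci = {(c, p) for (c, p, _s) in placements}
    pair.homeolog_tag = len(loci) >= 2
    return pair


def design_for_guide(
    guide: GuideRecord,
    genome: dict[str, GenomeSequence],
    cfg: PrimerConfig = PrimerConfig(),
    table: NNTable = DEFAULT_NN,
    tag_limit: int = 10,
    cache: Optional[TemplateCandidates] = None,
) -> GuideRecord:
    """Attach the best admissible primer pair to a guide.

    Pairs are walked in rank order; each is checked for homeologous
    placements and the first untagged pair wins.  If every checked pair is
    tagged (duplicated region), the top-ranked tagged pair is attached —
    amplifying all copies is still informative.  tag_limit bounds how many
    pairs are genome-scanned.  A guide with no admissible pair keeps
    primer_pair = None.
    """
    template = genome[guide.chrom_id]
    fwd, rev = generate_pools(template, guide.cutsite, cfg, table, cache=cache)
    pairs = match_pairs(fwd, rev, guide.cutsite, cfg)
    if not pairs:
        guide.primer_pair = None
        return guide
    first_tagged: Optional[PrimerPair] = None
    for pair in pairs[:tag_limit]:
        pair = tag_homeologs(pair, genome, cfg)
        if not pair.homeolog_tag:
            guide.primer_pair = pair
            return guide
        if first_tagged is None:
            first_tagged = pair
    guide.primer_pair = first_tagged
    return guide


def design_primers(
    guides: list[GuideRecord],
    genome: dict[str, GenomeSequence],
    cfg: PrimerConfig = PrimerConfig(),
    table: NNTable = DEFAULT_NN,
    tag_limit: int = 10,
) -> list[GuideRecord]:
    """Attach primer pairs to a batch of guides, sweeping each chromosome's
    candidate windows only once."""
    caches: dict[str, TemplateCandidates] = {}
    for g in guides:
        if g.chrom_id not in caches:
            caches[g.chrom_id] = TemplateCandidates(genome[g.chrom_id], cfg, table)
        design_for_guide(g, genome, cfg, table, tag_limit, cache=caches[g.chrom_id])
    return guides


def standalone_design(
    fasta_path: str,
    out_csv: str,
    positions: Optional[dict[str, list[int]]] = None,
    cfg: PrimerConfig = PrimerConfig(),
) -> int:
    """Design primer pairs for arbitrary FASTA records and write a CSV.

    Targets default to each record's midpoint; a {chrom: [positions]} map
    overrides.  Homeolog tagging runs against the whole input FASTA, so a
    duplicated record is detected.  Returns the number of rows written.
    """
    import csv

    from guideforge.sequence_io import read_fasta

    genome = read_fasta(fasta_path)
    rows = []
    for chrom_id, chrom in genome.items():
        targets = (positions or {}).get(chrom_id, [chrom.length // 2])
        for pos in targets:
            fwd, rev = generate_pools(chrom, pos, cfg)
            pairs = match_pairs(fwd, rev, pos, cfg)
            best = None
            for pair in pairs[:25]:
                pair = tag_homeologs(pair, genome, cfg)
                if not pair.homeolog_tag:
                    best = pair
                    break
                if best is None:
                    best = pair
            if best is None:
                rows.append([chrom_id, pos] + [""] * 8 + ["no_pair"])
            else:
                rows.append(
                    [
                        chrom_id,
                        pos,
                        best.forward.sequence,
                        best.reverse.sequence,
                        f"{best.forward.tm:.4f}",
                        f"{best.reverse.tm:.4f}",
                        f"{best.tm_delta:.4f}",
                        best.amplicon_start,
                        best.amplicon_end,
                        best.amplicon_length,
                        str(best.homeolog_tag).lower(),
                    ]
                )
    header = [
        "template_id",
        "target_pos",
        "fwd_seq",
        "rev_seq",
        "fwd_tm",
        "rev_tm",
        "tm_delta",
        "amplicon_start",
        "amplicon_end",
        "amplicon_length",
        "homeolog_tag",
    ]
    with open(out_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)
    return len(rows)
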