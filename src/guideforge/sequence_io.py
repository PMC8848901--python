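"""Input parsing: FASTA genomes, GFF3 annotation, and Phytozome annotation sidecars.

This module does faithful parsing and alphabet normalization only; no
biology happens here.  Sequences are normalized to uppercase {A,C,G,T,N}
(U becomes T, every other IUPAC ambiguity code becomes N) so that all
downstream scanning and encoding operates on a closed alphabet.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

_NORMALIZE = str.maketrans(
    {c: ("T" if c in "Uu" else c.upper() if c.upper() in "ACGTN" else "N")
     for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"}
)

# attribute keys probed, in priority order, for an initial functional annotation
_ANNOTATION_KEYS = ("Note", "description", "product", "Name")


class FastaFormatError(ValueError):
    pass


class GffFormatError(ValueError):
    pass


def normalize_sequence(seq: str) -> str:
    """Map a raw nucleotide string onto the {A,C,G,T,N} alphabet."""
    return seq.translate(_NORMALIZE)


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome (or scaffold): an id and a normalized sequence."""

    chrom_id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-normalized characters in {self.chrom_id}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """One GFF3 line: coordinates are 1-based inclusive, as in the file."""

    chrom_id: str
    source: str
    feature_type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)
    functional_annotation: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path: str | os.PathLike) -> dict[str, GenomeSequence]:
    """Read a (possibly line-wrapped) multi-record FASTA into a chrom dict.

    The chrom_id is the header token before the first whitespace.  Raises
    :class:`FastaFormatError` on a missing leading header or a duplicate id.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FastaFormatError(f"{path}: does not begin with a '>' FASTA header")
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        genome[rec.id] = GenomeSequence(rec.id, normalize_sequence(str(rec.seq)))
    return genome


def write_fasta(genome: dict[str, GenomeSequence], path: str | os.PathLike, width: int = 60) -> None:
    """Write the genome dict back out as wrapped FASTA."""
    with open(path, "w") as fh:
        for chrom in genome.values():
            fh.write(f">{chrom.chrom_id}\n")
            for i in range(0, chrom.length, width):
                fh.write(chrom.sequence[i : i + width] + "\n")


def _parse_attributes(column9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in column9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _initial_annotation(attrs: dict[str, str]) -> str:
    for key in _ANNOTATION_KEYS:
        if attrs.get(key):
            return attrs[key]
    return ""


def read_gff(path: str | os.PathLike) -> list[FeatureRecord]:
    """Parse a 9-column GFF3 file into FeatureRecords, preserving line order.

    Comment lines ('#') are skipped.  Rows with fewer than 9 tab-separated
    fields or non-integer coordinates raise :class:`GffFormatError` with the
    offending line number.
    """
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GffFormatError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, source, ftype, start_s, end_s, score, strand, phase = fields[:8]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffFormatError(f"{path}:{lineno}: non-integer start/end") from exc
            attrs = _parse_attributes(fields[8])
            records.append(
                FeatureRecord(
                    chrom_id=chrom,
                    source=source,
                    feature_type=ftype,
                    start=start,
                    end=end,
                    score=score,
                    strand=strand,
                    phase=phase,
                    attributes=attrs,
                    functional_annotation=_initial_annotation(attrs),
                )
            )
    return records


def sidecar_path(gff_path: str | os.PathLike) -> str:
    """Derive the Phytozome sidecar path: the GFF extension is replaced
    with ``.annotation_info.txt`` in the same directory."""
    base, _ = os.path.splitext(str(gff_path))
    return base + ".annotation_info.txt"


def _read_sidecar(path: str) -> dict[str, str]:
    """Parse the sidecar TSV into {join key -> appended annotation text}.

    The join column is the one whose header contains 'transcriptName'
    (case-insensitive); the second column is the fallback.  All remaining
    columns are concatenated with '; '.
    """
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if len(header) < 2:
            raise GffFormatError(f"{path}: sidecar has no parseable tab-separated header")
        key_idx = 1
        for i, name in enumerate(header):
            if "transcriptname" in name.lower():
                key_idx = i
                break
        mapping: dict[str, str] = {}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= key_idx:
                continue
            key = fields[key_idx]
            extras = [f for i, f in enumerate(fields) if i != key_idx and f]
            if key and extras:
                mapping[key] = "; ".join(extras)
    return mapping


def merge_phytozome_annotation(gff_path: str | os.PathLike, records: list[FeatureRecord]) -> list[FeatureRecord]:
    """Append sidecar annotation columns to records whose name matches a row.

    A record joins on any of its ID / Name / transcript-like attribute values.
    When the sidecar file does not exist the records are returned unchanged
    (with a logged warning).  The merge is idempotent: text already appended
    is not appended twice.
    """
    path = sidecar_path(gff_path)
    if not os.path.exists(path):
        logger.warning("annotation sidecar not found at %s; records left unchanged", path)
        return records
    mapping = _read_sidecar(path)
    out: list[FeatureRecord] = []
    for rec in records:
        keys = [rec.attributes.get(k) for k in ("ID", "Name", "transcript_id", "Parent")]
        extra = next((mapping[k] for k in keys if k and k in mapping), None)
        if extra and extra not in rec.functional_annotation:
            merged = f"{rec.functional_annotation}; {extra}" if rec.functional_annotation else extra
            out.append(replace_annotation(rec, merged))
        else:
            out.append(rec)
    return out


def replace_annotation(rec: FeatureRecord, text: str) -> FeatureRecord:
    new = FeatureRecord(
        chrom_id=rec.chrom_id,
        source=rec.source,
        feature_type=rec.feature_type,
        start=rec.start,
        end=rec.end,
        score=rec.score,
        strand=rec.strand,
        phase=rec.phase,
        attributes=dict(rec.attributes),
        functional_annotation=text,
    )
    return new
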