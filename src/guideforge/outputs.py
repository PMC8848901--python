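"""CSV serialization of the guide database, and filtered queries over it.

The CSV is the pipeline's single persistent product: one row per guide,
pinned column order, scores printed with six decimals, RFC-4180 quoting
(annotations often contain commas).  A written file re-reads losslessly,
so repeated runs on the same genome reduce to a database query.
"""

from __future__ import annotations

import csv
import gzip
import io
from typing import Optional

from guideforge.design import GuideRecord
from guideforge.primers import PrimerCandidate, PrimerPair

COLUMNS = [
    "guide_id",
    "chrom",
    "start",
    "end",
    "strand",
    "guide_seq",
    "pam_seq",
    "context_seq",
    "cutsite",
    "crispr_system",
    "onsite_score",
    "multi_hit",
    "annotation",
    "fwd_primer",
    "rev_primer",
    "fwd_tm",
    "rev_tm",
    "amplicon_length",
    "homeolog_tag",
]


class SchemaError(ValueError):
    pass


def _open(path: str, mode: str):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"), newline="")
    return open(path, mode, newline="")


def _row(g: GuideRecord) -> list[str]:
    p = g.primer_pair
    return [
        g.guide_id,
        g.chrom_id,
        str(g.start),
        str(g.end),
        g.strand,
        g.guide_seq,
        g.pam_seq,
        g.context_seq,
        str(g.cutsite),
        g.system,
        f"{g.onsite_score:.6f}" if g.onsite_score is not None else "",
        str(g.multi_hit).lower(),
        g.annotation,
        p.forward.sequence if p else "",
        p.reverse.sequence if p else "",
        f"{p.forward.tm:.4f}" if p else "",
        f"{p.reverse.tm:.4f}" if p else "",
        str(p.amplicon_length) if p else "",
        str(p.homeolog_tag).lower() if p else "",
    ]


def write_guides(guides: list[GuideRecord], path: str) -> None:
    """Write the guide table in (chrom, start, strand) order."""
    ordered = sorted(guides, key=lambda g: (g.chrom_id, g.start, g.strand))
    with _open(path, "w") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for g in ordered:
            writer.writerow(_row(g))


def read_guides(path: str) -> list[GuideRecord]:
    """Inverse of write_guides (primer genomic coordinates are not stored in
    the table, so re-read pairs carry None amplicon bounds)."""
    with _open(path, "r") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != COLUMNS:
            missing = [c for c in COLUMNS if c not in header]
            extra = [c for c in header if c not in COLUMNS]
            raise SchemaError(f"schema mismatch: missing {missing}, unexpected {extra}")
        guides = []
        for row in reader:
            rec = dict(zip(COLUMNS, row))
            pair: Optional[PrimerPair] = None
            if rec["fwd_primer"]:
                fwd = PrimerCandidate(rec["fwd_primer"], "+", -1, float("nan"), float(rec["fwd_tm"]))
                rev = PrimerCandidate(rec["rev_primer"], "-", -1, float("nan"), float(rec["rev_tm"]))
                pair = PrimerPair(
                    forward=fwd,
                    reverse=rev,
                    amplicon_start=None,
                    amplicon_end=None,
                    amplicon_length=int(rec["amplicon_length"]),
                    tm_delta=abs(fwd.tm - rev.tm),
                    homeolog_tag=rec["homeolog_tag"] == "true",
                )
            guides.append(
                GuideRecord(
                    guide_id=rec["guide_id"],
                    chrom_id=rec["chrom"],
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    strand=rec["strand"],
                    guide_seq=rec["guide_seq"],
                    pam_seq=rec["pam_seq"],
                    context_seq=rec["context_seq"],
                    cutsite=int(rec["cutsite"]),
                    system=rec["crispr_system"],
                    onsite_score=float(rec["onsite_score"]) if rec["onsite_score"] else None,
                    multi_hit=rec["multi_hit"] == "true",
                    annotation=rec["annotation"],
                    primer_pair=pair,
                )
            )
    return guides


def query_guides(
    guides: list[GuideRecord],
    chrom: Optional[str] = None,
    interval: Optional[tuple[int, int]] = None,
    min_score: Optional[float] = None,
    unique_only: bool = False,
    annotation_contains: Optional[str] = None,
) -> list[GuideRecord]:
    """Conjunctive filters over the guide table.

    interval is 0-based half-open on the forward strand and matches guides
    whose protospacer overlaps it.
    """
    out = []
    for g in guides:
        if chrom is not None and g.chrom_id != chrom:
            continue
        if interval is not None:
            lo, hi = interval
            if g.end <= lo or g.start >= hi:
                continue
        if min_score is not None and (g.onsite_score is None or g.onsite_score < min_score):
            continue
        if unique_only and g.multi_hit:
            continue
        if annotation_contains is not None and annotation_contains not in g.annotation:
            continue
        out.append(g)
    return out
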