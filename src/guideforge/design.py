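"""Guide discovery: scan both strands of each chromosome for PAM sites.

Every PAM occurrence whose full protospacer *and* scoring-context window
fit inside the chromosome yields one GuideRecord.  Minus-strand hits are
reported in forward-strand coordinates with guide, PAM and context
reverse-complemented into guide orientation.  Guides whose protospacer
or context contains N are dropped (one-hot encoding is undefined for N,
and assembly gaps are not designable targets anyway).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

from guideforge.sequence_io import GenomeSequence
from guideforge.systems import CrisprSystem, compile_pam, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from guideforge.primers import PrimerPair


class BoundaryError(ValueError):
    pass


@dataclass
class GuideRecord:
    """One candidate guide RNA.

    start/end are 0-based half-open protospacer coordinates on the forward
    strand; guide_seq / pam_seq / context_seq are in guide (5'->3') orientation;
    cutsite is the 0-based forward-strand position of the base immediately 5'
    of the blunt-cut bond.
    """

    guide_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    guide_seq: str
    pam_seq: str
    context_seq: str
    cutsite: int
    system: str = "cas9"
    onsite_score: Optional[float] = None
    multi_hit: bool = False
    annotation: str = ""
    primer_pair: Optional["PrimerPair"] = field(default=None, repr=False)


def assign_guide_id(chrom_id: str, start: int, strand: str, system: CrisprSystem) -> str:
    """Deterministic, collision-resistant guide identifier.

    A hash of the locus rather than a random token: identical inputs give
    identical IDs across runs, so re-running a genome reproduces the database.
    """
    key = f"{chrom_id}|{start}|{strand}|{system.name}"
    return hashlib.sha1(key.encode()).hexdigest()[:12]


def cutsite_position(start: int, end: int, strand: str, system: CrisprSystem) -> int:
    """Forward-strand cut position from the signed cut offset.

    The offset is measured from the PAM-proximal end of the protospacer;
    for SpCas9 (offset -3) the blunt cut falls between protospacer
    positions 17 and 18.
    """
    pam_at_end = (system.pam_side == "3prime") == (strand == "+")
    if pam_at_end:
        return end + system.cut_offset - 1
    return start - system.cut_offset - 1


def make_context(seq: GenomeSequence, start: int, end: int, strand: str, system: CrisprSystem) -> str:
    """Scoring context: flank + protospacer + flank, in guide orientation."""
    lo, hi = start - system.context_flank, end + system.context_flank
    if lo < 0 or hi > seq.length:
        raise BoundaryError(f"context window [{lo},{hi}) outside chromosome {seq.chrom_id}")
    window = seq.sequence[lo:hi]
    return window if strand == "+" else revcomp(window)


def scan_chromosome(seq: GenomeSequence, system: CrisprSystem) -> list[GuideRecord]:
    """All scoreable guides on both strands of one chromosome, sorted by
    (start, strand). Scores are left unset."""
    pam_re = compile_pam(system)
    minus_system = CrisprSystem(
        name=system.name,
        pam_pattern=_revcomp_motif(system.pam_pattern),
        pam_side=system.pam_side,
        guide_length=system.guide_length,
        context_flank=system.context_flank,
        cut_offset=system.cut_offset,
    )
    minus_re = compile_pam(minus_system)
    s = seq.sequence
    G, P = system.guide_length, system.pam_length
    records: list[GuideRecord] = []

    for m in pam_re.finditer(s):
        p = m.start()
        if system.pam_side == "3prime":
            start, end = p - G, p
            pam = s[p : p + P]
        else:
            start, end = p + P, p + P + G
            pam = s[p : p + P]
        rec = _emit(seq, start, end, "+", pam, system)
        if rec:
            records.append(rec)

    for m in minus_re.finditer(s):
        q = m.start()
        if system.pam_side == "3prime":
            # PAM on minus strand: protospacer lies 3' of it on the forward strand
            start, end = q + P, q + P + G
        else:
            start, end = q - G, q
        pam = revcomp(s[q : q + P])
        rec = _emit(seq, start, end, "-", pam, system)
        if rec:
            records.append(rec)

    records.sort(key=lambda r: (r.start, r.strand))
    return records


def _emit(seq: GenomeSequence, start: int, end: int, strand: str, pam: str, system: CrisprSystem) -> Optional[GuideRecord]:
    if start - system.context_flank < 0 or end + system.context_flank > seq.length:
        return None
    guide = seq.sequence[start:end]
    if strand == "-":
        guide = revcomp(guide)
    context = make_context(seq, start, end, strand, system)
    if "N" in guide or "N" in context or "N" in pam:
        return None
    return GuideRecord(
        guide_id=assign_guide_id(seq.chrom_id, start, strand, system),
        chrom_id=seq.chrom_id,
        start=start,
        end=end,
        strand=strand,
        guide_seq=guide,
        pam_seq=pam,
        context_seq=context,
        cutsite=cutsite_position(start, end, strand, system),
        system=system.name,
    )


def _revcomp_motif(motif: str) -> str:
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D",
    }
    return "".join(comp[c] for c in motif.upper())[::-1]


def scan_genome(genome: dict[str, GenomeSequence], system: CrisprSystem) -> list[GuideRecord]:
    """Scan every chromosome; results concatenated in genome dict order."""
    out: list[GuideRecord] = []
    for chrom in genome.values():
        out.extend(scan_chromosome(chrom, system))
    return out
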