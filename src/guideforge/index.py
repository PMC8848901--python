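"""Exact-match k-mer index over both genome strands.

Used to tag guides whose 20-mer occurs at more than one locus and to
test amplicon uniqueness.  Matching is exact with no mismatches; guides
hitting multiple loci are *tagged*, never penalized — in polyploid crops
editing every copy of a gene is often the goal.

A locus is a (chrom, forward-strand position) pair: a perfect-palindrome
word matching the same position on both strands counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from guideforge.design import GuideRecord
from guideforge.sequence_io import GenomeSequence
from guideforge.systems import revcomp

logger = logging.getLogger(__name__)


class IndexUsageError(ValueError):
    pass


class GuideIntegrityError(ValueError):
    pass


@dataclass
class KmerIndex:
    k: int
    postings: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    def loci(self, word: str) -> list[tuple[str, int]]:
        """Distinct (chrom, forward position) loci where `word` occurs on
        either strand, in sorted order."""
        if len(word) != self.k:
            raise IndexUsageError(f"query length {len(word)} != index k {self.k}")
        seen = {(c, p) for (c, p, _s) in self.postings.get(word, [])}
        seen |= {(c, p) for (c, p, _s) in self.postings.get(revcomp(word), []) }
        return sorted(seen)


def build_index(genome: dict[str, GenomeSequence], k: int) -> KmerIndex:
    """Index every N-free k-mer occurrence of the genome.

    Only forward-strand words are stored; minus-strand hits are resolved at
    query time by also looking up the query's reverse complement, which
    halves memory without losing any locus.
    """
    if k < 1:
        raise IndexUsageError("k must be >= 1")
    index = KmerIndex(k=k)
    indexed_any = False
    for chrom in genome.values():
        s = chrom.sequence
        for p in range(0, chrom.length - k + 1):
            word = s[p : p + k]
            if "N" in word:
                continue
            index.postings.setdefault(word, []).append((chrom.chrom_id, p, "+"))
            indexed_any = True
    if not indexed_any:
        logger.warning("k=%d exceeds every chromosome length; index is empty", k)
    for lst in index.postings.values():
        lst.sort(key=lambda t: (t[0], t[1]))
    return index


def locate_exact(index: KmerIndex, word: str) -> list[tuple[str, int]]:
    """All loci where `word` occurs on either strand, deduplicated."""
    return index.loci(word)


def tag_multi_hits(guides: list[GuideRecord], index: KmerIndex) -> list[GuideRecord]:
    """Set multi_hit on guides whose exact 20-mer occurs at >= 2 distinct loci.

    The guide's own locus counts as one hit.  Scores are never modified.
    Raises :class:`GuideIntegrityError` if a guide's claimed locus is absent
    from the index (a sign the index was built on a different assembly).
    """
    for g in guides:
        loci = index.loci(g.guide_seq)
        own = (g.chrom_id, g.start)
        if own not in loci:
            raise GuideIntegrityError(
                f"guide {g.guide_id} claims locus {own} but the index has no match there"
            )
        g.multi_hit = len(loci) >= 2
    return guides
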