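"""Functional annotation of guides by interval stabbing at the cut site.

Every GFF feature whose 1-based inclusive [start, end] interval contains
the cut position contributes its feature type and functional annotation
text to the guide; guides hitting no feature are intergenic and keep an
empty annotation (they are *not* dropped — genome-wide design is the
point).  Internal guide coordinates are 0-based, so the cut position is
shifted by +1 before the stab.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from guideforge.design import GuideRecord
from guideforge.sequence_io import FeatureRecord

logger = logging.getLogger(__name__)


@dataclass
class IntervalCatalog:
    """Per-chromosome feature intervals supporting point stabbing queries.

    Features are kept sorted by start; a query walks candidates whose start
    is <= the point and filters by end.  An auxiliary running maximum of
    interval ends lets the walk stop early on sorted data.
    """

    by_chrom: dict[str, list[FeatureRecord]] = field(default_factory=dict)
    _starts: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _max_end_prefix: dict[str, list[int]] = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, features: list[FeatureRecord]) -> "IntervalCatalog":
        cat = cls()
        for f in features:
            cat.by_chrom.setdefault(f.chrom_id, []).append(f)
        for chrom, feats in cat.by_chrom.items():
            feats.sort(key=lambda f: (f.start, f.end))
            cat._starts[chrom] = [f.start for f in feats]
            running, prefix = 0, []
            for f in feats:
                running = max(running, f.end)
                prefix.append(running)
            cat._max_end_prefix[chrom] = prefix
        return cat

    def stab(self, chrom_id: str, pos_1based: int) -> list[FeatureRecord]:
        """All features with start <= pos <= end (1-based inclusive)."""
        feats = self.by_chrom.get(chrom_id)
        if not feats:
            return []
        hi = bisect.bisect_right(self._starts[chrom_id], pos_1based)
        hits = []
        prefix = self._max_end_prefix[chrom_id]
        for i in range(hi - 1, -1, -1):
            if prefix[i] < pos_1based:
                break  # nothing earlier can reach this point
            if feats[i].end >= pos_1based:
                hits.append(feats[i])
        hits.reverse()
        return hits


def annotate_guides(guides: list[GuideRecord], catalog: IntervalCatalog) -> list[GuideRecord]:
    """Set guide.annotation from all features containing the cut site.

    Hits are joined as 'feature_type:annotation' in (start, feature_type)
    order.  A chromosome missing from the catalog logs a warning and leaves
    the annotation empty.
    """
    warned: set[str] = set()
    for g in guides:
        if g.chrom_id not in catalog.by_chrom:
            if g.chrom_id not in warned:
                logger.warning("chromosome %s absent from annotation catalog", g.chrom_id)
                warned.add(g.chrom_id)
            g.annotation = ""
            continue
        hits = catalog.stab(g.chrom_id, g.cutsite + 1)  # 0-based -> 1-based
        hits.sort(key=lambda f: (f.start, f.feature_type))
        g.annotation = "; ".join(
            f"{f.feature_type}:{f.functional_annotation}" if f.functional_annotation else f.feature_type
            for f in hits
        )
    return guides
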