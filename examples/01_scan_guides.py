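"""Scan a synthetic chromosome for Cas9 guides.

Every 20-bp protospacer adjacent to an NGG PAM on either strand is reported
with its genomic window, strand, 30-bp scoring context and predicted blunt
cut site three bases inside the protospacer.
"""

from guideforge import get_system, scan_chromosome
from guideforge.fixtures import FixtureSpec, make_genome

cas9 = get_system("cas9")
genome, _ = make_genome(FixtureSpec(seed=42, chrom_lengths=[10_000], gc_fraction=0.45))
guides = scan_chromosome(genome["chr1"], cas9)

print(f"chromosome length: {genome['chr1'].length} bp")
print(f"guides found: {len(guides)}")
plus = sum(1 for g in guides if g.strand == "+")
print(f"by strand: +{plus} / -{len(guides) - plus}  (roughly balanced, as expected for random sequence)")

g = guides[0]
print(f"first guide {g.guide_id}: {g.guide_seq} PAM={g.pam_seq} strand={g.strand}")
print(f"  occupies [{g.start}, {g.end}) with cut between bases {g.cutsite} and {g.cutsite + 1}")
print(f"  30-bp context used for scoring: {g.context_seq}")
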