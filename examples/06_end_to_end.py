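"""Full genome-mode pipeline on a synthetic genome, written to a CSV database.

Scan, score, multi-hit tag, annotate against a GFF3, design primers, write
the guide database, and query it back by region and score.
"""

import tempfile
from pathlib import Path

from guideforge import (
    IntervalCatalog,
    annotate_guides,
    build_index,
    get_system,
    query_guides,
    read_guides,
    scan_chromosome,
    score_logistic,
    tag_multi_hits,
    write_guides,
)
from guideforge.fixtures import FixtureSpec, make_genome, make_gff
from guideforge.primers import design_primers
from guideforge.sequence_io import read_gff

workdir = Path(tempfile.mkdtemp())
spec = FixtureSpec(seed=11, chrom_lengths=[20_000], gc_fraction=0.35,
                   duplication=(5000, 7000, 1), gene_density=2.0)
genome, _ = make_genome(spec, str(workdir / "genome.fa"))
make_gff(spec, genome, str(workdir / "genome.gff3"))

cas9 = get_system("cas9")
guides = scan_chromosome(genome["chr1"], cas9)
for g in guides:
    g.onsite_score = score_logistic(g.context_seq)
tag_multi_hits(guides, build_index(genome, cas9.guide_length))
annotate_guides(guides, IntervalCatalog.build(read_gff(workdir / "genome.gff3")))
design_primers(guides, genome)

db = workdir / "guides.csv"
write_guides(guides, str(db))
print(f"designed {len(guides)} guides; "
      f"{sum(g.multi_hit for g in guides)} multi-hit, "
      f"{sum(1 for g in guides if g.annotation)} inside annotated genes, "
      f"{sum(1 for g in guides if g.primer_pair)} with primer pairs")

rows = read_guides(str(db))
hits = query_guides(rows, chrom="chr1", interval=(0, 5000), min_score=0.6, unique_only=True)
print(f"query chr1:0-5000, score >= 0.6, unique only: {len(hits)} guides")
best = max(hits, key=lambda g: g.onsite_score)
print(f"best hit {best.guide_id}: score {best.onsite_score:.6f}, "
      f"annotation '{best.annotation or '(intergenic)'}'")
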