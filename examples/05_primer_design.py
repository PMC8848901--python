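"""Design a validation PCR primer pair around a guide's cut site.

Primer stability uses nearest-neighbor duplex free energies (kJ/mol at
37 C); pairs are matched on a melting-temperature surrogate derived from
the formation free energy, and amplicons that fall entirely inside a
duplicated region are tagged as homeologous.
"""

from guideforge import (
    design_for_guide,
    get_system,
    melting_temperature,
    nn_delta_g,
    scan_chromosome,
)
from guideforge.fixtures import FixtureSpec, make_genome

print(f"duplex dG(AA)   = {nn_delta_g('AA'):+.2f} kJ/mol (initiation only, unstable)")
print(f"duplex dG(ACGT) = {nn_delta_g('ACGT'):+.2f} kJ/mol (three stacks + termini)")
print(f"tm surrogate at dG = -100 kJ/mol: {melting_temperature(-100.0):.2f}")

cas9 = get_system("cas9")
genome, _ = make_genome(FixtureSpec(seed=42, chrom_lengths=[10_000], gc_fraction=0.45))
guide = scan_chromosome(genome["chr1"], cas9)[100]
design_for_guide(guide, genome)
p = guide.primer_pair
print(f"guide cut between bases {guide.cutsite} and {guide.cutsite + 1}")
print(f"forward primer: {p.forward.sequence} (tm {p.forward.tm:.2f})")
print(f"reverse primer: {p.reverse.sequence} (tm {p.reverse.tm:.2f})")
print(f"amplicon [{p.amplicon_start}, {p.amplicon_end}) = {p.amplicon_length} bp, "
      f"tm delta {p.tm_delta:.3f}, homeolog tag: {p.homeolog_tag}")
print("the amplicon brackets the cut site so the edited locus can be sequenced")
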