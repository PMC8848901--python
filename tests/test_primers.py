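import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guideforge.design import scan_chromosome
from guideforge.fixtures import FixtureSpec, make_genome
from guideforge.primers import (
    DEFAULT_NN,
    PrimerConfig,
    PrimerUsageError,
    design_for_guide,
    design_primers,
    generate_pools,
    match_pairs,
    melting_temperature,
    nn_delta_g,
    primer_pattern_ok,
    standalone_design,
    tag_homeologs,
)
from guideforge.sequence_io import GenomeSequence
from guideforge.systems import revcomp

dna = st.text(alphabet="ACGT", min_size=2, max_size=40)


class TestThermodynamics:
    def test_hand_sum_aa(self):
        # two A/T termini (4.31 each) + one AA stack (-4.26)
        assert nn_delta_g("AA") == pytest.approx(4.31 + 4.31 - 4.26, abs=1e-9)

    def test_hand_sum_acgt(self):
        # termini A,T; stacks AC, CG, GT (GT resolves via revcomp to AC)
        assert nn_delta_g("ACGT") == pytest.approx(4.31 + 4.31 - 6.09 - 9.07 - 6.09, abs=1e-9)

    @settings(max_examples=300, deadline=None)
    @given(seq=dna)
    def test_strand_symmetry(self, seq):
        """Both strands describe the same duplex, so the nearest-neighbor sum
        is invariant under reverse complementation."""
        assert nn_delta_g(seq) == pytest.approx(nn_delta_g(revcomp(seq)), abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(seq=dna, base=st.sampled_from("ACGT"))
    def test_extension_additivity(self, seq, base):
        """Appending one base adds exactly the new stack plus the change in
        the terminal initiation term."""
        init = {b: 4.31 if b in "AT" else 4.05 for b in "ACGT"}
        stack = seq[-1] + base
        table = DEFAULT_NN.stack_dg
        dg_stack = table.get(stack, table.get(revcomp(stack)))
        expected = nn_delta_g(seq) + dg_stack - init[seq[-1]] + init[base]
        assert nn_delta_g(seq + base) == pytest.approx(expected, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(PrimerUsageError):
            nn_delta_g("A")

    def test_melting_temperature_values(self):
        assert melting_temperature(-100.0) == pytest.approx(
            100000 / (8.314 * 310.15 * math.log(2)), abs=1e-9
        )
        assert melting_temperature(-100.0) == pytest.approx(55.95, abs=0.01)
        assert melting_temperature(nn_delta_g("ACGT")) == pytest.approx(7.07, abs=0.01)

    def test_tm_monotone_decreasing_in_dg(self):
        assert melting_temperature(-50) < melting_temperature(-60)


@pytest.fixture(scope="module")
def template():
    genome, _ = make_genome(FixtureSpec(seed=77, chrom_lengths=[2500], gc_fraction=0.5))
    return genome["chr1"]


class TestPools:
    def test_candidates_revalidate_and_match_pattern_oracle(self, template):
        cfg = PrimerConfig()
        cut = 1250
        fwd, rev = generate_pools(template, cut, cfg)
        assert fwd and rev
        s = template.sequence
        for c in fwd:
            assert c.sequence == s[c.genomic_start : c.genomic_end]
            assert c.genomic_end - 1 <= cut - cfg.min_arm
            assert primer_pattern_ok(c.sequence, cfg)
        for c in rev:
            assert c.sequence == revcomp(s[c.genomic_start : c.genomic_end])
            assert c.genomic_start >= cut + cfg.min_arm
            assert primer_pattern_ok(c.sequence, cfg)
        # brute-force oracle: every pattern-valid window in range appears
        # (up to the deterministic pool cap)
        expected_fwd = set()
        for a in range(max(0, cut - cfg.max_amplicon), cut):
            for ln in range(cfg.min_length, cfg.max_length + 1):
                b = a + ln
                if b - 1 <= cut - cfg.min_arm and primer_pattern_ok(s[a:b], cfg):
                    expected_fwd.add((a, b))
        got = {(c.genomic_start, c.genomic_end) for c in fwd}
        if len(expected_fwd) <= cfg.max_pool:
            assert got == expected_fwd
        else:
            assert got <= expected_fwd and len(got) == cfg.max_pool

    def test_pattern_filter_rules(self):
        cfg = PrimerConfig()
        assert not primer_pattern_ok("ACG", cfg)  # too short
        assert not primer_pattern_ok("A" * 24, cfg)  # homopolymer + no clamp
        assert not primer_pattern_ok("GCGCGCGCGCGCGCGCGCGC", cfg)  # GC too high
        assert not primer_pattern_ok("ATATGCGCATATGCGCATAT", cfg)  # 3' T: no clamp
        assert primer_pattern_ok("ATATGCGCATATGCGCATAC", cfg)
        assert not primer_pattern_ok("AAAAATGCGCATGCGCATAC", cfg)  # run of 5 A

    def test_cutsite_outside_template_rejected(self, template):
        with pytest.raises(PrimerUsageError):
            generate_pools(template, 99_999)


class TestPairs:
    def test_ranking_matches_cross_product_oracle(self, template):
        cfg = PrimerConfig()
        cut = 1250
        fwd, rev = generate_pools(template, cut, cfg)
        fwd, rev = fwd[:5], rev[:5]
        pairs = match_pairs(fwd, rev, cut, cfg)
        oracle = []
        for f in fwd:
            for r in rev:
                length = r.genomic_end - f.genomic_start
                if (
                    cfg.min_amplicon <= length <= cfg.max_amplicon
                    and f.genomic_start < cut < r.genomic_end - 1
                    and abs(f.tm - r.tm) <= cfg.max_tm_delta
                ):
                    oracle.append((f, r, length, abs(f.tm - r.tm)))
        oracle.sort(
            key=lambda t: (t[3], abs(t[2] - cfg.target_amplicon), t[0].genomic_start, t[0].sequence, t[1].sequence)
        )
        assert [(p.forward, p.reverse) for p in pairs] == [(f, r) for f, r, _, _ in oracle]
        for p in pairs:
            assert p.amplicon_start < cut < p.amplicon_end - 1
            assert p.amplicon_length == p.amplicon_end - p.amplicon_start

    def test_order_invariant_to_pool_permutation(self, template):
        cfg = PrimerConfig()
        cut = 1250
        fwd, rev = generate_pools(template, cut, cfg)
        a = match_pairs(fwd, rev, cut, cfg)
        b = match_pairs(list(reversed(fwd)), list(reversed(rev)), cut, cfg)
        assert [(p.forward.sequence, p.reverse.sequence) for p in a] == [
            (p.forward.sequence, p.reverse.sequence) for p in b
        ]


class TestHomeologs:
    def test_unique_genome_pairs_untagged(self, template):
        genome = {template.chrom_id: template}
        cfg = PrimerConfig()
        fwd, rev = generate_pools(template, 1250, cfg)
        pairs = match_pairs(fwd, rev, 1250, cfg)
        assert pairs
        assert not tag_homeologs(pairs[0], genome, cfg).homeolog_tag

    def test_duplicated_region_pairs_tagged(self):
        genome, truth = make_genome(
            FixtureSpec(seed=21, chrom_lengths=[6000], gc_fraction=0.5, duplication=(1000, 4000, 1))
        )
        chrom = genome["chr1"]
        cfg = PrimerConfig()
        cut = 2500  # deep inside the duplicated source interval
        fwd, rev = generate_pools(chrom, cut, cfg)
        pairs = match_pairs(fwd, rev, cut, cfg)
        inside = [
            p
            for p in pairs
            if any(p.amplicon_start >= lo and p.amplicon_end <= hi for lo, hi in truth["chr1"])
        ]
        assert inside
        for p in inside[:5]:
            assert tag_homeologs(p, genome, cfg).homeolog_tag

    def test_straddling_pair_untagged_and_preferred(self, cas9):
        genome, truth = make_genome(
            FixtureSpec(seed=21, chrom_lengths=[6000], gc_fraction=0.5, duplication=(1000, 4000, 1))
        )
        # cuts near the duplication edge whose candidate pools contain both
        # confined (duplicated) and straddling (unique) amplicons: with an
        # exhaustive tag walk the unique amplicon must win the selection
        chrom = genome["chr1"]
        guides = [g for g in scan_chromosome(chrom, cas9) if 3898 <= g.cutsite <= 3925]
        assert guides
        lo, hi = truth["chr1"][0]
        for g in guides:
            g = design_for_guide(g, genome, tag_limit=10_000)
            assert g.primer_pair is not None
            assert not g.primer_pair.homeolog_tag
            assert not (g.primer_pair.amplicon_start >= lo and g.primer_pair.amplicon_end <= hi)

    def test_design_attaches_amplicon_containing_cutsite(self, cas9, small_genome):
        guides = scan_chromosome(small_genome["chr1"], cas9)[:10]
        design_primers(guides, small_genome)
        attached = [g for g in guides if g.primer_pair is not None]
        assert attached
        for g in attached:
            p = g.primer_pair
            assert p.amplicon_start < g.cutsite < p.amplicon_end - 1
            assert p.tm_delta <= PrimerConfig().max_tm_delta


class TestStandalone:
    def test_single_record_csv(self, tmp_path, small_genome):
        import pandas as pd

        from guideforge.sequence_io import write_fasta

        fasta = tmp_path / "t.fa"
        write_fasta(small_genome, fasta)
        out = tmp_path / "primers.csv"
        n = standalone_design(str(fasta), str(out))
        df = pd.read_csv(out)
        assert n == len(df) == 1
        tag = str(df.iloc[0]["homeolog_tag"]).lower()
        assert tag in ("false", "no_pair")

    def test_duplicated_record_gets_homeolog_tag(self, tmp_path):
        genome, _ = make_genome(FixtureSpec(seed=33, chrom_lengths=[3000], gc_fraction=0.5))
        seq = genome["chr1"].sequence
        fasta = tmp_path / "dup.fa"
        fasta.write_text(f">copyA\n{seq}\n>copyB\n{seq}\n")
        out = tmp_path / "p.csv"
        import pandas as pd

        standalone_design(str(fasta), str(out))
        df = pd.read_csv(out)
        assert len(df) == 2
        designed = df[df["fwd_seq"].notna()]
        assert len(designed) == 2
        assert all(str(t).lower() == "true" for t in designed["homeolog_tag"])
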