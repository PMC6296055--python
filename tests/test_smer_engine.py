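"""Localized s-mer enumeration, probabilities, counting, and the export."""

from collections import Counter

import numpy as np
import pytest

from conftest import naive_substring_counts
from varsieve.fixtures import FixtureSpec, generate_panel, generate_reference
from varsieve.genome_io import HaplotypePanel, ReferenceGenome, VariantRecord
from varsieve.smer_engine import (
    ModelConfig,
    SmerError,
    SmerSpace,
    count_smers,
    enumerate_smers_at,
    external_counter_export,
    smer_probability,
    window_offsets,
)


def snv(chrom, pos, ref_base, alt, freq, vid, col=None):
    return VariantRecord(chrom=chrom, pos=pos, ref_allele=ref_base,
                         alt_allele=alt, alt_freq=freq, vid=vid,
                         panel_column=None if col is None
                         else np.asarray(col, dtype=np.uint8))


class TestModelConfig:
    def test_defaults(self):
        cfg = ModelConfig(s=100)
        assert (cfg.k_cap, cfg.w, cfg.erg_window) == (15, 0.5, 100)

    @pytest.mark.parametrize("kwargs", [{"s": 1}, {"s": 10, "k_cap": 0},
                                        {"s": 10, "k_cap": 25},
                                        {"s": 10, "w": 0.0}, {"s": 10, "w": 1.5}])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(SmerError):
            ModelConfig(**kwargs)


class TestWindowOffsets:
    ref10 = ReferenceGenome({"c": "ACGTACGGTC"})

    @pytest.mark.parametrize("pos,s,expected", [
        (5, 4, [2, 3, 4, 5]),   # interior SNV: s offsets
        (0, 4, [0]),            # left clip
        (9, 4, [6]),            # right clip
    ])
    def test_snv_offsets(self, pos, s, expected):
        v = snv("c", pos, self.ref10.chromosomes["c"][pos], "A", 0.1, 0)
        assert window_offsets(v, s, self.ref10) == expected

    def test_deletion_covers_deleted_bases(self):
        # REF spans [4, 7): windows overlapping the anchor or a deleted base
        v = VariantRecord(chrom="c", pos=4, ref_allele="CGG", alt_allele="C",
                          alt_freq=0.1, vid=0)
        assert window_offsets(v, 3, self.ref10) == [2, 3, 4, 5, 6]

    def test_chromosome_shorter_than_s(self):
        short = ReferenceGenome({"c": "ACGT"})
        v = snv("c", 1, "C", "T", 0.1, 0)
        assert window_offsets(v, 10, short) == []


class TestEnumerate:
    def test_gatyaca_toy(self):
        ref = ReferenceGenome({"toy": "GATTACA"})
        smers = enumerate_smers_at(ref, [snv("toy", 3, "T", "C", 0.5, 0)],
                                   l=2, s=3)
        assert sorted(sm.seq for sm in smers) == ["TCA", "TTA"]

    def test_two_variants_four_combos(self):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        vs = [snv("c", 3, "T", "G", 0.2, 0), snv("c", 5, "C", "A", 0.4, 1)]
        smers = enumerate_smers_at(ref, vs, l=2, s=5)
        assert len(smers) == 4
        assert sorted(sm.seq for sm in smers) == \
            sorted({"GTACG", "GGACG", "GTAAG", "GGAAG"})

    def test_no_variants_single_reference_smer(self):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        (sm,) = enumerate_smers_at(ref, [], l=2, s=4)
        assert sm.seq == "GTAC" and sm.allele_combo == () and sm.p_s == 1.0

    def test_insertion_prefix_extends_rightward(self):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        ins = VariantRecord(chrom="c", pos=2, ref_allele="G", alt_allele="GTT",
                            alt_freq=0.1, vid=0)
        smers = enumerate_smers_at(ref, [ins], l=1, s=4)
        assert sorted(sm.seq for sm in smers) == ["CGTA", "CGTT"]

    def test_deletion_consumes_reference(self):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        dele = VariantRecord(chrom="c", pos=2, ref_allele="GTA", alt_allele="G",
                             alt_freq=0.1, vid=0)
        smers = enumerate_smers_at(ref, [dele], l=1, s=4)
        assert sorted(sm.seq for sm in smers) == ["CGCG", "CGTA"]


class TestProbability:
    def test_unphased_product(self):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        vs = [snv("c", 3, "T", "G", 0.2, 0), snv("c", 5, "C", "A", 0.5, 1)]
        space = SmerSpace(ref, vs, s=5)
        smers = {sm.allele_combo: sm for sm in space.enumerate_at("c", 2)}
        assert smers[(0,)].p_s == pytest.approx(0.2 * 0.5)  # (ALT, REF)
        assert smers[()].p_s == pytest.approx(0.8 * 0.5)

    def test_phased_haplotype_count(self):
        # haplotype alleles (R,R),(A,R),(A,A),(A,A); combo (A,A) -> 2/4
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        vs = [snv("c", 3, "T", "G", 0.75, 0, col=[0, 1, 1, 1]),
              snv("c", 5, "C", "A", 0.5, 1, col=[0, 0, 1, 1])]
        space = SmerSpace(ref, vs, s=5, panel=HaplotypePanel(4))
        smers = {sm.allele_combo: sm for sm in
                 space.enumerate_at("c", 2, phased=True)}
        assert smers[(0, 1)].p_s == pytest.approx(0.5)
        assert smers[(0,)].p_s == pytest.approx(0.25)  # (A,R): haplotype 2 only

    def test_phased_without_panel_fatal(self):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        space = SmerSpace(ref, [snv("c", 3, "T", "G", 0.2, 0)], s=5)
        with pytest.raises(SmerError, match="panel"):
            space.enumerate_at("c", 2, phased=True)

    def test_smer_probability_recomputes(self):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        vs = [snv("c", 3, "T", "G", 0.2, 0)]
        space = SmerSpace(ref, vs, s=4)
        for sm in space.enumerate_at("c", 2):
            assert smer_probability(sm, vs, space.n_offsets) == pytest.approx(sm.p)

    @pytest.mark.parametrize("phased", [False, True])
    def test_normalization_per_offset(self, std_fixture, phased):
        """p_s over all combos at any offset sums to 1, phased or unphased."""
        _, ref, variants, panel = std_fixture
        space = SmerSpace(ref, variants, s=25, panel=panel)
        checked = 0
        for chrom, l in space.iter_offsets():
            if not space.window_variants(chrom, l):
                continue
            total = sum(sm.p_s for sm in
                        space.enumerate_at(chrom, l, phased=phased,
                                           need_seq=False))
            assert total == pytest.approx(1.0, abs=1e-9)
            checked += 1
        assert checked > 100

    def test_phased_equals_unphased_in_linkage_equilibrium(self):
        """Independent panel columns: co-occurrence counts equal products."""
        ref = ReferenceGenome({"c": "ACGTACGGTCACGTACGGTC"})
        vs = [snv("c", 3, "T", "G", 0.5, 0, col=[1, 1, 0, 0]),
              snv("c", 5, "C", "A", 0.5, 1, col=[1, 0, 1, 0])]
        space = SmerSpace(ref, vs, s=6, panel=HaplotypePanel(4))
        for l in range(3, 6):
            ph = {sm.allele_combo: sm.p_s
                  for sm in space.enumerate_at("c", l, phased=True)}
            un = {sm.allele_combo: sm.p_s
                  for sm in space.enumerate_at("c", l, phased=False)}
            assert ph == pytest.approx(un)


class TestCounting:
    def test_homopolymer(self):
        tab = count_smers(ReferenceGenome({"c": "AAAA"}), [], s=2)
        assert dict(tab.counts) == {"AA": 3}
        assert tab.total == 3

    def test_gatyaca_eight_singletons(self):
        ref = ReferenceGenome({"toy": "GATTACA"})
        tab = count_smers(ref, [snv("toy", 3, "T", "C", 0.5, 0)], s=3)
        assert sorted(tab.counts) == \
            ["ACA", "ATC", "ATT", "CAC", "GAT", "TAC", "TCA", "TTA"]
        assert all(c == 1 for c in tab.counts.values())
        assert tab.get("TCA") == 1

    def test_reference_counting_matches_naive(self):
        spec = FixtureSpec(seed=5, genome_length=5000, repeat_fraction=0.3,
                           n_variants=50, window=15)
        ref = generate_reference(spec)
        tab = count_smers(ref, [], s=15)
        assert dict(tab.counts) == dict(naive_substring_counts(ref, 15))

    def test_monotone_total_under_variant_addition(self, small_fixture):
        _, ref, variants, _ = small_fixture
        snvs = [v for v in variants if v.is_snv]
        space = SmerSpace(ref, snvs, s=12)
        prev = 0
        for n in (0, 5, 10, len(snvs)):
            total = space.count_table(
                included=frozenset(v.vid for v in snvs[:n])).total
            assert total >= prev
            prev = total

    def test_n_windows_excluded(self):
        ref = ReferenceGenome({"c": "ACGTNACGTACG"})
        space = SmerSpace(ref, [], s=4)
        # offsets 1..4 cover the N and are invalid
        assert space.n_offsets == 12 - 4 + 1 - 4
        tab = space.count_table()
        assert all("N" not in seq for seq in tab.counts)


class TestRandomGenomeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 16))
    def test_normalization_and_naive_count(self, seed):
        """Random small genomes with random SNVs: per-offset probabilities
        partition to 1, and variant-free counting is substring counting."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers(30, 120))
        s = int(rng.integers(2, 8))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        ref = ReferenceGenome({"c": seq})
        variants = []
        for vid, pos in enumerate(sorted(
                rng.choice(length, size=int(rng.integers(0, 6)),
                           replace=False).tolist())):
            base = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            variants.append(snv("c", pos, base, alt, float(rng.random()), vid))
        space = SmerSpace(ref, variants, s=s)
        for chrom, l in space.iter_offsets():
            total = sum(sm.p_s for sm in
                        space.enumerate_at(chrom, l, need_seq=False))
            assert total == pytest.approx(1.0, abs=1e-9)
        from conftest import naive_substring_counts

        assert dict(count_smers(ref, [], s).counts) == \
            dict(naive_substring_counts(ref, s))


class TestExport:
    def test_no_variants_empty_fasta(self, tmp_path):
        ref = ReferenceGenome({"c": "ACGTACGGTC"})
        out = tmp_path / "aug.fa"
        assert external_counter_export(ref, [], s=3, out=out) == 0
        assert out.read_text() == ""

    def test_one_snv_three_records(self, tmp_path):
        ref = ReferenceGenome({"toy": "GATTACA"})
        out = tmp_path / "aug.fa"
        n = external_counter_export(ref, [snv("toy", 3, "T", "C", 0.5, 0)],
                                    s=3, out=out)
        assert n == 3
        seqs = [ln for ln in out.read_text().splitlines()
                if not ln.startswith(">")]
        assert all(len(s) == 3 for s in seqs)

    def test_export_plus_reference_reproduces_count_table(self, small_fixture):
        """Counting the export with any exact counter equals count_smers."""
        _, ref, variants, _ = small_fixture
        snvs = [v for v in variants if v.is_snv]
        out_counts = Counter()
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            out = os.path.join(d, "aug.fa")
            external_counter_export(ref, snvs, s=12, out=out)
            with open(out) as fh:
                for line in fh:
                    if not line.startswith(">"):
                        out_counts[line.strip()] += 1
        ref_counts = naive_substring_counts(ref, 12)
        combined = ref_counts + out_counts
        assert dict(combined) == dict(count_smers(ref, snvs, s=12).counts)
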