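"""Subsampling, haplotype calling, thresholding, and dominance."""

import logging

import numpy as np
import pytest

from amplihap.haplo import (
    build_profile,
    call_haplotypes,
    dominant_haplotype,
    subsample_profiles,
)
from amplihap.simdata import TruthMixture, simulate_library
from amplihap.varmap import VariantProfile, profile_reads
from amplihap.variants import substitution

SNV_A = (substitution(10, "A", "T"),)
SNV_B = (substitution(20, "C", "G"),)
SNV_C = (substitution(30, "G", "A"),)


def make_profiles(n, events=(), mapped=True, prefix="r"):
    return [
        VariantProfile(read_id=f"{prefix}{i}", events=events if mapped else (), mapped=mapped)
        for i in range(n)
    ]


class TestSubsampling:
    def test_subsets_have_exact_size_and_distinct_reads(self):
        profiles = make_profiles(5000)
        subsets = subsample_profiles(profiles, subsample_size=1000, n_subsamples=5, seed=3)
        assert len(subsets) == 5
        for subset in subsets:
            assert len(subset) == 1000
            assert len({p.read_id for p in subset}) == 1000

    def test_clamping_when_pool_too_small(self, caplog):
        profiles = make_profiles(800)
        with caplog.at_level(logging.WARNING):
            subsets = subsample_profiles(profiles, subsample_size=1000, n_subsamples=3, seed=1)
        assert all(len(s) == 800 for s in subsets)
        assert any("full set" in rec.message for rec in caplog.records)

    def test_same_seed_gives_identical_subsets(self):
        profiles = make_profiles(2000)
        a = subsample_profiles(profiles, 500, 3, seed=11)
        b = subsample_profiles(profiles, 500, 3, seed=11)
        assert [[p.read_id for p in s] for s in a] == [[p.read_id for p in s] for s in b]

    def test_replicates_differ_from_each_other(self):
        profiles = make_profiles(2000)
        a, b, *_ = subsample_profiles(profiles, 500, 3, seed=11)
        assert {p.read_id for p in a} != {p.read_id for p in b}

    def test_unmapped_profiles_excluded(self):
        profiles = make_profiles(100) + make_profiles(50, mapped=False, prefix="u")
        subsets = subsample_profiles(profiles, subsample_size=200, n_subsamples=1, seed=0)
        assert len(subsets[0]) == 100

    def test_zero_mapped_reads_error(self):
        with pytest.raises(ValueError, match="no mapped"):
            subsample_profiles(make_profiles(10, mapped=False), 5, 1, seed=0)


class TestCallHaplotypes:
    def test_uniform_reference_reads(self):
        calls = call_haplotypes(make_profiles(100))
        assert calls == {(): 1.0}

    def test_counting_two_haplotypes(self):
        subset = make_profiles(7, events=SNV_A) + make_profiles(3, events=SNV_B, prefix="b")
        calls = call_haplotypes(subset)
        assert calls[SNV_A] == pytest.approx(0.7)
        assert calls[SNV_B] == pytest.approx(0.3)

    def test_frequencies_sum_to_one(self):
        subset = (
            make_profiles(5, events=SNV_A)
            + make_profiles(4, events=SNV_B, prefix="b")
            + make_profiles(11, prefix="c")
        )
        calls = call_haplotypes(subset)
        assert sum(calls.values()) == pytest.approx(1.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            call_haplotypes([])


class TestBuildProfile:
    def test_single_haplotype_profile(self):
        profile = build_profile([{(): 1.0}] * 3)
        assert len(profile.haplotypes) == 1
        assert profile.haplotypes[0].haplotype_id == "H1"
        assert profile.averaged_frequency[()] == pytest.approx(1.0)
        assert profile.background_frequency == 0.0

    def test_threshold_is_inclusive_at_exact_boundary(self):
        calls = [{(): 0.99, SNV_A: 0.01}] * 5
        profile = build_profile(calls, threshold=0.01)
        assert profile.retained[SNV_A] is True
        assert {c.haplotype_id for c in profile.haplotypes} == {"H1", "H2"}

    def test_sub_threshold_variant_absorbed_into_parent_pattern(self):
        # a 0.3% haplotype's variant never becomes demonstrable, so its
        # reads count toward the haplotype of its demonstrable variants
        # (here: the reference)
        calls = [{(): 0.997, SNV_A: 0.003}] * 5
        profile = build_profile(calls, threshold=0.01)
        assert [c.events for c in profile.haplotypes] == [()]
        assert profile.averaged_frequency[()] == pytest.approx(1.0)
        assert SNV_A[0] not in {ev for c in profile.haplotypes for ev in c.events}

    def test_absent_haplotype_counts_as_zero(self):
        calls = [{(): 0.9, SNV_A: 0.1}, {(): 1.0}]
        profile = build_profile(calls, threshold=0.01)
        assert profile.averaged_frequency[SNV_A] == pytest.approx(0.05)
        assert profile.per_subsample_frequencies[SNV_A] == [0.1, 0.0]

    def test_labels_ordered_by_descending_frequency(self):
        calls = [{(): 0.2, SNV_A: 0.5, SNV_B: 0.3}] * 2
        profile = build_profile(calls)
        assert [c.haplotype_id for c in profile.haplotypes] == ["H1", "H2", "H3"]
        assert profile.haplotypes[0].events == SNV_A
        assert profile.haplotypes[2].events == ()

    @pytest.mark.parametrize("thresholds", [(0.05, 0.01), (0.2, 0.02), (0.01, 0.001)])
    def test_lowering_threshold_never_drops_haplotypes(self, thresholds):
        high, low = thresholds
        calls = [
            {(): 0.60, SNV_A: 0.25, SNV_B: 0.10, SNV_C: 0.04, SNV_A + SNV_B: 0.01}
        ] * 5
        n_high = len(build_profile(calls, threshold=high).haplotypes)
        n_low = len(build_profile(calls, threshold=low).haplotypes)
        assert n_low >= n_high

    def test_projected_frequencies_sum_to_one_per_subsample(self):
        calls = [
            {(): 0.55, SNV_A: 0.30, SNV_B: 0.10, SNV_C: 0.049, SNV_A + SNV_C: 0.001},
            {(): 0.60, SNV_A: 0.25, SNV_B: 0.15},
        ]
        profile = build_profile(calls)
        per = np.array(list(profile.per_subsample_frequencies.values()))
        assert np.allclose(per.sum(axis=0), 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])


class TestDominantHaplotype:
    def profile_from(self, freqs):
        keys = [(), SNV_A, SNV_B, SNV_C][: len(freqs)]
        calls = [dict(zip(keys, freqs))]
        return build_profile(calls, threshold=0.01)

    def test_clear_dominant(self):
        top, co = dominant_haplotype(self.profile_from([0.95, 0.03, 0.02]))
        assert top.haplotype_id == "H1"
        assert co is False

    def test_codominant_top_two(self):
        top, co = dominant_haplotype(self.profile_from([0.43, 0.42, 0.14, 0.01]))
        assert top.haplotype_id == "H1"
        assert co is True

    def test_single_haplotype_not_codominant(self):
        top, co = dominant_haplotype(self.profile_from([1.0]))
        assert top.events == ()
        assert co is False

    def test_margin_is_exclusive(self):
        # dyadic frequencies so the gap equals the margin exactly
        top, co = dominant_haplotype(
            self.profile_from([0.5, 0.375, 0.125]), codominance_margin=0.125
        )
        assert co is False


class TestFrequencyRecovery:
    def test_error_free_mixture_recovered_within_binomial_bound(self, tmp_path):
        """End-to-end check at small scale: simulate, merge, map, call."""
        from amplihap.config import PipelineConfig
        from amplihap.pipeline import run_profile, run_simulate
        from amplihap.simdata import generate_reference

        ref = generate_reference(350, 0.5, seed=17)
        rs = ref.sequence

        def snv(pos):
            return substitution(pos, rs[pos - 1], "T" if rs[pos - 1] != "T" else "A")

        truth = {(): 0.55, (snv(61),): 0.30, (snv(100),): 0.10,
                 (snv(150),): 0.04, (snv(200),): 0.01}
        mix = TruthMixture(
            haplotypes=tuple((k, v) for k, v in truth.items()),
            error_rate=0.0, indel_error_rate=0.0,
            read_length=300, n_pairs=10_000, seed=23,
        )
        # threshold lowered: this test scores counting accuracy, not the
        # reporting threshold (covered elsewhere), so the boundary
        # haplotype at 0.01 must not sit on the retention edge
        cfg = PipelineConfig(
            seed=23, subsample_size=10_000, n_subsamples=5, threshold=0.001
        )
        lib = run_simulate(ref, mix, tmp_path / "sim", cfg)
        result = run_profile(lib.r1_path, lib.r2_path, ref, tmp_path / "prof", cfg)
        freqs = result.profile.averaged_frequency
        n = 10_000
        for events, f_true in truth.items():
            f_hat = freqs.get(events, 0.0)
            sd = np.sqrt(f_true * (1 - f_true) / n)
            assert abs(f_hat - f_true) <= 3 * sd + 1e-12

    def test_same_seed_gives_stable_labels(self, tmp_path):
        from amplihap.config import PipelineConfig
        from amplihap.pipeline import run_profile, run_simulate
        from amplihap.simdata import generate_reference

        ref = generate_reference(200, 0.5, seed=19)
        rs = ref.sequence
        mix = TruthMixture(
            haplotypes=(((), 0.7), ((substitution(50, rs[49], "T" if rs[49] != "T" else "A"),), 0.3)),
            error_rate=0.0, indel_error_rate=0.0, read_length=150,
            n_pairs=500, seed=29,
        )
        cfg = PipelineConfig(seed=29, subsample_size=500, n_subsamples=3, min_length=100)
        lib = run_simulate(ref, mix, tmp_path / "sim", cfg)
        p1 = run_profile(lib.r1_path, lib.r2_path, ref, tmp_path / "a", cfg).profile
        p2 = run_profile(lib.r1_path, lib.r2_path, ref, tmp_path / "b", cfg).profile
        assert [(c.haplotype_id, c.events) for c in p1.haplotypes] == [
            (c.haplotype_id, c.events) for c in p2.haplotypes
        ]
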