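"""Fit quality, activity statistics, energy-entropy profiles, Zipf slopes."""

import numpy as np
import pytest

import rbmtherm as rt
from rbmtherm.patterns import PatternDataset
from conftest import make_tiny_model


class TestModelDataKL:
    def test_identical_tables_give_zero(self):
        vecs = np.array([[0, 1], [1, 0], [0, 1], [1, 1]], dtype=np.uint8)
        d = PatternDataset.from_vectors(vecs)
        assert rt.model_data_kl(d, d, pseudocount=0.0) == 0.0

    def test_two_point_closed_form(self):
        held = PatternDataset.from_vectors(
            np.array([[0, 1], [1, 0]], dtype=np.uint8)
        )
        model = PatternDataset.from_vectors(
            np.array([[0, 1]] * 3 + [[1, 0]], dtype=np.uint8)
        )
        kl = rt.model_data_kl(model, held, pseudocount=0.0)
        expected = 0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)
        assert kl == pytest.approx(expected, abs=1e-12)
        assert kl == pytest.approx(0.2075, abs=1e-4)

    def test_missing_support_is_infinite_without_pseudocount(self):
        held = PatternDataset.from_vectors(np.array([[0, 1], [1, 0]], dtype=np.uint8))
        model = PatternDataset.from_vectors(np.array([[0, 1]], dtype=np.uint8))
        assert rt.model_data_kl(model, held, pseudocount=0.0) == np.inf
        assert np.isfinite(rt.model_data_kl(model, held, pseudocount=0.5))

    def test_pattern_space_mismatch(self):
        a = PatternDataset.from_vectors(np.zeros((2, 3), dtype=np.uint8))
        b = PatternDataset.from_vectors(np.zeros((2, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            rt.model_data_kl(a, b)


class TestActivityStats:
    def test_iid_fair_bits(self):
        m = rt.ModelParams.zeros(4, 3)
        ss = rt.gibbs_sample(m, n_chains=200, n_keep=50_000, thin=1, burn_in=10, seed=1)
        sparsity, corr = rt.activity_stats(ss)
        assert sparsity == pytest.approx(0.5, abs=0.01)
        assert corr < 0.01

    def test_duplicated_units_fully_correlated(self):
        h = np.random.default_rng(0).integers(0, 2, size=(1000, 1)).astype(np.uint8)
        ss = rt.StateSampleSet(
            hidden_states=np.hstack([h, h]),
            visible_states=np.zeros((1000, 2), dtype=np.uint8),
        )
        _, corr = rt.activity_stats(ss)
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_constant_units_contribute_zero_correlation(self):
        rng = np.random.default_rng(1)
        h = np.hstack(
            [
                rng.integers(0, 2, size=(1000, 2)).astype(np.uint8),
                np.ones((1000, 1), dtype=np.uint8),
            ]
        )
        ss = rt.StateSampleSet(
            hidden_states=h, visible_states=np.zeros((1000, 1), dtype=np.uint8)
        )
        _, corr = rt.activity_stats(ss)
        assert np.isfinite(corr)


class TestBinning:
    def test_arithmetic_example(self):
        idx, edges = rt.bin_by_stimulus_energy(np.array([1.0, 2, 3, 4]), 2)
        assert list(idx) == [0, 0, 1, 1]
        assert edges[1] == pytest.approx(2.5)

    def test_degenerate_range_single_bin(self):
        idx, _ = rt.bin_by_stimulus_energy(np.full(5, 3.0), 4)
        assert np.all(idx == 0)

    def test_right_edge_inclusive_and_conservation(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(5, 15, 500)
        idx, edges = rt.bin_by_stimulus_energy(e, 10)
        assert idx[np.argmax(e)] == 9
        assert np.bincount(idx, minlength=10).sum() == 500


class TestEnergyEntropyProfile:
    def test_zero_model_profile(self):
        """Uniform encoder: entropy pinned at n_hidden bits, zero slopes."""
        m = rt.ModelParams.zeros(3, 4)
        rng = np.random.default_rng(3)
        # nonuniform stimulus frequencies so E_v varies across patterns
        vecs = rt.all_binary_states(4)[rng.choice(16, 500, p=np.arange(1, 17) / 136)]
        data = PatternDataset.from_vectors(vecs)
        prof = rt.energy_entropy_profile(
            m, data, n_bins=4, mode="enumerate", seed=0, ev_source="empirical"
        )
        ok = prof.per_bin_count > 0
        assert np.allclose(prof.per_bin_mean_entropy[ok], 3.0, atol=1e-10)
        assert prof.slope_entropy_vs_Ev == pytest.approx(0.0, abs=1e-10)
        # codeword energies all equal under the uniform marginal
        assert np.allclose(prof.per_bin_mean_codeword_energy[ok], 0.0, atol=1e-10)
        assert prof.I_enc == pytest.approx(-3.0, abs=1e-10)

    def test_matches_enumeration_oracle_bin_by_bin(self):
        """Profile quantities recomputed independently from the enumerated
        joint distribution, including the anchoring convention."""
        m = make_tiny_model(n_hidden=3, n_visible=4, scale=1.5, seed=50)
        rng = np.random.default_rng(4)
        dist = rt.enumerate_model(m)
        vecs = rt.all_binary_states(4)[
            rng.choice(16, 2000, p=dist.visible_marginal)
        ]
        data = PatternDataset.from_vectors(vecs)
        n_bins = 4
        prof = rt.energy_entropy_profile(
            m, data, n_bins=n_bins, mode="enumerate", seed=0, ev_source="empirical"
        )
        # independent recomputation
        Hs = dist.hidden_states.astype(float)
        e_marg = -np.log(dist.hidden_marginal)
        anchor = e_marg.min()
        freqs = data.frequencies
        ev = -np.log2(freqs)
        ln2 = np.log(2)
        h_bits, e_bits = [], []
        for pat in data.unique_patterns.astype(float):
            vi = int(pat.astype(int) @ np.array([8, 4, 2, 1]))
            q = dist.conditional_hidden(vi)
            h_bits.append(-np.sum(q * np.log(np.clip(q, 1e-300, 1))) / ln2)
            e_bits.append(float(q @ (e_marg - anchor)) / ln2)
        h_bits, e_bits = np.array(h_bits), np.array(e_bits)
        idx, _ = rt.bin_by_stimulus_energy(ev, n_bins)
        for b in range(n_bins):
            mask = idx == b
            if not mask.any():
                continue
            w = freqs[mask] / freqs[mask].sum()
            assert prof.per_bin_mean_entropy[b] == pytest.approx(
                float(w @ h_bits[mask]), abs=1e-8
            )
            assert prof.per_bin_mean_codeword_energy[b] == pytest.approx(
                float(w @ e_bits[mask]), abs=1e-8
            )
        assert prof.I_enc == pytest.approx(
            float(freqs @ (e_bits - h_bits)), abs=1e-8
        )

    def test_ienc_is_mean_kl_up_to_anchor_constant(self):
        """I_enc equals the frequency-weighted mean KL(Q_{h|v} || Q_h),
        shifted by the (known) anchoring constant."""
        m = make_tiny_model(n_hidden=3, n_visible=3, scale=1.5, seed=51)
        rng = np.random.default_rng(5)
        dist = rt.enumerate_model(m)
        vecs = rt.all_binary_states(3)[rng.choice(8, 1000, p=dist.visible_marginal)]
        data = PatternDataset.from_vectors(vecs)
        prof = rt.energy_entropy_profile(m, data, n_bins=3, mode="enumerate", seed=0)
        freqs = data.frequencies
        kls = []
        for pat in data.unique_patterns.astype(float):
            vi = int(pat.astype(int) @ np.array([4, 2, 1]))
            q = dist.conditional_hidden(vi)
            kls.append(np.sum(q * np.log(q / dist.hidden_marginal)))
        mean_kl_bits = float(freqs @ np.array(kls)) / np.log(2)
        # anchoring constant: E_anchor - (-log of the normalizer of exp(-E_h))
        e_unnorm = rt.hidden_marginal_energy(m, dist.hidden_states.astype(float))
        c = rt.codeword_energy_anchor(m) + float(
            np.log(np.exp(-e_unnorm).sum())
        )
        assert prof.I_enc + c / np.log(2) == pytest.approx(mean_kl_bits, abs=1e-8)

    def test_profile_invariant_to_input_order(self):
        m = make_tiny_model(n_hidden=2, n_visible=3, seed=52)
        rng = np.random.default_rng(6)
        vecs = rt.all_binary_states(3)[rng.choice(8, 300)]
        a = rt.energy_entropy_profile(
            m, PatternDataset.from_vectors(vecs), n_bins=3, mode="enumerate", seed=0
        )
        b = rt.energy_entropy_profile(
            m,
            PatternDataset.from_vectors(vecs[rng.permutation(300)]),
            n_bins=3,
            mode="enumerate",
            seed=0,
        )
        assert np.allclose(a.per_bin_mean_entropy, b.per_bin_mean_entropy, equal_nan=True)
        assert a.I_enc == pytest.approx(b.I_enc, abs=1e-12)

    def test_sampled_profile_converges_to_enumerated(self):
        m = make_tiny_model(n_hidden=3, n_visible=3, scale=1.5, seed=53)
        rng = np.random.default_rng(7)
        vecs = rt.all_binary_states(3)[rng.choice(8, 500)]
        data = PatternDataset.from_vectors(vecs)
        ref = rt.energy_entropy_profile(m, data, n_bins=3, mode="enumerate", seed=0)
        errs = []
        for n in (25, 2500):
            prof = rt.energy_entropy_profile(
                m, data, n_bins=3, mode="sample", n_samples=n, seed=1
            )
            errs.append(
                np.abs(
                    prof.table["E_codeword_bits"].to_numpy()
                    - ref.table["E_codeword_bits"].to_numpy()
                ).mean()
            )
        # Monte-Carlo error shrinks roughly as 1/sqrt(n): 100x samples
        # should cut the mean error several-fold
        assert errs[1] < errs[0] / 3
        assert errs[1] < 0.05


class TestSlopeVsModelSize:
    def test_single_profile_onset_flags(self):
        m = rt.ModelParams.zeros(2, 3)
        rng = np.random.default_rng(8)
        data = PatternDataset.from_vectors(rt.all_binary_states(3)[rng.choice(8, 200)])
        prof = rt.energy_entropy_profile(m, data, n_bins=3, mode="enumerate", seed=0)
        st = rt.slope_vs_model_size({2: prof})
        assert st.suppression_onset is None  # zero slope is not negative
        assert list(st.table["n_hidden"]) == [2]

    def test_entropy_slope_crosses_negative_with_size(self, model_family):
        """Variability suppression emerges: the entropy-vs-E_v slope is
        positive for small hidden layers and negative for large ones."""
        for T, members in model_family.items():
            slopes = [m.profile.slope_entropy_vs_Ev for m in members]
            assert slopes[0] >= 0
            assert slopes[-1] < 0
            crossed = np.where(np.array(slopes) < 0)[0]
            # once negative, stays negative
            assert np.all(np.array(slopes)[crossed[0]:] < 0)

    def test_criticality_onset_decreases_with_temperature(self, model_family):
        """The hidden-layer size at which the energy-entropy slope reaches
        the 1:1 band is smaller for hotter (less structured) training data;
        an onset never reached counts as larger than any finite size."""
        onsets = {}
        for T, members in model_family.items():
            st = rt.slope_vs_model_size(
                {m.n_hidden: m.profile for m in members}, slope_tolerance=0.15
            )
            onsets[T] = st.criticality_onset
        assert onsets[3.5] is not None
        assert onsets[2.5] is None or onsets[3.5] <= onsets[2.5]


class TestRankFrequency:
    def test_uniform_distribution_slope_zero(self):
        vecs = np.repeat(rt.all_binary_states(4), 20, axis=0)
        rf = rt.rank_frequency(PatternDataset.from_vectors(vecs))
        assert rf.slope == pytest.approx(0.0, abs=1e-12)

    def test_inverse_rank_distribution_slope_minus_one(self):
        counts = np.round(100_000 / np.arange(1, 101)).astype(int)
        vecs = np.repeat(rt.all_binary_states(7)[:100], counts, axis=0)
        rf = rt.rank_frequency(PatternDataset.from_vectors(vecs))
        assert rf.slope == pytest.approx(-1.0, abs=0.01)

    def test_too_few_patterns_reports_missing(self):
        vecs = np.repeat(rt.all_binary_states(2), 10, axis=0)
        rf = rt.rank_frequency(PatternDataset.from_vectors(vecs))
        assert np.isnan(rf.slope)

    def test_large_model_closer_to_zipf_than_small(self, model_family):
        """Codeword statistics of the well-sized model lie nearer the
        rank-frequency slope -1 than those of the undersized model."""
        for T, members in model_family.items():
            small = members[0].zipf_slope
            large = members[-1].zipf_slope
            assert abs(large + 1) < abs(small + 1)


class TestFitQualityTrends:
    def test_heldout_kl_non_increasing_then_flat(self, model_family):
        """Fit quality improves with size then saturates; increases beyond
        0.01 bits count as inversions and at most one is allowed."""
        kls = [m.kl_bits for m in model_family[2.5]]
        inversions = int(np.sum(np.diff(kls) > 0.01))
        assert inversions <= 1
        assert kls[-1] < kls[0]

    def test_sparsity_and_correlation_decrease_with_size(self, model_family):
        for T, members in model_family.items():
            sp = [m.sparsity for m in members]
            co = [m.mean_abs_correlation for m in members]
            assert int(np.sum(np.diff(sp) > 0)) <= 1
            assert int(np.sum(np.diff(co) > 0)) <= 1
            assert sp[-1] < sp[0]
            assert co[-1] < co[0]
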