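"""Ploidy-effect calling, FDR, conservation and factor-dissection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ploidypheno.effects import (
    _ttest_matrix,
    bh_fdr,
    conserved_effects,
    fraction_significant_environments,
    haploid_score,
    mat_dependence_call,
    mat_dependence_table,
    per_strain_effect_matrix,
    ploidy_effect_table,
    size_dependence_call,
    ttest_homoscedastic,
)
from ploidypheno.synthetic import simulate_trait_dataset


def meta_for(mat, species="cerevisiae"):
    return pd.DataFrame(
        {"strain_id": sorted({i[0] for i in mat.index}), "species": species}
    )


class TestHaploidScore:
    def test_mean_of_mating_type_means(self):
        score, flags = haploid_score([1.0, 1.0], [3.0, 3.0])
        assert score == 2.0 and flags == ()

    def test_identical_replicates(self):
        score, _ = haploid_score([0.7, 0.7], [0.7])
        assert score == pytest.approx(0.7)

    def test_single_mating_type_flagged(self):
        score, flags = haploid_score([], [2.5, 3.5])
        assert score == 3.0
        assert "single_mating_type" in flags

    def test_both_missing(self):
        score, flags = haploid_score([], [np.nan])
        assert np.isnan(score) and "missing" in flags


class TestTTest:
    def test_identical_samples(self):
        res = ttest_homoscedastic([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        """Textbook pooled-t on a small perturbed example."""
        x = np.array([0.0, 0.01])
        y = np.array([1.0, 0.99])
        res = ttest_homoscedastic(x, y)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
        t_manual = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        p_manual = 2 * stats.t.sf(abs(t_manual), 2)
        assert res.t == pytest.approx(t_manual)
        assert res.p == pytest.approx(p_manual)

    def test_degenerate_zero_variance(self):
        res = ttest_homoscedastic([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate and res.p == 0.0
        res2 = ttest_homoscedastic([1.0, 1.0], [1.0, 1.0])
        assert res2.degenerate and res2.p == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_homoscedastic([1.0], [1.0, 2.0])

    def test_matrix_path_matches_scipy(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 40))
        Y = rng.standard_normal((6, 40)) + 0.3
        X[rng.random(X.shape) < 0.1] = np.nan
        t, p, nx, ny = _ttest_matrix(X, Y)
        for j in range(40):
            x = X[~np.isnan(X[:, j]), j]
            y = Y[:, j]
            ref = stats.ttest_ind(x, y, equal_var=True)
            assert t[j] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[j] == pytest.approx(ref.pvalue, rel=1e-10)


def bh_oracle(p, alpha=0.05):
    """Literal step-up definition, for cross-checking."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    sorted_q = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(sorted_q, 1.0)
    return q, reject


class TestBhFdr:
    def test_spec_example(self):
        q, rej = bh_fdr([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert list(rej) == [True, True, True, False]

    def test_all_ones(self):
        q, rej = bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_single_p(self):
        q, rej = bh_fdr([0.04], alpha=0.05)
        assert rej[0] and q[0] == pytest.approx(0.04)

    def test_empty(self):
        q, rej = bh_fdr([])
        assert q.size == 0 and rej.size == 0

    def test_nan_handling(self):
        q, rej = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not rej[1]
        assert rej[0]

    def test_against_oracle_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            m = int(rng.integers(1, 7))
            p = np.round(rng.random(m), 3)
            q, rej = bh_fdr(p, alpha=0.05)
            q0, rej0 = bh_oracle(p, alpha=0.05)
            np.testing.assert_array_equal(rej, rej0)
            np.testing.assert_allclose(q, q0, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=80)
    def test_q_monotone_in_p(self, p):
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


class TestPloidyEffectTable:
    def test_identical_ploidies_zero_effects(self):
        mat = simulate_trait_dataset(6, 9, sigma_noise=0.0, seed=0)
        rec = ploidy_effect_table(mat, meta_for(mat))
        np.testing.assert_allclose(rec["effect"], 0.0, atol=1e-12)
        assert not rec["significant"].any()

    def test_effect_antisymmetry(self):
        """Swapping ploidy labels negates effects, keeps p-values."""
        mat = simulate_trait_dataset(8, 12, deltas=np.full(12, 0.4), seed=1)
        rec = ploidy_effect_table(mat, meta_for(mat))
        swapped = mat.copy()
        idx = swapped.index.to_frame()
        idx["ploidy"] = idx["ploidy"].map({"haploid": "diploid", "diploid": "haploid"})
        idx["mating_type"] = idx["mating_type"].map(
            {"a": "a_alpha", "alpha": "a_alpha", "a_alpha": "a"}
        )
        swapped.index = pd.MultiIndex.from_frame(idx)
        swapped = swapped.groupby(level=[0, 1, 2]).mean()
        rec2 = ploidy_effect_table(swapped, meta_for(mat))
        merged = rec.merge(rec2, on=["environment", "component"], suffixes=("", "_sw"))
        np.testing.assert_allclose(merged["effect"], -merged["effect_sw"], atol=1e-9)

    def test_planted_effects_recovered(self):
        deltas = np.zeros(30)
        deltas[:3] = 0.5
        mat = simulate_trait_dataset(24, 30, deltas=deltas, seed=3)
        rec = ploidy_effect_table(mat, meta_for(mat))
        sig = rec["significant"].to_numpy()
        assert sig[:3].all()
        assert sig[3:].sum() <= 2

    def test_effect_sign_matches_planted_direction(self):
        deltas = np.concatenate([np.full(5, 1.0), np.full(5, -1.0)])
        mat = simulate_trait_dataset(12, 10, deltas=deltas, sigma_noise=0.01, seed=4)
        rec = ploidy_effect_table(mat, meta_for(mat))
        assert (rec["effect"].to_numpy()[:5] > 0).all()
        assert (rec["effect"].to_numpy()[5:] < 0).all()


class TestConservation:
    def _records(self, sig_c, sig_p, eff_c, eff_p):
        rows = []
        for sp, sig, eff in (("cerevisiae", sig_c, eff_c), ("paradoxus", sig_p, eff_p)):
            rows.append(
                dict(species=sp, environment="e1", component="rate",
                     effect=eff, p=0.01 if sig else 0.8, q=0.01 if sig else 0.9,
                     significant=sig)
            )
        return pd.DataFrame(rows)

    def test_same_sign_both_significant(self):
        out = conserved_effects(self._records(True, True, 0.5, 0.3))
        assert out["conserved"].iloc[0]
        assert out["classification"].iloc[0] == "both"

    def test_opposite_signs_not_conserved(self):
        out = conserved_effects(self._records(True, True, 0.5, -0.3))
        assert not out["conserved"].iloc[0]

    def test_one_species_missing_unclassified(self):
        rec = self._records(True, True, 0.5, 0.3)
        rec.loc[rec.species == "paradoxus", "p"] = np.nan
        out = conserved_effects(rec)
        assert out["classification"].iloc[0] == "unclassified"

    def test_generator_high_conservation_limit(self):
        """rho=1, large effects, low noise: conservation fraction -> 1."""
        deltas = np.full(20, 1.0)
        parts = []
        for sp in ("cerevisiae", "paradoxus"):
            mat = simulate_trait_dataset(
                12, 20, deltas=deltas, sigma_noise=0.02, seed=8, species=sp
            )
            parts.append(ploidy_effect_table(mat, meta_for(mat, species=sp)))
        out = conserved_effects(pd.concat(parts, ignore_index=True))
        assert out["conserved"].mean() == 1.0


class TestFractionSignificant:
    def _rec(self, env, comp, sig):
        return dict(species="cerevisiae", environment=env, component=comp,
                    significant=sig)

    def test_none_significant(self):
        rec = pd.DataFrame([self._rec("e1", "rate", False)])
        assert fraction_significant_environments(rec) == 0.0

    def test_all_significant(self):
        rec = pd.DataFrame([self._rec(f"e{i}", "rate", True) for i in range(5)])
        assert fraction_significant_environments(rec) == 1.0

    def test_any_vs_all_modes(self):
        rec = pd.DataFrame(
            [self._rec("e1", "rate", True), self._rec("e1", "lag", False),
             self._rec("e1", "efficiency", False),
             self._rec("e2", "rate", True), self._rec("e2", "lag", True),
             self._rec("e2", "efficiency", True)]
        )
        assert fraction_significant_environments(rec, mode="any") == 1.0
        assert fraction_significant_environments(rec, mode="all") == 0.5

    def test_planted_fraction(self):
        """7 of 10 environments planted with strong effects -> 0.7."""
        deltas = np.zeros(30)  # 10 environments x 3 components
        for env_idx in range(7):
            deltas[env_idx * 3 : env_idx * 3 + 3] = 1.2
        mat = simulate_trait_dataset(24, 30, deltas=deltas, seed=9)
        rec = ploidy_effect_table(mat, meta_for(mat))
        frac = fraction_significant_environments(rec)
        assert frac == pytest.approx(0.7, abs=0.10)


class TestSizeDependence:
    def _groups(self, eff_h, eff_d, n=6, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        mk = lambda shift: rng.normal(shift, noise, size=n)
        return mk(eff_h), mk(0.0), mk(eff_d), mk(0.0)

    def test_both_significant_same_sign_positive(self):
        hl, hs, dl, ds = self._groups(1.0, 1.0)
        out = size_dependence_call(hl, hs, dl, ds)
        assert out["positive_call"] and out["direction"] == 1.0

    def test_only_haploid_significant_negative(self):
        hl, hs, dl, ds = self._groups(1.0, 0.0)
        out = size_dependence_call(hl, hs, dl, ds)
        assert not out["positive_call"]

    def test_opposite_signs_negative(self):
        hl, hs, dl, ds = self._groups(1.0, -1.0)
        out = size_dependence_call(hl, hs, dl, ds)
        assert out["significant_haploid"] and out["significant_diploid"]
        assert not out["positive_call"]


class TestMatDependence:
    def test_all_identical_negative(self):
        v = np.array([0.5, 0.5, 0.5, 0.5])
        out = mat_dependence_call(v, v, v)
        assert not out["positive_call"]

    def test_single_shifted_hemizygote_positive(self):
        rng = np.random.default_rng(1)
        het = rng.normal(0, 0.05, 4)
        hemi_a = rng.normal(0, 0.05, 4)
        hemi_alpha = rng.normal(1.5, 0.05, 4)  # only alpha shifted
        out = mat_dependence_call(hemi_a, hemi_alpha, het)
        assert out["positive_call"]
        assert not out["significant_hemi_a"]
        assert out["significant_hemi_alpha"]

    def test_no_hemizygote_rejected(self):
        with pytest.raises(ValueError):
            mat_dependence_call(None, None, [0.1, 0.2, 0.3])

    def test_planted_shift_power_matches_analytic(self):
        """Detection power of a 3-sigma hemizygote shift at n=4.

        The analytic oracle: the shifted comparison's p follows a
        noncentral-t law (df=6, ncp = 3/sqrt(1/2)); the other hemizygote's
        p is uniform; the BH step-up over the two comparisons rejects both
        if both p <= alpha, else the smaller if it is <= alpha/2. The
        simulated positive-call rate must match this closed form within
        Monte-Carlo error, and the call is usefully powered (> 0.75).
        """
        df, ncp, alpha = 6, 3 / np.sqrt(0.5), 0.05

        def p_le(thr):
            tcrit = stats.t.isf(thr / 2, df)
            return stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)

        pa_half, pa_full = p_le(alpha / 2), p_le(alpha)
        analytic = (
            pa_half
            + (pa_full - pa_half) * alpha
            + (1 - pa_full) * alpha / 2
        )
        rng = np.random.default_rng(2)
        sigma = 0.1
        n_rep = 300
        hits = 0
        for _ in range(n_rep):
            het = rng.normal(0, sigma, 4)
            ha = rng.normal(3 * sigma, sigma, 4)
            hal = rng.normal(0, sigma, 4)
            hits += bool(mat_dependence_call(ha, hal, het)["positive_call"])
        power = hits / n_rep
        se = np.sqrt(analytic * (1 - analytic) / n_rep)
        assert power == pytest.approx(analytic, abs=3.5 * se)
        assert power > 0.75

    def test_planted_fraction_of_traits(self):
        """Effects planted in 3 of 24 traits give a 12.5% positive-call rate."""
        rng = np.random.default_rng(3)
        sigma = 0.1
        cols = pd.MultiIndex.from_tuples([(f"e{j}", "rate") for j in range(24)])
        het = pd.DataFrame(rng.normal(0, sigma, (4, 24)), columns=cols)
        ha = pd.DataFrame(rng.normal(0, sigma, (4, 24)), columns=cols)
        hal = pd.DataFrame(rng.normal(0, sigma, (4, 24)), columns=cols)
        for j in range(3):
            ha.iloc[:, j] += 6 * sigma
        table = mat_dependence_table(ha, hal, het)
        assert table["positive_call"].mean() == pytest.approx(3 / 24, abs=1 / 24)


class TestPerStrainEffectMatrix:
    def test_haploid_minus_diploid(self):
        mat = simulate_trait_dataset(5, 6, deltas=np.full(6, 0.8), sigma_noise=0.0, seed=0)
        em = per_strain_effect_matrix(mat)
        np.testing.assert_allclose(em.to_numpy(), 0.8, atol=1e-12)
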