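"""Scoring, logistic association, AUC/DeLong, quantile ORs and power."""

import math

import numpy as np
import pandas as pd
import pytest

from prstune.containers import GenotypeDataset, WeightVector
from prstune.evaluate import (
    auc,
    delong_test,
    evaluate_prs,
    logistic_fit,
    prevalence_percent,
    prs_power,
    quantile_contrast,
    score,
)
from prstune.harmonize import harmonize
from prstune.weights import pt_weights


def _weights(ids, alleles, w):
    return WeightVector(table=pd.DataFrame({
        "variant_id": ids, "counted_allele": alleles, "weight": w,
    }))


def _dataset(dosages, alts=None):
    n, m = np.asarray(dosages).shape
    tab = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)], "chr": "1",
        "pos": np.arange(1, m + 1) * 1000, "ref": "A",
        "alt": alts if alts is not None else ["G"] * m, "info_score": 1.0,
    })
    return GenotypeDataset(
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        variants=tab, dosages=np.asarray(dosages, dtype=float),
    )


def naive_score(dosages, weights, flip_mask):
    n, m = dosages.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            d = dosages[i, j]
            if np.isnan(d):
                d = np.nanmean(dosages[:, j])
            if flip_mask[j]:
                d = 2.0 - d
            out[i] += weights[j] * d
    return out


class TestScore:
    FIXTURE = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 0.0, 1.0],
        [2.0, 2.0, 0.0],
        [1.0, 1.0, 1.0],
    ])

    def test_matches_naive_double_loop(self):
        ds = _dataset(self.FIXTURE)
        w = _weights(["v0", "v1", "v2"], ["G", "G", "G"], [0.5, -0.25, 0.1])
        res = score(ds, w)
        oracle = naive_score(self.FIXTURE, [0.5, -0.25, 0.1], [False] * 3)
        assert np.allclose(res.scores, oracle)
        assert res.coverage == 1.0

    def test_all_zero_weights_give_zero_scores(self):
        ds = _dataset(self.FIXTURE)
        w = _weights(["v0", "v1", "v2"], ["G"] * 3, [0.0] * 3)
        assert np.all(score(ds, w).scores == 0.0)

    def test_single_unit_weight_returns_dosage(self):
        ds = _dataset(self.FIXTURE)
        w = _weights(["v1"], ["G"], [1.0])
        assert np.allclose(score(ds, w).scores, self.FIXTURE[:, 1])

    def test_reference_allele_weight_uses_complementary_dosage(self):
        ds = _dataset(self.FIXTURE)
        w = _weights(["v0"], ["A"], [1.0])  # counted allele is the ref
        assert np.allclose(score(ds, w).scores, 2.0 - self.FIXTURE[:, 0])

    def test_missing_dosages_mean_imputed(self):
        dos = self.FIXTURE.copy()
        dos[0, 0] = np.nan
        ds = _dataset(dos)
        w = _weights(["v0"], ["G"], [1.0])
        expected = naive_score(dos[:, :1], [1.0], [False])
        assert np.allclose(score(ds, w).scores, expected)

    def test_partial_coverage_reported(self):
        ds = _dataset(self.FIXTURE)
        w = _weights(["v0", "missing1"], ["G", "G"], [1.0, 1.0])
        res = score(ds, w)
        assert res.coverage == 0.5 and res.n_matched == 1

    def test_standardize_flag(self):
        ds = _dataset(self.FIXTURE)
        w = _weights(["v0", "v1"], ["G", "G"], [1.0, 0.5])
        s = score(ds, w, standardize=True).scores
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.std() == pytest.approx(1.0, abs=1e-12)


class TestAlleleFlipInvariance:
    def test_flipping_counted_allele_leaves_prs_unchanged(self, study):
        """Recoding a dataset variant to count the opposite allele
        (dosage -> 2 - dosage, ref/alt swapped) must not change any PRS
        after harmonization."""
        harm = harmonize(study.summary_stats, study.target)
        idx = harm.dataset_indices[:10]
        wv = pt_weights(harm, list(harm.table["variant_id"]), p_threshold=1.0)
        base = score(study.target, wv).scores

        flipped = GenotypeDataset(
            sample_ids=study.target.sample_ids,
            variants=study.target.variants.copy(),
            dosages=study.target.dosages.copy(),
        )
        for j in idx:
            flipped.dosages[:, j] = 2.0 - flipped.dosages[:, j]
            r, a = flipped.variants.at[j, "ref"], flipped.variants.at[j, "alt"]
            flipped.variants.at[j, "ref"], flipped.variants.at[j, "alt"] = a, r
        harm2 = harmonize(study.summary_stats, flipped)
        wv2 = pt_weights(harm2, list(harm2.table["variant_id"]), p_threshold=1.0)
        flipped_scores = score(flipped, wv2).scores
        # scores may differ by the constant 2*sum(flipped weights)
        assert np.allclose(flipped_scores - flipped_scores.mean(),
                           base - base.mean(), atol=1e-10)
        y = study.target_status
        assert auc(y, flipped_scores) == pytest.approx(auc(y, base), abs=1e-12)


class TestLogisticFit:
    def test_two_by_two_matches_cross_product_ratio(self):
        y = np.array([1] * 30 + [0] * 20 + [1] * 30 + [0] * 70)
        x = np.array([1.0] * 50 + [0.0] * 100)
        fit = logistic_fit(y, x)
        assert fit.beta == pytest.approx(math.log(3.5), abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        p = 1.0 / (1.0 + np.exp(-(-0.3 + 0.5 * x)))
        y = (rng.random(5000) < p).astype(int)
        fit = logistic_fit(y, x)
        assert abs(fit.beta - 0.5) < 3 * fit.se

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            y = rng.integers(0, 2, 120)
            x = rng.normal(size=120)
            pvals.append(logistic_fit(y, x).p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_perfect_separation_flagged(self):
        y = np.array([0] * 20 + [1] * 20)
        x = np.concatenate([np.arange(20.0), 100 + np.arange(20.0)])
        fit = logistic_fit(y, x)
        assert fit.separation and np.isinf(fit.beta)

    def test_beta_scales_with_score_sd(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000) * 3.7 + 1.2
        p = 1.0 / (1.0 + np.exp(-0.4 * (x - 1.2) / 3.7))
        y = (rng.random(2000) < p).astype(int)
        raw = logistic_fit(y, x)
        std = logistic_fit(y, (x - x.mean()) / x.std())
        assert std.beta == pytest.approx(raw.beta * x.std(), abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            logistic_fit(np.r_[np.zeros(5), np.ones(5)], np.ones(10))


def exhaustive_auc(status, x):
    """O(cases x controls) pairwise enumeration oracle."""
    cases = x[status == 1]
    controls = x[status == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_perfect_separation_is_one(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        assert auc(y, np.array([1.0, 2, 3, 4, 5, 6])) == 1.0

    def test_constant_score_is_half(self):
        y = np.array([0, 0, 1, 1])
        assert auc(y, np.ones(4)) == 0.5

    def test_tie_fixture_matches_exhaustive_enumeration(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([3.0, 2.0, 1.0, 2.0, 1.0, 0.0])  # ties across classes
        assert auc(y, x) == pytest.approx(exhaustive_auc(y, x), abs=1e-15)

    def test_negation_identity_without_ties(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        x = rng.permutation(np.arange(80.0))
        assert auc(y, x) == pytest.approx(1.0 - auc(y, -x), abs=1e-15)

    def test_one_class_absent_is_an_error(self):
        with pytest.raises(ValueError):
            auc(np.ones(5, dtype=int), np.arange(5.0))


def slow_delong_variance(status, xa, xb):
    """O(n^2) placement-value reference for the DeLong covariance."""
    y = np.asarray(status).astype(bool)
    a_cases, a_controls = xa[y], xa[~y]
    b_cases, b_controls = xb[y], xb[~y]
    m, n = len(a_cases), len(a_controls)

    def psi(c, d):
        return 1.0 if c > d else (0.5 if c == d else 0.0)

    v10 = np.zeros((2, m))
    v01 = np.zeros((2, n))
    for i in range(m):
        v10[0, i] = np.mean([psi(a_cases[i], d) for d in a_controls])
        v10[1, i] = np.mean([psi(b_cases[i], d) for d in b_controls])
    for j in range(n):
        v01[0, j] = np.mean([psi(c, a_controls[j]) for c in a_cases])
        v01[1, j] = np.mean([psi(c, b_controls[j]) for c in b_cases])
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    cov = s10 / m + s01 / n
    return cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]


class TestDelong:
    def test_identical_scores_degenerate(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        x = rng.normal(size=50)
        res = delong_test(x, x, y)
        assert res.degenerate and res.p == 1.0 and res.delta == 0.0

    def test_variance_matches_quadratic_reference(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        xa = rng.normal(size=100) + 0.5 * y
        xb = rng.normal(size=100) + 0.3 * y
        res = delong_test(xa, xb, y)
        oracle = slow_delong_variance(y, xa, xb)
        assert res.variance == pytest.approx(oracle, abs=1e-10)

    def test_tiny_perturbation_gives_small_delta_and_valid_p(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200)
        x = rng.normal(size=200)
        res = delong_test(x, x + rng.normal(scale=1e-9, size=200), y)
        assert abs(res.delta) < 1e-6
        assert 0.0 <= res.p <= 1.0


class TestQuantileContrast:
    def test_two_by_two_cross_product(self):
        status = np.array([1] * 30 + [0] * 20 + [1] * 30 + [0] * 70)
        x = np.array([1.0] * 50 + [0.0] * 100)
        qc = quantile_contrast(status, x, top_q=0.25, reference="rest")
        assert qc.odds_ratio == pytest.approx(3.5, abs=1e-6)
        assert qc.ci_low < 3.5 < qc.ci_high

    def test_null_odds_ratio_near_one(self):
        rng = np.random.default_rng(8)
        ors = []
        for _ in range(30):
            y = rng.integers(0, 2, 400)
            x = rng.normal(size=400)
            ors.append(quantile_contrast(y, x).odds_ratio)
        assert np.mean(np.log(ors)) == pytest.approx(0.0, abs=0.12)

    def test_top_vs_bottom_at_least_top_vs_rest_under_monotone_risk(self):
        rng = np.random.default_rng(9)
        wins = 0
        for _ in range(10):
            x = rng.normal(size=600)
            p = 1 / (1 + np.exp(-(x - 0.3)))
            y = (rng.random(600) < p).astype(int)
            top_rest = quantile_contrast(y, x, reference="rest").odds_ratio
            top_bottom = quantile_contrast(y, x, reference="bottom").odds_ratio
            wins += int(top_bottom >= top_rest)
        assert wins >= 8

    def test_sparse_cell_uses_continuity_correction(self):
        y = np.array([0] * 75 + [1] * 25)
        x = np.arange(100.0)
        qc = quantile_contrast(y, x, top_q=0.25)
        assert qc.sparse_correction and np.isfinite(qc.odds_ratio)


class TestPower:
    def test_null_r2_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            assert prs_power(0.0, 100, 100, alpha) == pytest.approx(alpha, abs=1e-12)

    def test_strong_signal_is_fully_powered(self):
        # 20% variance explained in an 832-sample cohort
        assert prs_power(0.2, 301, 531, 0.05) > 0.999

    def test_monotone_in_r2_n_alpha(self):
        p1 = [prs_power(r2, 200, 200, 0.05) for r2 in (0.01, 0.05, 0.1)]
        assert p1[0] < p1[1] < p1[2]
        p2 = [prs_power(0.02, n, n, 0.05) for n in (100, 400, 1600)]
        assert p2[0] < p2[1] < p2[2]
        p3 = [prs_power(0.02, 200, 200, a) for a in (0.01, 0.05, 0.2)]
        assert p3[0] < p3[1] < p3[2]

    def test_harmonic_effective_size_reduces_power_when_unbalanced(self):
        bal = prs_power(0.05, 500, 500, harmonic_neff=True)
        unbal = prs_power(0.05, 50, 950, harmonic_neff=True)
        assert unbal < bal

    def test_prevalence_arithmetic(self):
        assert prevalence_percent(301, 832) == 36.2
        assert prevalence_percent(52, 2386) == 2.2
        with pytest.raises(ValueError):
            prevalence_percent(5, 0)


class TestEvaluatePrs:
    def test_summary_bundle(self, study):
        rng = np.random.default_rng(10)
        prs = study.target.dosages @ rng.normal(size=study.target.n_variants)
        ev = evaluate_prs(study.target_status, prs)
        assert 0.0 <= ev.auc <= 1.0
        assert ev.n_cases + ev.n_controls == study.target.n_samples
        assert len(ev.quantile_contrasts) == 2
        row = ev.summary_row()
        assert set(row) >= {"beta", "se", "p", "auc", "coverage"}
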