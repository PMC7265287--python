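"""Scoring and association machinery: PRS computation, logistic association,
Mann-Whitney AUC, the DeLong test for correlated ROC curves, quantile odds
ratios and a one-stage PRS power calculation."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats as sps

from .containers import GenotypeDataset, WeightVector


# ---------------------------------------------------------------------------
# scoring

@dataclass
class ScoreResult:
    """Per-sample scores plus the fraction of weight variants found."""

    scores: np.ndarray
    coverage: float
    n_matched: int

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.scores, dtype=dtype)


def score(
    ds: GenotypeDataset,
    weights: WeightVector,
    standardize: bool = False,
) -> ScoreResult:
    """Weighted allele-dosage sum per sample.

    Weight variants are matched by id; where the weight's counted allele is
    the dataset reference allele the complementary dosage (2 - d) is used.
    Missing dosages are mean-imputed per variant. Weight variants absent
    from the dataset are skipped and reported through ``coverage`` (a
    replication run warns when coverage drops below 0.98).
    """
    lookup = {v: j for j, v in enumerate(ds.variants["variant_id"])}
    wt = weights.table
    cols, wvals, flip = [], [], []
    for vid, allele, w in zip(wt["variant_id"], wt["counted_allele"], wt["weight"]):
        j = lookup.get(vid)
        if j is None:
            continue
        ref, alt = ds.variants.at[j, "ref"], ds.variants.at[j, "alt"]
        if allele == alt:
            flip.append(False)
        elif allele == ref:
            flip.append(True)
        else:
            continue  # allele mismatch: cannot count this variant
        cols.append(j)
        wvals.append(w)
    n_matched = len(cols)
    if len(wt) and n_matched == 0:
        raise ValueError("no weight variants found in the dataset")
    coverage = n_matched / len(wt) if len(wt) else 1.0
    if not cols:
        s = np.zeros(ds.n_samples)
    else:
        d = ds.dosages[:, cols].copy()
        mean = np.nanmean(d, axis=0)
        nan_mask = np.isnan(d)
        if nan_mask.any():
            d[nan_mask] = np.take(mean, np.where(nan_mask)[1])
        flip = np.asarray(flip)
        if flip.any():
            d[:, flip] = 2.0 - d[:, flip]
        s = d @ np.asarray(wvals)
    if standardize:
        sd = s.std()
        s = (s - s.mean()) / sd if sd > 0 else s - s.mean()
    return ScoreResult(scores=s, coverage=coverage, n_matched=n_matched)


# ---------------------------------------------------------------------------
# logistic association

@dataclass
class LogisticFit:
    beta: float
    se: float
    p: float
    converged: bool = True
    separation: bool = False


def logistic_fit(status: np.ndarray, x: np.ndarray) -> LogisticFit:
    """Univariate logistic regression of case status on a score (ML fit).

    Wald SE and two-sided P for the slope. Perfect separation is flagged
    and reported with an infinite-beta sentinel instead of raising.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(status, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both case and control classes must be present")
    if x.std() == 0:
        raise ValueError("score is constant; logistic slope undefined")
    # detect perfect separation up front: the ML slope is then unbounded
    if x[y == 1].min() > x[y == 0].max():
        return LogisticFit(beta=math.inf, se=math.inf, p=0.0,
                           converged=False, separation=True)
    if x[y == 1].max() < x[y == 0].min():
        return LogisticFit(beta=-math.inf, se=math.inf, p=0.0,
                           converged=False, separation=True)
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-10)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            sign = 1.0 if np.corrcoef(x, y)[0, 1] >= 0 else -1.0
            return LogisticFit(beta=sign * math.inf, se=math.inf, p=0.0,
                               converged=False, separation=True)
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if not np.isfinite(se) or se > 1e6:
        return LogisticFit(beta=beta, se=math.inf, p=1.0,
                           converged=False, separation=True)
    return LogisticFit(beta=beta, se=se, p=float(fit.pvalues[1]),
                       converged=bool(fit.mle_retvals.get("converged", True)))


# ---------------------------------------------------------------------------
# AUC and the DeLong test

def _placements(status: np.ndarray, x: np.ndarray):
    """Midrank placement values V10 (cases) and V01 (controls), plus AUC."""
    y = np.asarray(status).astype(bool)
    x = np.asarray(x, dtype=float)
    cases, controls = x[y], x[~y]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("both case and control classes must be present")
    allx = np.concatenate([cases, controls])
    ranks = sps.rankdata(allx)  # midranks handle ties with the 1/2 convention
    r_cases, r_controls = ranks[:m], ranks[m:]
    rank_in_cases = sps.rankdata(cases)
    rank_in_controls = sps.rankdata(controls)
    auc_val = (r_cases.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_cases - rank_in_cases) / n            # P(control < case) per case
    v01 = 1.0 - (r_controls - rank_in_controls) / m  # per control
    return auc_val, v10, v01


def auc(status: np.ndarray, x: np.ndarray, return_se: bool = False):
    """Mann-Whitney AUC: P(case score > control score) + 1/2 P(tie).

    With ``return_se`` the DeLong structural-components standard error is
    returned as well.
    """
    a, v10, v01 = _placements(status, x)
    if not return_se:
        return a
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) \
        + (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    return a, math.sqrt(max(var, 0.0))


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p: float
    degenerate: bool = False


def delong_test(score_a: np.ndarray, score_b: np.ndarray, status: np.ndarray) -> DelongResult:
    """DeLong's test for two correlated ROC curves on the same samples.

    Uses the structural-components (placement-value) estimator of the 2x2
    covariance of the two AUCs; z = dAUC / sqrt(var), two-sided normal P.
    Zero estimated variance (e.g. identical scores) yields p = 1 with the
    degenerate flag set.
    """
    if len(score_a) != len(score_b) or len(score_a) != len(status):
        raise ValueError("scores and status must share samples")
    auc_a, v10_a, v01_a = _placements(status, score_a)
    auc_b, v10_b, v01_b = _placements(status, score_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    delta = auc_a - auc_b
    if var <= 0:
        return DelongResult(auc_a, auc_b, delta, 0.0, 0.0, 1.0, degenerate=True)
    z = delta / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, delta, var, z, min(p, 1.0))


# ---------------------------------------------------------------------------
# quantile contrasts

@dataclass
class QuantileContrast:
    definition: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_high: int
    n_reference: int
    sparse_correction: bool = False


def quantile_contrast(
    status: np.ndarray,
    x: np.ndarray,
    top_q: float = 0.25,
    reference: str = "rest",
) -> QuantileContrast:
    """Odds ratio of case status for top-quantile score membership.

    "Top 25%" means score >= the empirical 75th percentile (inclusive,
    lower-interpolation quantile). ``reference`` is ``"rest"`` (everyone
    else) or ``"bottom"`` (the mirrored bottom quantile). An empty 2x2 cell
    falls back to the add-1/2 (median-unbiased) correction with a flag.
    """
    if reference not in ("rest", "bottom"):
        raise ValueError("reference must be 'rest' or 'bottom'")
    y = np.asarray(status, dtype=int)
    x = np.asarray(x, dtype=float)
    hi_thr = np.quantile(x, 1.0 - top_q, method="lower")
    high = x >= hi_thr
    if reference == "rest":
        ref = ~high
        definition = f"top {top_q:.0%} vs remaining {1 - top_q:.0%}"
    else:
        lo_thr = np.quantile(x, top_q, method="lower")
        ref = x <= lo_thr
        ref &= ~high
        definition = f"top {top_q:.0%} vs lowest {top_q:.0%}"
    if not high.any() or not ref.any():
        raise ValueError("both contrast groups must be non-empty")
    sel = high | ref
    ys, hs = y[sel], high[sel].astype(float)
    a = int(((ys == 1) & (hs == 1)).sum())  # case, high
    b = int(((ys == 0) & (hs == 1)).sum())
    c = int(((ys == 1) & (hs == 0)).sum())
    d = int(((ys == 0) & (hs == 0)).sum())
    if min(a, b, c, d) == 0:
        # sparse table: Haldane-Anscombe correction on the 2x2
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        se = math.sqrt(sum(1.0 / (k + 0.5) for k in (a, b, c, d)))
        z = math.log(orr) / se
        return QuantileContrast(
            definition, orr, math.exp(math.log(orr) - 1.959963984540054 * se),
            math.exp(math.log(orr) + 1.959963984540054 * se),
            2.0 * sps.norm.sf(abs(z)), int(high.sum()), int(ref.sum()),
            sparse_correction=True,
        )
    fit = logistic_fit(ys, hs)
    zq = 1.959963984540054
    return QuantileContrast(
        definition, math.exp(fit.beta),
        math.exp(fit.beta - zq * fit.se), math.exp(fit.beta + zq * fit.se),
        fit.p, int(high.sum()), int(ref.sum()),
    )


# ---------------------------------------------------------------------------
# power

def prs_power(
    variance_explained: float,
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
    harmonic_neff: bool = False,
) -> float:
    """One-stage power of the PRS association test.

    Non-centrality lambda = N_eff * R2 / (1 - R2) on a 1-df chi-square;
    ``harmonic_neff`` replaces the total sample count with the harmonic-mean
    case-control effective size 4 / (1/n_cases + 1/n_controls).
    """
    r2 = variance_explained
    if not (0 <= r2 < 1):
        raise ValueError("variance_explained must lie in [0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls) if harmonic_neff \
        else float(n_cases + n_controls)
    crit = sps.chi2.ppf(1.0 - alpha, df=1)
    lam = n_eff * r2 / (1.0 - r2)
    if lam == 0:
        return float(alpha)
    return float(sps.ncx2.sf(crit, df=1, nc=lam))


def prevalence_percent(n_cases: int, n_total: int, digits: int = 1) -> float:
    """Case prevalence as a percentage, rounded as printed in cohort tables."""
    if n_total <= 0 or n_cases < 0 or n_cases > n_total:
        raise ValueError("need 0 <= n_cases <= n_total with n_total > 0")
    return round(100.0 * n_cases / n_total, digits)


# ---------------------------------------------------------------------------
# one-stop evaluation

@dataclass
class PRSEvaluation:
    """Association results for one score against a binary phenotype."""

    beta_per_sd: float
    se: float
    p: float
    auc: float
    auc_se: float
    n_cases: int
    n_controls: int
    quantile_contrasts: List[QuantileContrast] = field(default_factory=list)
    coverage: float = 1.0
    config: Optional[dict] = None

    def summary_row(self) -> dict:
        return {
            "beta": self.beta_per_sd, "se": self.se, "p": self.p,
            "auc": self.auc, "auc_se": self.auc_se,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "coverage": self.coverage,
        }


def evaluate_prs(
    status: np.ndarray,
    prs: np.ndarray,
    top_q: float = 0.25,
    coverage: float = 1.0,
    config: Optional[dict] = None,
    contrasts: bool = True,
) -> PRSEvaluation:
    """Standardize the score, fit the univariate logistic model, compute the
    AUC and (optionally) the quartile odds-ratio contrasts."""
    y = np.asarray(status, dtype=int)
    x = np.asarray(prs, dtype=float)
    sd = x.std()
    xs = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    if sd > 0:
        fit = logistic_fit(y, xs)
    else:  # constant score: no information
        fit = LogisticFit(beta=0.0, se=math.inf, p=1.0, converged=False)
    if sd > 0:
        a, a_se = auc(y, xs, return_se=True)
    else:
        a, a_se = 0.5, 0.0
    qc = []
    if contrasts and sd > 0:
        qc = [
            quantile_contrast(y, xs, top_q=top_q, reference="rest"),
            quantile_contrast(y, xs, top_q=top_q, reference="bottom"),
        ]
    return PRSEvaluation(
        beta_per_sd=fit.beta, se=fit.se, p=fit.p, auc=a, auc_se=a_se,
        n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
        quantile_contrasts=qc, coverage=coverage, config=config,
    )
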