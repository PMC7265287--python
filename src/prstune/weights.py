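"""The three LD-aware PRS weight-estimation methods.

* clumping + thresholding (P+T): greedy selection of the most significant
  variant per LD neighborhood, followed by a P-value filter;
* LDpred-style Bayesian shrinkage: a point-normal prior on standardized
  effects with a Gibbs sweep conditioning on neighbors within an LD radius;
* GraBLD-style calibration: gradient-boosted regression trees predict
  per-variant association magnitudes from summary features, divided by a
  regional LD score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from .containers import WeightVector
from .harmonize import HarmonizedSet
from .ld import LDWindowMatrix


# ---------------------------------------------------------------------------
# clumping + thresholding

@dataclass(frozen=True)
class ClumpParams:
    """Greedy clumping parameters (defaults follow the common tooling)."""

    index_p_cutoff: float = 1.0
    r2_threshold: float = 0.5
    window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.index_p_cutoff <= 1):
            raise ValueError("index_p_cutoff must lie in (0, 1]")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


def clump(stats: HarmonizedSet, ld: LDWindowMatrix, params: ClumpParams) -> list:
    """Greedy LD clumping; returns the index-variant ids.

    Candidates with P <= ``index_p_cutoff`` are visited in order of
    ascending P (ties: ascending position, then lexicographic id); each
    unclaimed candidate becomes an index variant and claims every in-window
    candidate with r^2 >= ``r2_threshold``. Independent of input row order.
    """
    tab = stats.table
    cand = tab[tab["p"] <= params.index_p_cutoff]
    if len(cand) == 0:
        return []
    order = cand.sort_values(
        ["p", "pos", "variant_id"], kind="stable"
    ).index.to_numpy()
    ld_idx = ld.index_of(tab["variant_id"].to_numpy())
    pos = tab["pos"].to_numpy()
    chrom = tab["chr"].to_numpy(dtype=object)
    # map LD-matrix index -> candidate row for fast claiming
    row_of = {int(ld_idx[i]): i for i in order}
    removed = np.zeros(len(tab), dtype=bool)
    radius = params.window_kb * 1000.0
    indices = []
    for i in order:
        if removed[i]:
            continue
        indices.append(tab.at[i, "variant_id"])
        removed[i] = True
        neighbors, rvals = ld.row(int(ld_idx[i]))
        for jj, r in zip(neighbors, rvals):
            k = row_of.get(int(jj))
            if k is None or removed[k]:
                continue
            if chrom[k] != chrom[i] or abs(pos[k] - pos[i]) > radius:
                continue
            if r * r >= params.r2_threshold:
                removed[k] = True
    return indices


def pt_weights(
    stats: HarmonizedSet,
    indices: Sequence[str],
    p_threshold: float,
    provenance: Optional[dict] = None,
) -> WeightVector:
    """P+T weights: the aligned summary beta for index variants with P <= threshold."""
    tab = stats.table
    keep = tab["variant_id"].isin(set(indices)) & (tab["p"] <= p_threshold)
    sub = tab[keep]
    out = pd.DataFrame({
        "variant_id": sub["variant_id"],
        "chr": sub["chr"],
        "pos": sub["pos"],
        "counted_allele": sub["counted_allele"],
        "weight": sub["beta"].astype(float),
    })
    prov = {"method": "PT", "p_threshold": p_threshold}
    prov.update(provenance or {})
    return WeightVector(table=out, provenance=prov)


# ---------------------------------------------------------------------------
# LDpred-style Bayesian point-normal shrinkage

@dataclass(frozen=True)
class LdpredParams:
    """Point-normal Gibbs parameters.

    ``fraction_causal`` is the prior mixing proportion p; ``h2`` the assumed
    liability heritability; ``n`` the effective GWAS sample size (median of
    the per-variant N when omitted); ``ld_radius`` the number of flanking
    variants conditioned on (default round(M / 3000), floor 1).
    """

    fraction_causal: float = 1.0
    h2: float = 0.5
    n: Optional[float] = None
    ld_radius: Optional[int] = None
    iterations: int = 100
    burn_in: int = 20
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.fraction_causal <= 1):
            raise ValueError("fraction_causal must lie in (0, 1]")
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")
        if self.ld_radius is not None and self.ld_radius < 0:
            raise ValueError("ld_radius must be >= 0")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must be < iterations")


def default_ld_radius(n_variants: int) -> int:
    """Recommended per-model LD radius: round(M / 3000), at least 1."""
    return max(1, round(n_variants / 3000))


def standardized_betas(stats: HarmonizedSet, n: np.ndarray) -> np.ndarray:
    """beta_std = z / sqrt(N) with z = beta / se (unit-robust conversion)."""
    tab = stats.table
    z = tab["beta"].to_numpy(dtype=float) / tab["se"].to_numpy(dtype=float)
    return z / np.sqrt(n)


def _band_matrix(stats: HarmonizedSet, ld: LDWindowMatrix, radius: int) -> np.ndarray:
    """Dense (M, 2L+1) band of r between consecutive harmonized variants.

    Column L is the diagonal; pairs outside the LD matrix's window are 0.
    Variants on different chromosomes are never conditioned on each other.
    """
    m = len(stats)
    ld_idx = ld.index_of(stats.table["variant_id"].to_numpy())
    chrom = stats.table["chr"].to_numpy(dtype=object)
    band = np.zeros((m, 2 * radius + 1))
    band[:, radius] = 1.0
    lookup = {int(g): i for i, g in enumerate(ld_idx)}
    for i in range(m):
        neighbors, rvals = ld.row(int(ld_idx[i]))
        for jj, r in zip(neighbors, rvals):
            k = lookup.get(int(jj))
            if k is None or k == i:
                continue
            off = k - i
            if abs(off) <= radius and chrom[k] == chrom[i]:
                band[i, radius + off] = r
    return band


def ldpred_gibbs(
    beta_std: np.ndarray,
    band: np.ndarray,
    params: LdpredParams,
    n: float,
    m_total: Optional[int] = None,
) -> np.ndarray:
    """Posterior-mean standardized weights under the point-normal model.

    Each sweep updates variants in order: the residual marginal effect
    conditional on current neighbors within the radius is scored against the
    two mixture components (causal: N(0, sigma2 + 1/N); null: N(0, 1/N)),
    a causal indicator and effect are sampled, and the output is the average
    of (inclusion probability x conditional mean) over post-burn-in sweeps.

    A divergence guard restarts the chain with the prior variance halved
    whenever the sampled signal variance exceeds 10 x h2.
    """
    m = len(beta_std)
    if band.shape[0] != m or band.shape[1] % 2 != 1:
        raise ValueError("band must be (M, 2L+1)")
    radius = band.shape[1] // 2
    m_eff = m_total if m_total is not None else m
    p = params.fraction_causal
    sigma2 = params.h2 / (m_eff * p)
    shrink_scale = 1.0
    rng = np.random.default_rng(params.seed)
    inv_n = 1.0 / n

    for attempt in range(5):
        s2 = sigma2 * shrink_scale
        cur = np.array(beta_std, copy=True)
        accum = np.zeros(m)
        kept = 0
        diverged = False
        # padded current-beta vector so window slices never branch
        pad = np.zeros(m + 2 * radius)
        pad[radius:radius + m] = cur
        log_p = math.log(p) if p < 1 else 0.0
        log_q = math.log1p(-p) if p < 1 else -math.inf
        var_c = s2 + inv_n
        var_0 = inv_n
        post_var = s2 * inv_n / var_c  # = sigma2 / (N sigma2 + 1), 1/N-scaled
        shrinkage = s2 / var_c
        for sweep in range(params.iterations):
            noise = rng.standard_normal(m)
            unif = rng.random(m)
            sweep_mean = np.zeros(m)
            for j in range(m):
                w = pad[j:j + 2 * radius + 1]
                resid = beta_std[j] - (band[j] @ w) + pad[radius + j]
                if p >= 1.0:
                    pbar = 1.0
                else:
                    # log-domain mixture posterior for numerical safety
                    lc = log_p - 0.5 * math.log(var_c) - 0.5 * resid * resid / var_c
                    l0 = log_q - 0.5 * math.log(var_0) - 0.5 * resid * resid / var_0
                    hi = max(lc, l0)
                    pbar = math.exp(lc - hi) / (math.exp(lc - hi) + math.exp(l0 - hi))
                mean = shrinkage * resid
                sweep_mean[j] = pbar * mean
                if unif[j] < pbar:
                    pad[radius + j] = mean + math.sqrt(post_var) * noise[j]
                else:
                    pad[radius + j] = 0.0
            if sweep >= params.burn_in:
                accum += sweep_mean
                kept += 1
            if float(pad[radius:radius + m] @ pad[radius:radius + m]) > 10.0 * params.h2:
                diverged = True
                break
        if not diverged:
            return accum / max(kept, 1)
        shrink_scale *= 0.5
        warnings.warn(
            "LDpred Gibbs diverged; restarting with prior variance halved",
            stacklevel=2,
        )
    return accum / max(kept, 1)


def ldpred_grid_point(
    stats: HarmonizedSet,
    ld: LDWindowMatrix,
    params: LdpredParams,
    output_scale: str = "allele",
    provenance: Optional[dict] = None,
) -> WeightVector:
    """One point of the LDpred tuning grid: posterior-mean weights.

    Summary betas are converted to the standardized scale via
    z / sqrt(N); the Gibbs posterior-mean standardized weights are mapped
    back to per-allele scale by dividing by the panel dosage SD (set
    ``output_scale="standardized"`` to keep them standardized).
    """
    if output_scale not in ("allele", "standardized"):
        raise ValueError("output_scale must be 'allele' or 'standardized'")
    tab = stats.table
    n_per = tab["n"].to_numpy(dtype=float)
    n_eff = params.n if params.n is not None else float(np.nanmedian(n_per))
    beta_std = standardized_betas(stats, np.where(np.isnan(n_per), n_eff, n_per))
    radius = params.ld_radius if params.ld_radius is not None else default_ld_radius(len(stats))
    band = _band_matrix(stats, ld, radius)
    w_std = ldpred_gibbs(beta_std, band, params, n=n_eff)
    if output_scale == "allele":
        sd = ld.dosage_sd[ld.index_of(tab["variant_id"].to_numpy())]
        weight = np.where(sd > 0, w_std / np.where(sd > 0, sd, 1.0), 0.0)
    else:
        weight = w_std
    out = pd.DataFrame({
        "variant_id": tab["variant_id"],
        "chr": tab["chr"],
        "pos": tab["pos"],
        "counted_allele": tab["counted_allele"],
        "weight": weight,
    })
    prov = {
        "method": "LDPRED", "fraction_causal": params.fraction_causal,
        "h2": params.h2, "n": n_eff, "ld_radius": radius,
        "iterations": params.iterations, "burn_in": params.burn_in,
        "seed": params.seed, "output_scale": output_scale,
    }
    prov.update(provenance or {})
    return WeightVector(table=out, provenance=prov)


# ---------------------------------------------------------------------------
# GraBLD-style boosted calibration with regional LD adjustment

@dataclass(frozen=True)
class GrabldParams:
    """Gradient-boosting hyperparameters for the calibration model."""

    n_estimators: int = 250
    max_depth: int = 3
    learning_rate: float = 0.05
    mode: str = "loco"  # leave-one-chromosome-out; "full" mirrors whole-cohort calibration
    seed: int = 42

    def __post_init__(self) -> None:
        if self.mode not in ("loco", "full"):
            raise ValueError("mode must be 'loco' or 'full'")


def _calibration_targets(dosages: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """|slope| of phenotype on standardized dosage, per variant (vectorized OLS)."""
    y = np.asarray(phenotype, dtype=float)
    x = dosages.copy()
    mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(mean, np.where(nan_mask)[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    x = x / np.where(sd > 0, sd, 1.0)
    x[:, sd <= 0] = 0.0
    yc = y - y.mean()
    slope = (x * yc[:, None]).sum(axis=0) / len(y)  # x standardized: Sxx = n
    return np.abs(slope)


def grabld_weights(
    stats: HarmonizedSet,
    calibration: "GenotypeDataset",  # noqa: F821 - forward ref, avoids cycle
    phenotype: np.ndarray,
    ld: LDWindowMatrix,
    params: GrabldParams = GrabldParams(),
    provenance: Optional[dict] = None,
) -> WeightVector:
    """Boosted-tree SNP weight calibration with regional LD adjustment.

    Per variant, gradient-boosted regression trees predict the magnitude of
    its univariate association with the phenotype in the calibration cohort
    from summary features {|beta|, -log10 P, N, allele frequency, regional
    LD score}; the weight is sign(beta) * max(0, prediction) / ld_score.
    Default is leave-one-chromosome-out prediction to avoid calibrating a
    variant on itself; ``mode="full"`` trains on all variants at once.
    """
    from sklearn.ensemble import GradientBoostingRegressor

    tab = stats.table
    ids = tab["variant_id"].to_numpy()
    cal_lookup = {v: j for j, v in enumerate(calibration.variants["variant_id"])}
    try:
        cal_idx = np.array([cal_lookup[v] for v in ids])
    except KeyError as e:
        raise KeyError(f"variant {e.args[0]!r} absent from calibration cohort") from None
    # align calibration dosages to the counted allele
    dos = calibration.dosages[:, cal_idx].copy()
    cal_alt = calibration.variants["alt"].to_numpy(dtype=object)[cal_idx]
    flipped = cal_alt != tab["counted_allele"].to_numpy(dtype=object)
    dos[:, flipped] = 2.0 - dos[:, flipped]

    target = _calibration_targets(dos, phenotype)
    scores = ld.ld_scores()[ld.index_of(ids)]
    freq = np.nanmean(dos, axis=0) / 2.0
    features = np.column_stack([
        np.abs(tab["beta"].to_numpy(dtype=float)),
        -np.log10(tab["p"].to_numpy(dtype=float)),
        tab["n"].to_numpy(dtype=float),
        freq,
        scores,
    ])

    chrom = tab["chr"].to_numpy(dtype=object)
    chroms = pd.unique(chrom)
    pred = np.empty(len(tab))

    def _model():
        return GradientBoostingRegressor(
            n_estimators=params.n_estimators, max_depth=params.max_depth,
            learning_rate=params.learning_rate, loss="squared_error",
            random_state=params.seed,
        )

    if params.mode == "loco":
        if len(chroms) < 2:
            raise ValueError(
                "leave-one-chromosome-out calibration needs >= 2 chromosomes; "
                "use mode='full' for single-chromosome data"
            )
        for c in chroms:
            held = chrom == c
            model = _model().fit(features[~held], target[~held])
            pred[held] = model.predict(features[held])
    else:
        model = _model().fit(features, target)
        pred = model.predict(features)

    sign = np.sign(tab["beta"].to_numpy(dtype=float))
    w_std = sign * np.maximum(pred, 0.0) / scores
    # per-allele scale for scoring raw dosages
    sd = dos.std(axis=0)
    weight = np.where(sd > 0, w_std / np.where(sd > 0, sd, 1.0), 0.0)
    out = pd.DataFrame({
        "variant_id": ids,
        "chr": tab["chr"],
        "pos": tab["pos"],
        "counted_allele": tab["counted_allele"],
        "weight": weight,
        "weight_std": w_std,
    })
    prov = {
        "method": "GRABLD", "mode": params.mode,
        "n_estimators": params.n_estimators, "max_depth": params.max_depth,
        "learning_rate": params.learning_rate, "seed": params.seed,
    }
    prov.update(provenance or {})
    return WeightVector(table=out, provenance=prov)
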