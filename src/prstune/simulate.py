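"""Synthetic cohorts with known LD structure and causal architecture.

Generates block-LD genotypes via a Gaussian copula (one latent Gaussian per
haplotype, thresholded at the allele-frequency quantile), point-normal causal
effects, a liability-threshold binary phenotype at configurable prevalence,
and a training-cohort GWAS summary-statistics table with heterogeneous
per-variant sample sizes — a ground-truth test bed for every downstream
stage of PRS construction.

Allele frequencies, variant metadata and the per-variant sample-size pattern
are functions of the configuration (its ``seed``), so all cohorts drawn from
one :class:`SimConfig` describe the same synthetic population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cholesky, toeplitz

from .containers import SUMMARY_COLUMNS, GenotypeDataset, validate_summary_frame

#: sentinel for a sample whose GDM status cannot be determined
GDM_UNKNOWN = -1

#: South Asian-specific oral-glucose-tolerance cut-offs (mmol/L, inclusive)
FASTING_GLUCOSE_CUTOFF = 5.2
TWO_HOUR_GLUCOSE_CUTOFF = 7.2

# non-palindromic ref/alt pairs cycled by variant index
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population and study design.

    Parameters
    ----------
    n_variants
        Total variant count M; must be a multiple of ``block_size``.
    block_size
        Variants per LD block. Blocks are independent of one another.
    within_block_r
        Latent adjacent-pair correlation target inside a block; correlation
        decays with distance as ``r ** |i - j|``.
    maf_range
        (low, high) bounds of the uniform per-variant allele-frequency draw.
    fraction_causal
        Point-normal mixing proportion p: probability a variant is causal.
    heritability
        Liability-scale h2 in [0, 1).
    prevalence
        Population case proportion K; the liability threshold is the
        (1 - K) standard-normal quantile.
    n_train, n_target, n_reference
        Default cohort sizes for the training GWAS, the tuning target and
        the LD reference panel.
    missing_n_pattern
        Rule assigning per-variant training sample sizes: ``"constant"``
        (every variant tested in all n_train samples) or ``"default"``
        (70% of variants at the maximum N, 30% uniform on [0.5, 1] x max),
        which exercises every sample-size-floor filter level.
    n_chromosomes
        Number of synthetic chromosomes the blocks are spread over
        (variant positions at 1 kb spacing within each chromosome).
    dosage_noise_sd
        If > 0, adds truncated Gaussian noise to hard-call dosages,
        emulating imputed fractional dosages.
    seed
        Population seed: fixes frequencies, metadata and the N pattern.
    """

    n_variants: int = 2000
    block_size: int = 10
    within_block_r: float = 0.6
    maf_range: Tuple[float, float] = (0.05, 0.5)
    fraction_causal: float = 0.01
    heritability: float = 0.5
    prevalence: float = 0.36
    n_train: int = 20_000
    n_target: int = 1_000
    n_reference: int = 500
    missing_n_pattern: str = "default"
    n_chromosomes: int = 1
    dosage_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0 or self.block_size <= 0:
            raise ValueError("n_variants and block_size must be positive")
        if self.n_variants % self.block_size:
            raise ValueError("n_variants must be a multiple of block_size")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.fraction_causal <= 1):
            raise ValueError("fraction_causal must lie in (0, 1]")
        if not (0 <= self.heritability < 1):
            raise ValueError("heritability must lie in [0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("n_train", "n_target", "n_reference"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.missing_n_pattern not in ("default", "constant"):
            raise ValueError("missing_n_pattern must be 'default' or 'constant'")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        n_blocks = self.n_variants // self.block_size
        if n_blocks % self.n_chromosomes:
            raise ValueError("block count must divide evenly across chromosomes")


@dataclass(frozen=True)
class TrueArchitecture:
    """Ground-truth causal architecture of a synthetic population.

    ``true_beta`` holds standardized per-variant effects: N(0, h2 / (M p))
    for causal variants, 0 otherwise, so the genetic liability variance is
    h2 in expectation.
    """

    causal_mask: np.ndarray
    true_beta: np.ndarray

    def __post_init__(self) -> None:
        if self.causal_mask.shape != self.true_beta.shape:
            raise ValueError("causal_mask and true_beta must align")
        if np.any(self.true_beta[~self.causal_mask] != 0):
            raise ValueError("non-causal variants must carry zero effect")


def population_frequencies(config: SimConfig) -> np.ndarray:
    """Per-variant alt-allele frequencies, fixed by the population seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_variants)


def variant_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic variant metadata: 1 kb spacing per chromosome."""
    m = config.n_variants
    per_chrom = m // config.n_chromosomes
    idx = np.arange(m)
    chrom = (idx // per_chrom + 1).astype(str)
    pos = (idx % per_chrom + 1) * 1000
    ref = [_ALLELE_CYCLE[i % 4][0] for i in idx]
    alt = [_ALLELE_CYCLE[i % 4][1] for i in idx]
    return pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in idx],
        "chr": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "info_score": 1.0,
    })


def per_variant_n(config: SimConfig) -> np.ndarray:
    """Per-variant training sample sizes under ``missing_n_pattern``."""
    if config.missing_n_pattern == "constant":
        return np.full(config.n_variants, config.n_train, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    n = np.full(config.n_variants, config.n_train, dtype=float)
    reduced = rng.random(config.n_variants) < 0.30
    n[reduced] = rng.uniform(0.5, 1.0, size=int(reduced.sum())) * config.n_train
    return np.maximum(np.round(n).astype(int), 2)


def _block_chol(config: SimConfig) -> np.ndarray:
    r = config.within_block_r
    corr = toeplitz(r ** np.arange(config.block_size))
    return cholesky(corr, lower=True)


def simulate_genotypes(config: SimConfig, n: int, seed: int) -> GenotypeDataset:
    """Draw an ``n``-sample cohort from the synthetic population.

    Each haplotype is a latent multivariate normal with block-Toeplitz
    correlation ``within_block_r ** |i - j|``; the allele is present where
    the latent value falls below the frequency quantile, and the dosage is
    the sum over the two haplotypes. Blocks are mutually independent.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, seed]))
    freqs = population_frequencies(config)
    thresholds = sps.norm.ppf(freqs)
    bs = config.block_size
    n_blocks = config.n_variants // bs
    chol = _block_chol(config)
    dosages = np.empty((n, config.n_variants), dtype=float)
    for b in range(n_blocks):
        z = rng.standard_normal((2 * n, bs))
        if config.within_block_r > 0:
            z = z @ chol.T
        hap = z < thresholds[b * bs:(b + 1) * bs]
        dosages[:, b * bs:(b + 1) * bs] = hap[0::2].astype(float) + hap[1::2]
    if config.dosage_noise_sd > 0:
        dosages += rng.normal(0.0, config.dosage_noise_sd, size=dosages.shape)
        np.clip(dosages, 0.0, 2.0, out=dosages)
    return GenotypeDataset(
        sample_ids=np.array([f"S{seed}_{i}" for i in range(n)], dtype=object),
        variants=variant_table(config),
        dosages=dosages,
    )


def draw_effects(config: SimConfig, seed: int) -> TrueArchitecture:
    """Point-normal effect draw: causal w.p. p, beta ~ N(0, h2 / (M p))."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, seed]))
    m, p = config.n_variants, config.fraction_causal
    causal = rng.random(m) < p
    beta = np.zeros(m)
    if config.heritability > 0:
        sigma = math.sqrt(config.heritability / (m * p))
        beta[causal] = rng.normal(0.0, sigma, size=int(causal.sum()))
    return TrueArchitecture(causal_mask=causal, true_beta=beta)


def _standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    mean = np.nanmean(dosages, axis=0)
    sd = np.nanstd(dosages, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (dosages - mean) / sd
    return np.nan_to_num(x, nan=0.0)


def simulate_phenotype(
    genotypes: GenotypeDataset,
    arch: TrueArchitecture,
    config: SimConfig,
    seed: int,
    return_liability: bool = False,
):
    """Liability-threshold phenotype at prevalence K.

    liability = standardized-genotype . true_beta + e, e ~ N(0, 1 - h2);
    a sample is a case when its liability exceeds the (1 - K) quantile of
    the standard normal.
    """
    if genotypes.n_variants != len(arch.true_beta):
        raise ValueError("genotype and architecture variant counts differ")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, seed]))
    x = _standardize_dosages(genotypes.dosages)
    genetic = x @ arch.true_beta
    liability = genetic + rng.normal(
        0.0, math.sqrt(1.0 - config.heritability), size=genotypes.n_samples
    )
    threshold = sps.norm.ppf(1.0 - config.prevalence)
    status = (liability > threshold).astype(int)
    if return_liability:
        return status, liability
    return status


def label_gdm(fasting_mmol_L=None, two_hour_mmol_L=None, self_report=None):
    """Binary GDM status from oral-glucose-tolerance measures.

    Case iff fasting glucose >= 5.2 mmol/L or 2-hour post-load glucose
    >= 7.2 mmol/L (both boundaries inclusive). When both measures are
    absent the self-reported flag is used; when that too is absent the
    :data:`GDM_UNKNOWN` sentinel is returned. Scalar or array inputs.
    """
    fasting = np.asarray(fasting_mmol_L, dtype=float) if fasting_mmol_L is not None else None
    two_hour = np.asarray(two_hour_mmol_L, dtype=float) if two_hour_mmol_L is not None else None
    shape = fasting.shape if fasting is not None else (
        two_hour.shape if two_hour is not None else np.shape(self_report))
    if fasting is None:
        fasting = np.full(shape, np.nan)
    if two_hour is None:
        two_hour = np.full(shape, np.nan)
    if np.nanmin(np.concatenate([fasting.ravel(), two_hour.ravel()]), initial=0.0) < 0:
        raise ValueError("glucose concentrations must be non-negative")
    measured = ~(np.isnan(fasting) & np.isnan(two_hour))
    with np.errstate(invalid="ignore"):
        case = (fasting >= FASTING_GLUCOSE_CUTOFF) | (two_hour >= TWO_HOUR_GLUCOSE_CUTOFF)
    out = np.where(measured, case.astype(int), GDM_UNKNOWN)
    if self_report is not None:
        sr = np.asarray(self_report, dtype=float)
        fallback = ~measured & ~np.isnan(sr)
        out = np.where(fallback, sr.astype(int), out)
    if out.ndim == 0:
        return int(out)
    return out.astype(int)


def _linear_gwas(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Simple-regression slope, SE and two-sided P of y on x (intercept fitted)."""
    n = len(y)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0 or n < 3:
        return np.nan, np.nan, np.nan
    beta = float(xc @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = math.sqrt(max(sigma2, 1e-300) / sxx)
    t = beta / se if se > 0 else 0.0
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return beta, se, min(max(p, np.finfo(float).tiny), 1.0)


def make_summary_stats(
    train_genotypes: GenotypeDataset,
    phenotype: np.ndarray,
    config: SimConfig,
    model: str = "linear",
) -> pd.DataFrame:
    """Per-variant univariate GWAS emulating consortium meta-analysis output.

    Each variant is regressed on a per-variant subsample whose size follows
    ``config.missing_n_pattern`` (the leading rows of the cohort), so the
    table carries heterogeneous per-variant N as real meta-analyses do.
    ``model`` is ``"linear"`` (phenotype treated as continuous; the default,
    appropriate for the liability) or ``"logistic"`` (binary status;
    per-variant maximum-likelihood fits, markedly slower).
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != train_genotypes.n_samples:
        raise ValueError("phenotype length must match sample count")
    if model not in ("linear", "logistic"):
        raise ValueError("model must be 'linear' or 'logistic'")
    m = train_genotypes.n_variants
    ns = np.minimum(per_variant_n(config), train_genotypes.n_samples)
    x_all = _standardize_dosages(train_genotypes.dosages)
    sds = np.nanstd(train_genotypes.dosages, axis=0)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)

    if model == "linear":
        # vectorize the (typically large) full-N group, loop the rest
        full = ns == train_genotypes.n_samples
        if full.any():
            xf = x_all[:, full]
            # re-standardize within subsample is a no-op for the full group
            n = len(y)
            yc = y - y.mean()
            xc = xf - xf.mean(axis=0)
            sxx = (xc * xc).sum(axis=0)
            ok = sxx > 0
            b = np.where(ok, (xc * yc[:, None]).sum(axis=0) / np.where(ok, sxx, 1.0), np.nan)
            resid = yc[:, None] - b * xc
            sigma2 = (resid * resid).sum(axis=0) / (n - 2)
            s = np.sqrt(np.where(ok, sigma2 / np.where(ok, sxx, 1.0), np.nan))
            t = np.where(s > 0, b / s, 0.0)
            pv = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
            idx = np.where(full)[0][ok]
            beta[idx] = b[ok]
            se[idx] = s[ok]
            pval[idx] = np.clip(pv[ok], np.finfo(float).tiny, 1.0)
        for j in np.where(~full)[0]:
            nj = ns[j]
            xj = train_genotypes.dosages[:nj, j]
            sd = np.nanstd(xj)
            if not sd > 0:
                continue
            xj = np.nan_to_num((xj - np.nanmean(xj)) / sd, nan=0.0)
            beta[j], se[j], pval[j] = _linear_gwas(xj, y[:nj])
    else:
        import statsmodels.api as sm
        for j in range(m):
            nj = ns[j]
            if sds[j] <= 0:
                continue
            xj = sm.add_constant(x_all[:nj, j])
            try:
                fit = sm.Logit(y[:nj], xj).fit(disp=0, maxiter=100)
                beta[j] = fit.params[1]
                se[j] = fit.bse[1]
                pval[j] = min(max(fit.pvalues[1], np.finfo(float).tiny), 1.0)
            except Exception:
                continue

    tab = train_genotypes.variants
    stats = pd.DataFrame({
        "variant_id": tab["variant_id"],
        "chr": tab["chr"],
        "pos": tab["pos"],
        "effect_allele": tab["alt"],
        "other_allele": tab["ref"],
        "beta": beta,
        "se": se,
        "p": pval,
        "n": ns.astype(float),
    }, columns=SUMMARY_COLUMNS)
    stats.attrs["n_monomorphic"] = int(np.isnan(beta).sum())
    return validate_summary_frame(stats)


@dataclass
class SyntheticStudy:
    """Convenience bundle: one population, all cohorts, truth and GWAS."""

    config: SimConfig
    architecture: TrueArchitecture
    train: GenotypeDataset
    target: GenotypeDataset
    reference: GenotypeDataset
    train_status: np.ndarray
    train_liability: np.ndarray
    target_status: np.ndarray
    summary_stats: pd.DataFrame = field(repr=False, default=None)


def simulate_study(config: SimConfig, seed: int = 0) -> SyntheticStudy:
    """Generate training, target and reference cohorts plus summary stats."""
    arch = draw_effects(config, seed)
    train = simulate_genotypes(config, config.n_train, seed=seed * 4 + 1)
    target = simulate_genotypes(config, config.n_target, seed=seed * 4 + 2)
    reference = simulate_genotypes(config, config.n_reference, seed=seed * 4 + 3)
    train_status, train_liab = simulate_phenotype(
        train, arch, config, seed=seed * 4 + 1, return_liability=True)
    target_status = simulate_phenotype(target, arch, config, seed=seed * 4 + 2)
    stats = make_summary_stats(train, train_liab, config)
    return SyntheticStudy(
        config=config, architecture=arch, train=train, target=target,
        reference=reference, train_status=np.asarray(train_status),
        train_liability=train_liab, target_status=np.asarray(target_status),
        summary_stats=stats,
    )
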