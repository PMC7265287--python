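"""Windowed linkage-disequilibrium structure from a reference genotype panel.

Pairwise dosage correlations are computed within a physical (kb) or
variant-count window and held in banded sparse storage; out-of-window pairs
are treated as zero. The panel can first be subset to mimic the ethnic
composition of the consortium whose summary statistics are being used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import GenotypeDataset


@dataclass(frozen=True)
class PanelSpec:
    """Reference-panel recipe: source label + subpopulation proportions."""

    source: str
    proportions: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proportions:
            w = np.array(list(self.proportions.values()), dtype=float)
            if (w < 0).any():
                raise ValueError("population weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("population weights must sum to 1")


def largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` by weight, largest-remainder rule."""
    raw = np.asarray(weights, dtype=float) * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def subset_reference(
    panel: GenotypeDataset,
    spec: PanelSpec,
    total_size: Optional[int] = None,
    seed: int = 0,
) -> GenotypeDataset:
    """Draw a panel subset matching the spec's subpopulation proportions.

    Per-label counts are ``round(weight x total_size)`` with a
    largest-remainder correction so they sum exactly; samples are drawn
    without replacement within each label.
    """
    if not spec.proportions:
        return panel
    if panel.populations is None:
        raise ValueError("panel carries no per-sample population labels")
    total = total_size if total_size is not None else panel.n_samples
    labels = list(spec.proportions)
    weights = np.array([spec.proportions[k] for k in labels])
    counts = largest_remainder_counts(weights, total)
    rng = np.random.default_rng(seed)
    chosen = []
    for label, k in zip(labels, counts):
        pool = np.where(panel.populations == label)[0]
        if spec.proportions[label] > 0 and len(pool) == 0:
            raise ValueError(f"population label {label!r} absent from panel")
        if k > len(pool):
            raise ValueError(
                f"population {label!r} has {len(pool)} samples, {k} requested"
            )
        chosen.append(rng.choice(pool, size=k, replace=False))
    idx = np.sort(np.concatenate(chosen))
    return panel.take_samples(idx)


@dataclass
class LDWindowMatrix:
    """Banded within-window correlation structure over ordered variants.

    ``r`` is a symmetric CSR matrix holding Pearson r for in-window pairs
    (diagonal = 1); pairs outside the window are structurally zero.
    ``dosage_sd`` is the panel dosage standard deviation per variant, used
    to move weights between standardized and per-allele scales.
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    r: sparse.csr_matrix
    n_ref: int
    window_kb: Optional[float]
    window_count: Optional[int]
    dosage_sd: np.ndarray = None
    monomorphic: np.ndarray = None

    def __post_init__(self) -> None:
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("correlation matrix does not match variant count")
        if self.monomorphic is None:
            self.monomorphic = np.zeros(m, dtype=bool)
        if self.dosage_sd is None:
            self.dosage_sd = np.ones(m)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_ids) -> np.ndarray:
        try:
            return np.array([self._index[v] for v in variant_ids])
        except KeyError as e:
            raise KeyError(f"variant {e.args[0]!r} absent from LD matrix") from None

    def pair_r(self, i: int, j: int) -> float:
        return float(self.r[i, j])

    def row(self, i: int):
        """(neighbor indices, r values) of variant i's in-window band."""
        sl = slice(self.r.indptr[i], self.r.indptr[i + 1])
        return self.r.indices[sl], self.r.data[sl]

    def ld_scores(self) -> np.ndarray:
        """Regional LD score per variant: sum of in-window r^2 (self included)."""
        sq = self.r.copy()
        sq.data = sq.data ** 2
        return np.asarray(sq.sum(axis=1)).ravel()

    def to_tsv(self, path) -> None:
        coo = sparse.triu(self.r).tocoo()
        pd.DataFrame({
            "variant_i": self.variant_ids[coo.row],
            "variant_j": self.variant_ids[coo.col],
            "r": coo.data,
        }).to_csv(path, sep="\t", index=False, float_format="%.8g")


def _window_bounds(chrom, pos, window_kb, window_count):
    """Per-variant [start, stop) column bounds of the in-window band."""
    m = len(pos)
    starts = np.empty(m, dtype=int)
    stops = np.empty(m, dtype=int)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    boundaries = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1], True])
    for b in range(len(boundaries) - 1):
        lo, hi = boundaries[b], boundaries[b + 1]
        p = pos[lo:hi]
        if window_count is not None:
            idx = np.arange(hi - lo)
            starts[lo:hi] = np.maximum(idx - window_count, 0) + lo
            stops[lo:hi] = np.minimum(idx + window_count + 1, hi - lo) + lo
        else:
            radius = window_kb * 1000.0
            starts[lo:hi] = np.searchsorted(p, p - radius, side="left") + lo
            stops[lo:hi] = np.searchsorted(p, p + radius, side="right") + lo
    return starts, stops


def compute_ld(
    ds: GenotypeDataset,
    window_kb: Optional[float] = 250.0,
    window_count: Optional[int] = None,
    shrink: bool = False,
) -> LDWindowMatrix:
    """Pearson dosage correlation for all in-window variant pairs.

    Variants must already be position-sorted within each chromosome (no
    silent sorting). Missing dosages are mean-imputed per variant before
    correlation; monomorphic variants get r = 0 off-diagonal and are
    flagged. ``shrink`` applies optional r <- r / (1 + 1/n_ref) damping
    (off by default).
    """
    if ds.n_samples < 2:
        raise ValueError("LD computation needs at least 2 panel samples")
    if window_count is not None:
        window_kb = None
    elif window_kb is None:
        raise ValueError("one of window_kb or window_count is required")
    vt = ds.variants
    chrom = vt["chr"].to_numpy(dtype=object)
    pos = vt["pos"].to_numpy(dtype=float)
    for b in np.split(np.arange(len(pos)), np.flatnonzero(chrom[1:] != chrom[:-1]) + 1):
        if np.any(np.diff(pos[b]) < 0):
            raise ValueError("variants must be position-sorted within each chromosome")

    x = ds.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    mono = sd <= 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic variants; off-diagonal r set to 0",
                      stacklevel=2)
    x = x / np.where(mono, 1.0, sd)
    x[:, mono] = 0.0
    n, m = x.shape

    starts, stops = _window_bounds(chrom, pos, window_kb, window_count)
    max_band = int(np.max(stops - np.arange(m))) if m else 0

    rows, cols, vals = [], [], []
    chunk = max(1, min(m, 512))
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        hi = min(m, int(stops[a:b].max()))
        g = (x[:, a:b].T @ x[:, a:hi]) / n
        for i in range(a, b):
            lo_i, hi_i = starts[i], stops[i]
            # store the upper triangle of the band; mirror later
            j0 = max(lo_i, i)
            cols_i = np.arange(j0, hi_i)
            vals_i = g[i - a, j0 - a:hi_i - a].copy()
            rows.append(np.full(len(cols_i), i))
            cols.append(cols_i)
            vals.append(vals_i)
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    vals = np.concatenate(vals) if vals else np.empty(0)
    vals = np.clip(vals, -1.0, 1.0)
    if shrink:
        off = rows != cols
        vals[off] = vals[off] / (1.0 + 1.0 / ds.n_samples)
    # exact diagonal, including monomorphic variants
    diag = rows == cols
    vals[diag] = 1.0
    upper = sparse.coo_matrix((vals, (rows, cols)), shape=(m, m))
    strict = sparse.triu(upper, k=1)
    r = (sparse.eye(m, format="coo") + strict + strict.T).tocsr()
    return LDWindowMatrix(
        variant_ids=vt["variant_id"].to_numpy(dtype=object),
        chrom=chrom, pos=pos.astype(int), r=r, n_ref=ds.n_samples,
        window_kb=window_kb, window_count=window_count,
        dosage_sd=np.where(mono, 0.0, sd),
        monomorphic=mono,
    )


def ld_scores(ld: LDWindowMatrix) -> np.ndarray:
    """Convenience wrapper for :meth:`LDWindowMatrix.ld_scores`."""
    return ld.ld_scores()
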