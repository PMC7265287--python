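"""Grid orchestration: enumerate the tuning grid, run every cell, rank by
AUC, freeze the top PRS and apply it to a replication cohort.

The study is exposed statsmodels-style: :class:`PRSGridStudy` holds the data
and the grid definition; :meth:`PRSGridStudy.fit` evaluates every cell and
returns a :class:`TuneResult` carrying the ranked table, the frozen top
weights, a deterministic run manifest and a ``summary()`` view. Replication
happens only through :meth:`TuneResult.replicate`, on frozen weights.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .containers import GenotypeDataset, WeightVector
from .evaluate import PRSEvaluation, evaluate_prs, score
from .harmonize import HarmonizedSet, harmonize
from .io import filter_info, filter_sample_size
from .ld import LDWindowMatrix, compute_ld
from .weights import (
    ClumpParams,
    GrabldParams,
    LdpredParams,
    clump,
    grabld_weights,
    ldpred_grid_point,
    pt_weights,
)

METHODS = ("PT", "LDPRED", "GRABLD")
DEFAULT_N_FLOORS = (0.0, 0.85, 0.90, 0.95, 0.98)


def threshold_grid(n: int = 64, low: float = 5e-8, high: float = 1.0) -> np.ndarray:
    """Log-uniform grid of n significance / fraction-causal thresholds.

    Shared between the P+T index P-value cutoffs and the LDpred
    fraction-causal values; endpoints (5e-8 and 1) are included exactly.
    """
    grid = np.logspace(np.log10(low), np.log10(high), n)
    grid[0], grid[-1] = low, high
    return grid


@dataclass(frozen=True)
class PRSConfig:
    """One tuning-grid cell: method x source x N floor x LD source x threshold."""

    method: str
    summary_source: str
    n_floor_fraction: float
    ld_source: str
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if (self.threshold is None) != (self.method == "GRABLD"):
            raise ValueError("threshold must be present iff method != GRABLD")
        if not (0 <= self.n_floor_fraction <= 1):
            raise ValueError("n_floor_fraction must lie in [0, 1]")

    @property
    def config_hash(self) -> str:
        payload = json.dumps({
            "method": self.method, "summary_source": self.summary_source,
            "n_floor_fraction": repr(self.n_floor_fraction),
            "ld_source": self.ld_source,
            "threshold": None if self.threshold is None else repr(self.threshold),
        }, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def cell_seed(self) -> int:
        """Deterministic per-cell seed derived from the config hash."""
        return int(self.config_hash[:7], 16) % (2 ** 31)


@dataclass(frozen=True)
class GridSpec:
    """Tuning-grid definition (axes of the Cartesian product)."""

    summary_sources: Tuple[str, ...]
    ld_sources: Tuple[str, ...]
    methods: Tuple[str, ...] = METHODS
    n_floors: Tuple[float, ...] = DEFAULT_N_FLOORS
    pt_thresholds: Tuple[float, ...] = tuple(threshold_grid())
    ldpred_fractions: Tuple[float, ...] = tuple(threshold_grid())

    def __post_init__(self) -> None:
        for name in ("summary_sources", "ld_sources", "methods", "n_floors"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid axis {name!r} is empty")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        if "PT" in self.methods and len(self.pt_thresholds) == 0:
            raise ValueError("pt_thresholds axis is empty")
        if "LDPRED" in self.methods and len(self.ldpred_fractions) == 0:
            raise ValueError("ldpred_fractions axis is empty")

    def to_manifest(self) -> dict:
        return {
            "summary_sources": list(self.summary_sources),
            "ld_sources": list(self.ld_sources),
            "methods": list(self.methods),
            "n_floors": [repr(f) for f in self.n_floors],
            "pt_thresholds": [repr(t) for t in self.pt_thresholds],
            "ldpred_fractions": [repr(t) for t in self.ldpred_fractions],
        }


def enumerate_grid(spec: GridSpec) -> List[PRSConfig]:
    """Deterministic Cartesian product of the tuning axes, per method."""
    configs: List[PRSConfig] = []
    for method in spec.methods:
        if method == "PT":
            thresholds: Sequence[Optional[float]] = spec.pt_thresholds
        elif method == "LDPRED":
            thresholds = spec.ldpred_fractions
        else:
            thresholds = (None,)
        for source in spec.summary_sources:
            for floor in spec.n_floors:
                for ld_source in spec.ld_sources:
                    for thr in thresholds:
                        configs.append(PRSConfig(
                            method=method, summary_source=source,
                            n_floor_fraction=floor, ld_source=ld_source,
                            threshold=thr,
                        ))
    return configs


@dataclass
class TuneResult:
    """Ranked outcome of a grid run (the Results object).

    ``ranked`` pairs every successful cell with its evaluation, ordered by
    descending AUC (ties: ascending slope P, then config hash); ``top_*``
    freeze the winner; ``manifest`` makes the run byte-reproducible.
    """

    ranked: List[Tuple[PRSConfig, PRSEvaluation]]
    top_config: PRSConfig
    top_weights: WeightVector
    manifest: dict
    failures: List[Tuple[PRSConfig, str]] = field(default_factory=list)

    @property
    def top_evaluation(self) -> PRSEvaluation:
        return self.ranked[0][1]

    def summary(self, max_rows: Optional[int] = 10) -> pd.DataFrame:
        rows = []
        for cfg, ev in self.ranked[:max_rows]:
            row = {
                "method": cfg.method, "source": cfg.summary_source,
                "n_floor": cfg.n_floor_fraction, "ld_source": cfg.ld_source,
                "threshold": cfg.threshold, "config_hash": cfg.config_hash,
            }
            row.update(ev.summary_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, sort_keys=True, indent=1)

    def replicate(
        self,
        cohort: GenotypeDataset,
        status: np.ndarray,
        info_threshold: float = 0.6,
    ) -> PRSEvaluation:
        """Apply the frozen top weights to an independent replication cohort.

        The cohort is first filtered at the replication info-score threshold
        (default 0.6); the fraction of weight variants found is reported and
        a warning is emitted below 98% coverage. No re-tuning happens here.
        """
        filtered = filter_info(cohort, threshold=info_threshold)
        res = score(filtered, self.top_weights)
        if res.coverage == 0:
            raise ValueError("replication cohort covers none of the top PRS variants")
        if res.coverage < 0.98:
            warnings.warn(
                f"replication coverage {res.coverage:.3f} is below 0.98",
                stacklevel=2,
            )
        return evaluate_prs(
            np.asarray(status), res.scores, coverage=res.coverage,
            config={"config_hash": self.top_config.config_hash,
                    "stage": "replication"},
        )


@dataclass
class StudyData:
    """Inputs of one tuning run.

    ``summary_stats`` maps source label -> canonical summary frame;
    ``ld_panels`` maps LD source label -> genotype panel (e.g. an external
    reference panel and the target cohort itself). The replication cohort is
    deliberately not part of this container: tuning can never read it.
    """

    summary_stats: Dict[str, pd.DataFrame]
    target: GenotypeDataset
    target_status: np.ndarray
    ld_panels: Dict[str, GenotypeDataset]
    ldpred_h2: float = 0.5
    ld_window_kb: float = 250.0
    clump_r2: float = 0.5
    grabld_params: GrabldParams = field(default_factory=GrabldParams)
    info_threshold: float = 0.7


def _cell_weights(
    cfg: PRSConfig,
    harmonized: HarmonizedSet,
    ld: LDWindowMatrix,
    data: StudyData,
) -> WeightVector:
    prov = {"config_hash": cfg.config_hash}
    if cfg.method == "PT":
        params = ClumpParams(
            index_p_cutoff=cfg.threshold, r2_threshold=data.clump_r2,
            window_kb=data.ld_window_kb,
        )
        idx = clump(harmonized, ld, params)
        return pt_weights(harmonized, idx, cfg.threshold, provenance=prov)
    if cfg.method == "LDPRED":
        params = LdpredParams(
            fraction_causal=cfg.threshold, h2=data.ldpred_h2,
            seed=cfg.cell_seed(),
        )
        return ldpred_grid_point(harmonized, ld, params, provenance=prov)
    grab = data.grabld_params
    if grab.mode == "loco" and harmonized.table["chr"].nunique() < 2:
        grab = GrabldParams(
            n_estimators=grab.n_estimators, max_depth=grab.max_depth,
            learning_rate=grab.learning_rate, mode="full", seed=grab.seed,
        )
    return grabld_weights(
        harmonized, data.target, data.target_status, ld,
        params=grab, provenance=prov,
    )


def run_grid(spec: GridSpec, data: StudyData, use_cache: bool = True) -> TuneResult:
    """Evaluate every grid cell, rank by AUC and freeze the top PRS.

    Harmonization is cached per (source, N floor) and LD per LD source;
    individual cell failures are logged and excluded rather than fatal.
    """
    for label in spec.summary_sources:
        if label not in data.summary_stats:
            raise KeyError(f"summary source {label!r} not provided")
    for label in spec.ld_sources:
        if label not in data.ld_panels:
            raise KeyError(f"LD source {label!r} not provided")

    target = filter_info(data.target, threshold=data.info_threshold)
    status = np.asarray(data.target_status)
    configs = enumerate_grid(spec)

    ld_cache: Dict[str, LDWindowMatrix] = {}
    harm_cache: Dict[Tuple[str, float], HarmonizedSet] = {}

    def get_ld(label: str) -> LDWindowMatrix:
        if not use_cache or label not in ld_cache:
            ld_cache[label] = compute_ld(
                data.ld_panels[label], window_kb=data.ld_window_kb
            )
            if not use_cache:
                return ld_cache.pop(label)
        return ld_cache[label]

    def get_harmonized(source: str, floor: float) -> HarmonizedSet:
        key = (source, floor)
        if not use_cache or key not in harm_cache:
            stats = filter_sample_size(data.summary_stats[source], floor)
            stats = stats[stats["beta"].notna()]  # monomorphic-in-training records
            harm_cache[key] = harmonize(stats, target)
            if not use_cache:
                return harm_cache.pop(key)
        return harm_cache[key]

    results: List[Tuple[PRSConfig, PRSEvaluation]] = []
    weight_store: Dict[str, WeightVector] = {}
    failures: List[Tuple[PRSConfig, str]] = []
    for cfg in configs:
        try:
            harmonized = get_harmonized(cfg.summary_source, cfg.n_floor_fraction)
            ld = get_ld(cfg.ld_source)
            wv = _cell_weights(cfg, harmonized, ld, data)
            res = score(target, wv) if len(wv) else None
            if res is None:
                ev = evaluate_prs(status, np.zeros(target.n_samples),
                                  contrasts=False, coverage=0.0)
            else:
                ev = evaluate_prs(status, res.scores, coverage=res.coverage,
                                  contrasts=False)
            ev.config = {"config_hash": cfg.config_hash}
            results.append((cfg, ev))
            weight_store[cfg.config_hash] = wv
        except Exception as exc:  # cell-level failure: log, continue
            failures.append((cfg, f"{type(exc).__name__}: {exc}"))
    if not results:
        raise RuntimeError(
            "every grid cell failed; first error: "
            + (failures[0][1] if failures else "unknown")
        )

    results.sort(key=lambda ce: (-ce[1].auc, ce[1].p, ce[0].config_hash))
    top_cfg, top_ev = results[0]
    top_weights = weight_store[top_cfg.config_hash]
    # recompute the winner's evaluation with the quartile contrasts attached
    top_scores = score(target, top_weights)
    top_full = evaluate_prs(status, top_scores.scores,
                            coverage=top_scores.coverage)
    top_full.config = {"config_hash": top_cfg.config_hash}
    results[0] = (top_cfg, top_full)

    manifest = {
        "package_version": _pkg_version,
        "grid": spec.to_manifest(),
        "n_cells": len(configs),
        "n_failed": len(failures),
        "info_threshold": repr(data.info_threshold),
        "clump_r2": repr(data.clump_r2),
        "ld_window_kb": repr(data.ld_window_kb),
        "ldpred_h2": repr(data.ldpred_h2),
        "grabld": {k: repr(v) for k, v in asdict(data.grabld_params).items()},
        "ranking": [
            {"config_hash": cfg.config_hash, "auc": repr(ev.auc), "p": repr(ev.p)}
            for cfg, ev in results
        ],
        "top_config_hash": top_cfg.config_hash,
        "quantile_policy": "top 25% = score >= lower-interpolated 75th percentile",
    }
    return TuneResult(
        ranked=results, top_config=top_cfg, top_weights=top_weights,
        manifest=manifest, failures=failures,
    )


class PRSGridStudy:
    """The tuning study as a model object.

    Parameters mirror :class:`StudyData`; ``fit()`` runs the grid and
    returns a :class:`TuneResult`.

    Examples
    --------
    >>> from prstune.simulate import SimConfig, simulate_study
    >>> study = simulate_study(SimConfig(n_variants=200, n_train=2000,
    ...                                  n_target=400, seed=7), seed=7)
    >>> model = PRSGridStudy.from_synthetic(study,
    ...     spec=GridSpec(summary_sources=("train_gwas",),
    ...                   ld_sources=("reference_panel",),
    ...                   methods=("PT",), n_floors=(0.0,),
    ...                   pt_thresholds=(0.05, 1.0)))
    >>> result = model.fit()
    >>> result.top_config.method
    'PT'
    """

    def __init__(self, spec: GridSpec, data: StudyData):
        self.spec = spec
        self.data = data

    @classmethod
    def from_synthetic(cls, study, spec: Optional[GridSpec] = None,
                       **data_kwargs) -> "PRSGridStudy":
        """Build a study from a :class:`~prstune.simulate.SyntheticStudy`.

        Exposes two LD sources (the external reference panel and the target
        cohort itself) under the labels ``reference_panel`` and
        ``target_cohort``, and the training GWAS as ``train_gwas``.
        """
        if spec is None:
            spec = GridSpec(
                summary_sources=("train_gwas",),
                ld_sources=("reference_panel", "target_cohort"),
            )
        data = StudyData(
            summary_stats={"train_gwas": study.summary_stats},
            target=study.target,
            target_status=np.asarray(study.target_status),
            ld_panels={
                "reference_panel": study.reference,
                "target_cohort": study.target,
            },
            **data_kwargs,
        )
        return cls(spec=spec, data=data)

    def fit(self, use_cache: bool = True) -> TuneResult:
        return run_grid(self.spec, self.data, use_cache=use_cache)
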