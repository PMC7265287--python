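"""Core in-memory containers shared across the pipeline.

Genotypes live in a :class:`GenotypeDataset` (samples x variants dosage
matrix plus a variant table); external GWAS results in a pandas DataFrame
with the canonical columns of :data:`SUMMARY_COLUMNS`; score weights in a
:class:`WeightVector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: canonical column order of a summary-statistics table
SUMMARY_COLUMNS = [
    "variant_id", "chr", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "n",
]

#: canonical column order of a variant table
VARIANT_COLUMNS = ["variant_id", "chr", "pos", "ref", "alt", "info_score"]


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's external GWAS result.

    ``beta`` is the per-effect-allele log-odds (binary trait) or linear
    effect; ``n`` is the per-variant analyzed sample count, which varies
    across variants in meta-analyses.
    """

    variant_id: str
    chr: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    n: float

    def __post_init__(self) -> None:
        if np.isfinite(self.beta) and not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0 when beta present")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect allele equals other allele")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.variant_id}: p must lie in (0, 1]")


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    """Stack records into the canonical summary-statistics DataFrame."""
    return pd.DataFrame([r.__dict__ for r in records], columns=SUMMARY_COLUMNS)


def frame_to_records(stats: pd.DataFrame) -> Iterator[SummaryStatRecord]:
    for row in stats.itertuples(index=False):
        yield SummaryStatRecord(
            variant_id=row.variant_id, chr=str(row.chr), pos=int(row.pos),
            effect_allele=row.effect_allele, other_allele=row.other_allele,
            beta=float(row.beta), se=float(row.se), p=float(row.p),
            n=float(row.n),
        )


def validate_summary_frame(stats: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a summary-statistics table; return it unchanged."""
    missing = [c for c in SUMMARY_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    has_beta = stats["beta"].notna()
    if (stats.loc[has_beta, "se"] <= 0).any():
        raise ValueError("se must be positive where beta is present")
    p = stats["p"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p must lie in (0, 1]")
    if (stats["effect_allele"] == stats["other_allele"]).any():
        raise ValueError("effect allele must differ from other allele")
    return stats


@dataclass
class GenotypeDataset:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages[i, j]`` counts copies of the *alt* allele of variant ``j``
    carried by sample ``i`` (in [0, 2]; NaN marks a missing call).
    ``variants`` has columns :data:`VARIANT_COLUMNS`; ``info_score`` is the
    imputation quality in [0, 1] (NaN when unknown, e.g. directly typed).
    ``populations`` optionally labels each sample (reference panels).
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    populations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages must lie within [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
            if len(self.populations) != len(self.sample_ids):
                raise ValueError("populations must label every sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, idx: np.ndarray) -> "GenotypeDataset":
        """Subset to the given variant indices (order preserved as given)."""
        return GenotypeDataset(
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            populations=self.populations,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            sample_ids=self.sample_ids[idx],
            variants=self.variants,
            dosages=self.dosages[idx, :],
            populations=None if self.populations is None else self.populations[idx],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class WeightVector:
    """Per-variant score weights tied to a counted effect allele.

    ``table`` columns: variant_id, chr, pos, counted_allele, weight.
    ``provenance`` carries the configuration that produced the weights
    (method name, thresholds, hashes) for run manifests.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"variant_id", "counted_allele", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        if self.table["variant_id"].duplicated().any():
            raise ValueError("weight table contains duplicate variants")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["method"] = self.provenance.get("method", "")
        out["config_hash"] = self.provenance.get("config_hash", "")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WeightVector":
        tab = pd.read_csv(path, sep="\t", dtype={"chr": str})
        prov = {}
        if "method" in tab.columns:
            prov["method"] = str(tab["method"].iloc[0]) if len(tab) else ""
            tab = tab.drop(columns=["method"])
        if "config_hash" in tab.columns:
            prov["config_hash"] = str(tab["config_hash"].iloc[0]) if len(tab) else ""
            tab = tab.drop(columns=["config_hash"])
        return cls(table=tab, provenance=prov)
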