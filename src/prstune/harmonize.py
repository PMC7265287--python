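"""Effect-allele alignment between GWAS summary statistics and genotypes.

After harmonization every retained summary beta multiplies the dosage of the
dataset's counted (alt) allele: betas are sign-flipped where the summary
effect allele is the dataset reference allele, strand complements are
resolved, and palindromic (A/T, C/G) variants are dropped by default because
strand cannot be established without allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .containers import SUMMARY_COLUMNS, GenotypeDataset, validate_summary_frame

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: per-variant provenance flags
FLAG_DIRECT = "direct"
FLAG_SWAP = "allele_swap"
FLAG_STRAND = "strand_flip"
FLAG_STRAND_SWAP = "strand_flip_swap"
DROP_PALINDROMIC = "dropped_palindromic"
DROP_MISMATCH = "dropped_mismatch"
DROP_DUPLICATE = "dropped_duplicate"
DROP_UNMATCHED = "dropped_unmatched"


def _complement(allele: str) -> Optional[str]:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def is_palindromic(ea: str, oa: str) -> bool:
    return _complement(ea) == oa


@dataclass
class HarmonizedSet:
    """Matched, allele-aligned summary statistics for one genotype dataset.

    ``table`` columns: variant_id, chr, pos, counted_allele, other_allele,
    beta (aligned), se, p, n, flag; ``dataset_indices`` maps each row to its
    column in the dataset's dosage matrix. ``log`` counts every harmonization
    decision, including drops.
    """

    table: pd.DataFrame
    dataset_indices: np.ndarray
    log: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["variant_id"].duplicated().any():
            raise ValueError("harmonized set contains duplicate variants")
        if len(self.table) != len(self.dataset_indices):
            raise ValueError("table and dataset_indices must align")

    def __len__(self) -> int:
        return len(self.table)

    def to_summary_frame(self) -> pd.DataFrame:
        """Re-express as a canonical summary table (effect = counted allele)."""
        out = pd.DataFrame({
            "variant_id": self.table["variant_id"],
            "chr": self.table["chr"],
            "pos": self.table["pos"],
            "effect_allele": self.table["counted_allele"],
            "other_allele": self.table["other_allele"],
            "beta": self.table["beta"],
            "se": self.table["se"],
            "p": self.table["p"],
            "n": self.table["n"],
        }, columns=SUMMARY_COLUMNS)
        return validate_summary_frame(out)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def harmonize(
    stats: pd.DataFrame,
    ds: GenotypeDataset,
    drop_palindromic: bool = True,
) -> HarmonizedSet:
    """Match summary records to dataset variants and align effect alleles.

    Matching is by chr:pos primarily, with variant_id as a fallback for
    records whose position is absent or unmatched. Duplicate positions (on
    either side) are dropped rather than arbitrated. Allele resolution, in
    order: summary (EA, OA) equal to dataset (alt, ref) keeps the beta;
    equal to (ref, alt) negates it; the same two rules are retried after
    strand-complementing the summary alleles; anything else is dropped as a
    mismatch.
    """
    if len(stats) == 0 or ds.n_variants == 0:
        raise ValueError("harmonize requires non-empty summary statistics and genotypes")
    log: Dict[str, int] = {k: 0 for k in (
        FLAG_DIRECT, FLAG_SWAP, FLAG_STRAND, FLAG_STRAND_SWAP,
        DROP_PALINDROMIC, DROP_MISMATCH, DROP_DUPLICATE, DROP_UNMATCHED,
    )}

    vt = ds.variants
    ds_keys = vt["chr"].astype(str) + ":" + vt["pos"].astype(str)
    dup_ds_pos = set(ds_keys[ds_keys.duplicated(keep=False)])
    by_pos: Dict[str, int] = {}
    by_id: Dict[str, int] = {}
    dup_ds_id = set(vt["variant_id"][vt["variant_id"].duplicated(keep=False)])
    for j, (key, vid) in enumerate(zip(ds_keys, vt["variant_id"])):
        if key not in dup_ds_pos:
            by_pos[key] = j
        if vid not in dup_ds_id:
            by_id[vid] = j

    stat_keys = stats["chr"].astype(str) + ":" + stats["pos"].astype(str)
    dup_stat_pos = set(stat_keys[stat_keys.duplicated(keep=False)])
    dup_stat_id = set(stats["variant_id"][stats["variant_id"].duplicated(keep=False)])

    rows = []
    indices = []
    claimed: set = set()
    for i, rec in enumerate(stats.itertuples(index=False)):
        key = f"{rec.chr}:{rec.pos}"
        if key in dup_stat_pos or rec.variant_id in dup_stat_id or key in dup_ds_pos:
            log[DROP_DUPLICATE] += 1
            continue
        j = by_pos.get(key)
        if j is None:
            j = by_id.get(rec.variant_id)
        if j is None:
            log[DROP_UNMATCHED] += 1
            continue
        if j in claimed:
            log[DROP_DUPLICATE] += 1
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if drop_palindromic and is_palindromic(ea, oa):
            log[DROP_PALINDROMIC] += 1
            continue
        ref, alt = vt.at[j, "ref"], vt.at[j, "alt"]
        flag, sign = None, 1.0
        if (ea, oa) == (alt, ref):
            flag, sign = FLAG_DIRECT, 1.0
        elif (ea, oa) == (ref, alt):
            flag, sign = FLAG_SWAP, -1.0
        else:
            cea, coa = _complement(ea), _complement(oa)
            if cea is not None and (cea, coa) == (alt, ref):
                flag, sign = FLAG_STRAND, 1.0
            elif cea is not None and (cea, coa) == (ref, alt):
                flag, sign = FLAG_STRAND_SWAP, -1.0
        if flag is None:
            log[DROP_MISMATCH] += 1
            continue
        log[flag] += 1
        claimed.add(j)
        rows.append((
            vt.at[j, "variant_id"], str(vt.at[j, "chr"]), int(vt.at[j, "pos"]),
            alt, ref, sign * rec.beta, rec.se, rec.p, rec.n, flag,
        ))
        indices.append(j)

    if not rows:
        raise ValueError("no variants could be matched between summary stats and genotypes")
    table = pd.DataFrame(rows, columns=[
        "variant_id", "chr", "pos", "counted_allele", "other_allele",
        "beta", "se", "p", "n", "flag",
    ])
    order = np.argsort(indices, kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    return HarmonizedSet(
        table=table, dataset_indices=np.asarray(indices)[order], log=log
    )


def _align_pair(recA, recB) -> Optional[float]:
    """Sign with which B's beta maps onto A's effect allele (None: no match)."""
    a = (recA.effect_allele, recA.other_allele)
    b = (recB.effect_allele, recB.other_allele)
    if b == a:
        return 1.0
    if b == a[::-1]:
        return -1.0
    cb = (_complement(b[0]), _complement(b[1]))
    if None not in cb:
        if cb == a:
            return 1.0
        if cb == a[::-1]:
            return -1.0
    return None


def sign_concordance(
    statsA: pd.DataFrame,
    statsB: pd.DataFrame,
    p_cutoff: Optional[float] = None,
) -> float:
    """Fraction of shared variants whose effect directions agree.

    Variants are matched by id, B's beta is aligned to A's effect allele
    (allele swap and strand complement handled; irreconcilable allele pairs
    skipped), and the concordant fraction is computed over variants with a
    defined, nonzero beta in both sets. With ``p_cutoff``, only variants
    nominally significant (P <= cutoff) in both sets count.
    """
    bmap = {r.variant_id: r for r in statsB.itertuples(index=False)}
    agree = total = 0
    for ra in statsA.itertuples(index=False):
        rb = bmap.get(ra.variant_id)
        if rb is None:
            continue
        if p_cutoff is not None and not (ra.p <= p_cutoff and rb.p <= p_cutoff):
            continue
        sign = _align_pair(ra, rb)
        if sign is None:
            continue
        ba, bb = ra.beta, sign * rb.beta
        if not (np.isfinite(ba) and np.isfinite(bb)) or ba == 0 or bb == 0:
            continue
        total += 1
        agree += int(np.sign(ba) == np.sign(bb))
    if total == 0:
        raise ValueError("no shared variants between the two summary sets")
    return agree / total
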