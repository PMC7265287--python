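"""Readers, writers and variant filters for the standard exchange formats.

Summary statistics arrive as whitespace/tab-delimited tables in one of
several column dialects; genotypes as VCF (GT or DS), PLINK BED/BIM/FAM or
Oxford GEN+SAMPLE with SNPTEST-style info files. All readers produce the
canonical containers of :mod:`prstune.containers`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    SUMMARY_COLUMNS,
    VARIANT_COLUMNS,
    GenotypeDataset,
    validate_summary_frame,
)

# ---------------------------------------------------------------------------
# summary statistics

# column-name synonym tables per dialect; "beta"/"or_" are alternatives
_DIALECTS: Dict[str, Dict[str, Sequence[str]]] = {
    "generic": {
        "variant_id": ("SNP", "variant_id", "rsid", "MarkerName", "ID"),
        "chr": ("CHR", "chr", "chromosome", "Chr"),
        "pos": ("POS", "pos", "BP", "position", "Position"),
        "effect_allele": ("EA", "effect_allele", "A1", "Allele1", "EFFECT_ALLELE"),
        "other_allele": ("NEA", "other_allele", "A2", "Allele2", "OTHER_ALLELE"),
        "beta": ("BETA", "beta", "Effect", "b"),
        "or_": ("OR", "or"),
        "se": ("SE", "se", "StdErr", "stderr"),
        "p": ("P", "p", "P-value", "pvalue", "P_VALUE", "Pvalue"),
        "n": ("N", "n", "N_SAMPLES", "TotalSampleSize", "Neff"),
    },
    # trans-ethnic consortium release style: odds ratios, upper-case names
    "diagram2014": {
        "variant_id": ("SNP",),
        "chr": ("CHROMOSOME",),
        "pos": ("POSITION",),
        "effect_allele": ("RISK_ALLELE",),
        "other_allele": ("OTHER_ALLELE",),
        "beta": (),
        "or_": ("OR",),
        "se": ("SE", "OR_SE"),
        "p": ("P_VALUE",),
        "n": ("N_SAMPLES",),
    },
    # European-ancestry meta-analysis style: log-OR effects
    "diagram2017": {
        "variant_id": ("MarkerName", "SNP"),
        "chr": ("Chr", "CHR"),
        "pos": ("Pos", "POS"),
        "effect_allele": ("Allele1",),
        "other_allele": ("Allele2",),
        "beta": ("Effect", "Beta"),
        "or_": (),
        "se": ("StdErr", "SE"),
        "p": ("P-value", "P"),
        "n": ("TotalSampleSize", "Neff", "N"),
    },
}

_REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "p")


def read_summary_stats(
    path,
    dialect: str = "generic",
    column_map: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Read a GWAS summary-statistics table into the canonical frame.

    ``dialect`` names a column-synonym table; ``column_map`` (canonical
    field -> file column) overrides it. Odds ratios are converted to
    ``beta = ln(OR)``. Rows whose required fields do not parse (or whose P
    falls outside (0, 1]) are dropped and counted in
    ``result.attrs["n_dropped"]``.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(_DIALECTS)}")
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    synonyms = _DIALECTS[dialect]
    colmap: Dict[str, str] = {}
    for field, names in synonyms.items():
        for name in names:
            if name in raw.columns:
                colmap[field] = name
                break
    if column_map:
        colmap.update(column_map)
    for field in _REQUIRED_FIELDS:
        if field not in colmap:
            raise ValueError(
                f"summary file is missing a column for {field!r} "
                f"(dialect {dialect!r}; header {list(raw.columns)})"
            )
    if "beta" not in colmap and "or_" not in colmap:
        raise ValueError("summary file has neither a beta nor an OR column")

    def _num(field, default=np.nan):
        if field not in colmap:
            return pd.Series(default, index=raw.index, dtype=float)
        return pd.to_numeric(raw[colmap[field]], errors="coerce")

    out = pd.DataFrame({
        "variant_id": raw[colmap["variant_id"]].astype(str).str.strip(),
        "chr": raw[colmap["chr"]].astype(str).str.strip() if "chr" in colmap
               else pd.Series("", index=raw.index),
        "pos": _num("pos"),
        "effect_allele": raw[colmap["effect_allele"]].astype(str).str.strip().str.upper(),
        "other_allele": raw[colmap["other_allele"]].astype(str).str.strip().str.upper(),
        "se": _num("se"),
        "p": _num("p"),
        "n": _num("n"),
    })
    if "beta" in colmap:
        out["beta"] = _num("beta")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["beta"] = np.log(_num("or_"))
    out = out[SUMMARY_COLUMNS]

    n_in = len(out)
    ok = (
        out["variant_id"].str.len().gt(0)
        & out["effect_allele"].str.len().gt(0)
        & out["other_allele"].str.len().gt(0)
        & (out["effect_allele"] != out["other_allele"])
        & out["p"].notna() & (out["p"] > 0) & (out["p"] <= 1)
        & (out["beta"].isna() | (out["se"] > 0))
    )
    out = out[ok].reset_index(drop=True)
    out["pos"] = out["pos"].fillna(-1).astype(int)
    if len(out) == 0:
        raise ValueError(f"no parsable summary-statistic rows in {path}")
    out.attrs["n_dropped"] = int(n_in - len(out))
    return validate_summary_frame(out)


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    """Write the canonical frame as TSV (SNP,CHR,POS,EA,NEA,BETA,SE,P,N)."""
    out = stats[SUMMARY_COLUMNS].copy()
    out.columns = ["SNP", "CHR", "POS", "EA", "NEA", "BETA", "SE", "P", "N"]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant filters

def filter_info(
    ds: GenotypeDataset,
    threshold: float = 0.7,
    missing_passes: bool = True,
) -> GenotypeDataset:
    """Keep variants with imputation info score >= threshold (inclusive).

    Variants without an info score pass by default (with a warning), since
    directly genotyped variants carry none.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("info-score threshold must lie in [0, 1]")
    info = ds.variants["info_score"].to_numpy(dtype=float)
    missing = np.isnan(info)
    if missing.any() and missing_passes:
        warnings.warn(
            f"{int(missing.sum())} variants lack an info score and were kept",
            stacklevel=2,
        )
    keep = np.where(missing, missing_passes, info >= threshold)
    return ds.take_variants(np.where(keep)[0])


def filter_sample_size(stats: pd.DataFrame, floor_fraction: float) -> pd.DataFrame:
    """Keep records tested in at least ``floor_fraction`` x max(N) samples.

    ``floor_fraction = 0`` encodes the "all variants" level and is the
    identity. The boundary is inclusive (>=), matching the sample-size
    floors of 85/90/95/98% of the maximum per-variant N.
    """
    if not (0 <= floor_fraction <= 1):
        raise ValueError("floor_fraction must lie in [0, 1]")
    if floor_fraction == 0:
        return stats.reset_index(drop=True)
    n = stats["n"].to_numpy(dtype=float)
    if np.isnan(n).all():
        raise ValueError("no per-variant sample sizes present; cannot apply N floor")
    floor = floor_fraction * np.nanmax(n)
    keep = n >= floor  # NaN compares False: records without N are dropped
    return stats[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field.

    Hard-call dosages also get a GT field; the imputation info score is
    stored in the INFO column as ``INFO=<x>``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        for chrom in pd.unique(ds.variants["chr"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in ds.sample_ids) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(ds.variants.itertuples(index=False)):
            info = "." if pd.isna(v.info_score) else f"INFO={v.info_score:g}"
            fields = [str(v.chr), str(v.pos), str(v.variant_id), v.ref, v.alt,
                      ".", "PASS", info, "GT:DS"]
            col = ds.dosages[:, j]
            cells = []
            for d in col:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = gts.get(int(round(d)), "./.") if abs(d - round(d)) < 1e-9 else "./."
                    cells.append(f"{gt}:{d:g}")
            fh.write("\t".join(fields + cells) + "\n")


def _read_vcf_text(path, field: str) -> GenotypeDataset:
    samples, rows, cols = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            info_score = np.nan
            for kv in parts[7].split(";"):
                if kv.startswith("INFO="):
                    info_score = float(kv[5:])
            fmt = parts[8].split(":")
            try:
                fi = fmt.index(field)
            except ValueError:
                fi = None
            dos = np.full(len(samples), np.nan)
            for i, cell in enumerate(parts[9:]):
                sub = cell.split(":")
                if field == "DS" and fi is not None and fi < len(sub) and sub[fi] not in (".", ""):
                    dos[i] = float(sub[fi])
                elif field == "GT":
                    gt = sub[fmt.index("GT")] if "GT" in fmt else "./."
                    alleles = gt.replace("|", "/").split("/")
                    if "." not in alleles:
                        dos[i] = sum(int(a) for a in alleles)
            rows.append((vid, chrom, pos, ref, alt, info_score))
            cols.append(dos)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeDataset(
        sample_ids=np.array(samples, dtype=object), variants=variants, dosages=dosages
    )


def read_vcf(path, field: str = "DS") -> GenotypeDataset:
    """Read a VCF into dosages; ``field`` selects DS or GT."""
    if field not in ("DS", "GT"):
        raise ValueError("field must be 'DS' or 'GT'")
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is an optional accelerator
        return _read_vcf_text(path, field)
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    rows, cols = [], []
    for v in vcf:
        info_score = v.INFO.get("INFO")
        rows.append((
            v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), int(v.POS),
            v.REF, v.ALT[0] if v.ALT else ".",
            np.nan if info_score is None else float(info_score),
        ))
        if field == "DS":
            ds_arr = v.format("DS")
            if ds_arr is None:
                cols.append(np.full(len(samples), np.nan))
            else:
                col = ds_arr.astype(float).reshape(-1)
                col[col < 0] = np.nan
                cols.append(col)
        else:
            gt = np.array(v.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            cols.append(col)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeDataset(sample_ids=samples, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM (SNP-major 2-bit codec)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def write_plink(ds: GenotypeDataset, prefix) -> None:
    """Write hard-call dosages as PLINK BED/BIM/FAM (A1 = alt allele)."""
    prefix = Path(prefix)
    bim = ds.variants[["chr", "variant_id", "pos", "alt", "ref"]].copy()
    bim.insert(2, "cm", 0)
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame({
        "fid": ds.sample_ids, "iid": ds.sample_ids,
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)
    n = ds.n_samples
    # codes index by A1 dosage: 0 copies -> 0b11, 1 -> 0b10, 2 -> 0b00, missing -> 0b01
    code_for = {0: 0b11, 1: 0b10, 2: 0b00}
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        nbytes = (n + 3) // 4
        for j in range(ds.n_variants):
            col = ds.dosages[:, j]
            buf = bytearray(nbytes)
            for i, d in enumerate(col):
                code = 0b01 if np.isnan(d) else code_for[int(round(d))]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


def read_plink(prefix) -> GenotypeDataset:
    """Read PLINK BED/BIM/FAM; dosages count the BIM A1 allele (stored as alt)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chr", "variant_id", "cm", "pos", "a1", "a2"], dtype={"chr": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK BED file")
    nbytes = (n + 3) // 4
    body = raw[3:].reshape(m, nbytes)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, nbytes * 4)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])  # 00 hom-A1, 01 missing, 10 het, 11 hom-A2
    dosages = lut[codes].T
    variants = pd.DataFrame({
        "variant_id": bim["variant_id"].astype(str),
        "chr": bim["chr"].astype(str),
        "pos": bim["pos"].astype(int),
        "ref": bim["a2"].astype(str),
        "alt": bim["a1"].astype(str),
        "info_score": np.nan,
    })
    return GenotypeDataset(
        sample_ids=fam["iid"].astype(str).to_numpy(dtype=object),
        variants=variants, dosages=dosages,
    )


# ---------------------------------------------------------------------------
# Oxford GEN + SAMPLE (+ SNPTEST-style info file)

def write_gen(ds: GenotypeDataset, prefix) -> None:
    """Write hard-call dosages as Oxford GEN/SAMPLE plus an info file."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".gen"), "w") as fh:
        for j, v in enumerate(ds.variants.itertuples(index=False)):
            fields = [str(v.chr), str(v.variant_id), str(v.pos), v.ref, v.alt]
            for d in ds.dosages[:, j]:
                if np.isnan(d):
                    fields += ["0", "0", "0"]
                else:
                    probs = ["0", "0", "0"]
                    probs[int(round(d))] = "1"
                    fields += probs
            fh.write(" ".join(fields) + "\n")
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in ds.sample_ids:
            fh.write(f"{s} {s} 0\n")
    info = ds.variants[["variant_id", "info_score"]].copy()
    info.columns = ["rsid", "info"]
    info.to_csv(prefix.with_suffix(".info"), sep=" ", index=False)


def read_gen(prefix) -> GenotypeDataset:
    """Read Oxford GEN/SAMPLE; alt dosage = P(het) + 2 P(hom-alt)."""
    prefix = Path(prefix)
    sample = pd.read_csv(prefix.with_suffix(".sample"), sep=r"\s+", skiprows=[1])
    sample_ids = sample["ID_2"].astype(str).to_numpy(dtype=object)
    n = len(sample_ids)
    rows, cols = [], []
    with open(prefix.with_suffix(".gen")) as fh:
        for line in fh:
            parts = line.split()
            chrom, vid, pos, ref, alt = parts[:5]
            probs = np.array(parts[5:], dtype=float).reshape(n, 3)
            total = probs.sum(axis=1)
            dos = np.where(total > 0, probs[:, 1] + 2 * probs[:, 2], np.nan)
            rows.append((vid, chrom, int(pos), ref, alt, np.nan))
            cols.append(dos)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    info_path = prefix.with_suffix(".info")
    if info_path.exists():
        info = pd.read_csv(info_path, sep=r"\s+")
        lookup = dict(zip(info["rsid"].astype(str), info["info"]))
        variants["info_score"] = [lookup.get(v, np.nan) for v in variants["variant_id"]]
    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    return GenotypeDataset(sample_ids=sample_ids, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# small TSV sidecars

def write_phenotype(path, sample_ids, status, fasting=None, two_hour=None) -> None:
    tab = pd.DataFrame({"IID": sample_ids, "STATUS": status})
    tab["FPG"] = fasting if fasting is not None else np.nan
    tab["PG2H"] = two_hour if two_hour is not None else np.nan
    tab.to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"IID": str})


def write_truth(path, variant_ids, causal_mask, true_beta) -> None:
    pd.DataFrame({
        "variant": variant_ids, "causal": np.asarray(causal_mask).astype(int),
        "true_beta": true_beta,
    }).to_csv(path, sep="\t", index=False)


def read_populations(path) -> pd.DataFrame:
    """Two-column TSV (sample, population) labelling panel samples."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if list(tab.columns[:2]) != ["sample", "population"]:
        tab.columns = ["sample", "population"] + list(tab.columns[2:])
    return tab
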