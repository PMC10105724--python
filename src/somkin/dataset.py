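"""Compiled kinetics table: read/write, validation, gap filling, summaries.

One row of the table is one fitted incubation record — site coordinates and
covariates, the pool model variant (M1/M2/M3), fitted fractions f1..f3 and
rates k1..k3 (stored in d^-1), and fit diagnostics — mirroring the schema of
a literature synthesis of laboratory soil incubations.

Missing values are empty cells (never 0 or -999).  Rows failing validation
are collected in a reject report with row numbers and reasons, not silently
dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as _metrics

__all__ = ["SCHEMA_COLUMNS", "REFERENCE_MODELS", "read_table", "write_table",
           "validate_table", "fill_missing_covariates", "pool_comparison"]

#: canonical column order of the compiled table
SCHEMA_COLUMNS = [
    "record_id", "source_id", "latitude", "longitude", "Elev", "MAP", "MAT",
    "ecosystem", "Sand", "Silt", "Clay", "pH", "moisture", "IncT", "duration",
    "measured", "model_type", "f1", "f2", "f3", "k1", "k2", "k3",
    "r2_fit", "rmse_fit", "aic_fit", "bic_fit", "MBC", "SOC", "NDVI", "Slope",
]

_MANDATORY = ["record_id", "model_type", "f1", "k1"]

#: per-pool reference decomposition rates (d^-1) of four standard SOM models
REFERENCE_MODELS = {
    "ANIMO":   {"pools": 2, "k": (5.5e-3, 6.0e-4)},
    "DAISY":   {"pools": 2, "k": (5.0e-2, 5.0e-3)},
    "CLMcn":   {"pools": 3, "k": (7.1e-2, 1.4e-3, 1.0e-4)},
    "DAYCENT": {"pools": 3, "k": (3.0e-2, 1.1e-3, 9.0e-6)},
}

_KNOWN_UNITS = {"d-1": 1.0, "per_day": 1.0, "yr-1": 1.0 / 365.0,
                "per_year": 1.0 / 365.0}


def read_table(path, k_unit: str = "d-1", column_map: dict | None = None):
    """Read and validate a compiled kinetics table from CSV.

    ``k_unit`` applies to all rate columns unless the file carries a per-row
    ``k_unit`` column; rates are harmonized to d^-1 (yr^-1 divides by 365).
    ``column_map`` renames source columns to the canonical schema.

    Returns ``(records, rejects)``: the validated table and a reject report
    (row, reason).  Unknown units or missing mandatory columns are hard
    errors.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    if "k_unit" in df.columns:
        factors = df["k_unit"].map(_KNOWN_UNITS)
        if factors.isna().any():
            bad = sorted(df.loc[factors.isna(), "k_unit"].unique())
            raise ValueError(f"unknown rate units: {bad}")
        df = df.drop(columns=["k_unit"])
    else:
        if k_unit not in _KNOWN_UNITS:
            raise ValueError(f"unknown rate unit {k_unit!r}")
        factors = pd.Series(_KNOWN_UNITS[k_unit], index=df.index)
    for c in ("k1", "k2", "k3"):
        if c in df.columns:
            df[c] = df[c] * factors
    return validate_table(df)


def write_table(records: pd.DataFrame, path):
    """Write the table as CSV with empty cells for missing values."""
    cols = [c for c in SCHEMA_COLUMNS if c in records.columns] + \
        [c for c in records.columns if c not in SCHEMA_COLUMNS]
    records[cols].to_csv(path, index=False)


def validate_table(df: pd.DataFrame):
    """Validate records; derive implied fractions; split off rejects.

    * f2 = 1 - f1 (M2) and f3 = 1 - f1 - f2 (M3) are recomputed when absent.
    * Present fractions must sum to 1 within 1e-6; rates positive and
      descending; coordinates in range; Sand+Silt+Clay within 2 of 100.
    """
    df = df.copy().reset_index(drop=True)
    for c in ("f2", "f3", "k2", "k3", "latitude", "longitude",
              "Sand", "Silt", "Clay"):
        if c not in df.columns:
            df[c] = np.nan
    # derive the closing fraction
    m2 = df["model_type"] == "M2"
    m3 = df["model_type"] == "M3"
    df.loc[m2 & df["f2"].isna(), "f2"] = 1.0 - df.loc[m2, "f1"]
    need = m3 & df["f3"].isna() & df["f1"].notna() & df["f2"].notna()
    df.loc[need, "f3"] = 1.0 - df.loc[need, "f1"] - df.loc[need, "f2"]

    reasons = []
    for i, row in df.iterrows():
        why = []
        mt = row["model_type"]
        if mt not in ("M1", "M2", "M3"):
            why.append(f"unknown model_type {mt!r}")
        else:
            npools = int(mt[1])
            fs = [row.get(f"f{j}") for j in range(1, npools + 1)]
            ks = [row.get(f"k{j}") for j in range(1, npools + 1)]
            if any(pd.isna(v) for v in fs):
                why.append("missing pool fraction")
            elif abs(sum(fs) - 1.0) > 1e-6:
                why.append(f"fractions sum to {sum(fs):.6g}")
            elif any(not 0 <= v <= 1 for v in fs):
                why.append("fraction outside [0,1]")
            if any(pd.isna(v) for v in ks):
                why.append("missing rate")
            elif any(v <= 0 for v in ks):
                why.append("non-positive rate")
            elif any(ks[j] <= ks[j + 1] for j in range(npools - 1)):
                why.append("rates not descending")
        lat, lon = row["latitude"], row["longitude"]
        if pd.notna(lat) and not -90 <= lat <= 90:
            why.append("latitude out of range")
        if pd.notna(lon) and not -180 <= lon <= 180:
            why.append("longitude out of range")
        tex = row[["Sand", "Silt", "Clay"]]
        if tex.notna().all() and abs(tex.sum() - 100.0) > 2.0:
            why.append(f"texture sums to {tex.sum():.3g}")
        if why:
            reasons.append({"row": i, "record_id": row.get("record_id"),
                            "reason": "; ".join(why)})
    rejects = pd.DataFrame(reasons, columns=["row", "record_id", "reason"])
    keep = ~df.index.isin(rejects["row"])
    return df[keep].reset_index(drop=True), rejects


def fill_missing_covariates(records: pd.DataFrame, rasters: dict) -> pd.DataFrame:
    """Fill missing covariate cells from rasters at the site coordinates.

    Sampling uses the nearest cell center; present values are never
    overwritten.  Each filled covariate gains a boolean ``<name>_gap_filled``
    column; sites outside a raster's extent stay missing (flag False).
    """
    out = records.copy()
    lat = out["latitude"].to_numpy(float)
    lon = out["longitude"].to_numpy(float)
    for name, raster in rasters.items():
        if name not in out.columns:
            continue
        flag = np.zeros(len(out), dtype=bool)
        miss = out[name].isna().to_numpy()
        if miss.any():
            sampled = raster.sample(lat[miss], lon[miss])
            got = np.isfinite(sampled)
            vals = out[name].to_numpy(float)
            vals[np.where(miss)[0][got]] = sampled[got]
            out[name] = vals
            flag[np.where(miss)[0][got]] = True
        out[f"{name}_gap_filled"] = flag
    return out


def pool_comparison(records: pd.DataFrame) -> dict:
    """Distribution summary of kinetics parameters by model variant.

    Returns medians with 50% and 90% CIs per (model_type, parameter), the
    Kruskal-Wallis test between the two- and three-pool groups for the shared
    rates, and whether each standard model's reference rates fall within the
    corresponding 50% CI.
    """
    rows = []
    for mt, grp in records.groupby("model_type"):
        npools = int(mt[1]) if mt[1].isdigit() else 0
        for par in [f"k{j}" for j in range(1, npools + 1)] + \
                   [f"f{j}" for j in range(1, npools + 1)]:
            vals = grp[par].dropna()
            if len(vals) < 2:
                continue
            s = _metrics.quantile_summary(vals)
            rows.append({"model_type": mt, "parameter": par,
                         "n": len(vals), "median": s["median"],
                         "ci50_low": s["ci50"][0], "ci50_high": s["ci50"][1],
                         "ci90_low": s["ci90"][0], "ci90_high": s["ci90"][1]})
    summary = pd.DataFrame(rows)

    kw = {}
    have = set(records["model_type"].unique())
    if {"M2", "M3"} <= have:
        for par in ("k1", "k2"):
            a = records.loc[records["model_type"] == "M2", par].dropna()
            b = records.loc[records["model_type"] == "M3", par].dropna()
            if len(a) >= 2 and len(b) >= 2:
                kw[par] = _metrics.kruskal_wallis([a, b])
    else:
        kw["notice"] = "both M2 and M3 required for the between-model test"

    checks = []
    for name, ref in REFERENCE_MODELS.items():
        mt = f"M{ref['pools']}"
        for j, kref in enumerate(ref["k"], start=1):
            row = summary[(summary["model_type"] == mt)
                          & (summary["parameter"] == f"k{j}")]
            if row.empty:
                continue
            lo, hi = row.iloc[0][["ci50_low", "ci50_high"]]
            checks.append({"model": name, "parameter": f"k{j}",
                           "k_ref": kref,
                           "within_ci50": bool(lo <= kref <= hi)})
    return {"summary": summary, "kw": kw,
            "reference_checks": pd.DataFrame(checks)}
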