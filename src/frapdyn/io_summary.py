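"""Fit/tip table ingestion and the descriptive statistics reported for them.

The published per-experiment results ship with the package as CSV fixtures:
``table1_cytoplasm_fits.csv`` holds the cytoplasmic (D, beta) fits for GFP
and huDysGFP under the different fit windows and model geometries, and
``table2``..``table5`` hold the per-tip statistics for the four experimental
groups (huDysGFP in wild-type, huDysGFP in dmd^ta222a/ta222a and siblings,
zfDysGFP, and endogenously driven zfDysCitrine).

Statistics are deliberately descriptive only: means, ranges, sample
standard deviations and Pearson correlations. SD uses the n-1 convention.
Rounding happens only at display time; stored values keep full precision.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .tips import RECOVERY_CLASSES

__all__ = [
    "load_fit_table",
    "load_tip_table",
    "summarize_D",
    "summarize_tips",
    "pearson_pairs",
    "TIP_TABLES",
]

logger = logging.getLogger("frapdyn")

TIP_TABLES = {
    "hudysgfp_wt": "table2_hudysgfp_wt_tips.csv",
    "hudysgfp_dmd": "table3_hudysgfp_dmd_tips.csv",
    "zfdysgfp": "table4_zfdysgfp_tips.csv",
    "zfdyscitrine": "table5_zfdyscitrine_tips.csv",
}

_VALID_WIDTHS = {4, 8, 10, 16, 20, 32}
_VALID_FINAL_POINTS = {50, 200, 500}


def _data_path(name: str):
    return resources.files("frapdyn.data").joinpath(name)


def load_fit_table(path=None) -> pd.DataFrame:
    """Load a cytoplasmic fit table (packaged fixture by default)."""
    src = path if path is not None else _data_path("table1_cytoplasm_fits.csv")
    df = pd.read_csv(src)
    bad_w = set(df["bleach_width_px"]) - _VALID_WIDTHS
    if bad_w:
        raise ValueError(f"unexpected bleach widths {sorted(bad_w)}")
    bad_p = set(df["final_fitted_point"]) - _VALID_FINAL_POINTS
    if bad_p:
        raise ValueError(f"unexpected final fitted points {sorted(bad_p)}")
    return df


def load_tip_table(which: str = "hudysgfp_wt", path=None) -> pd.DataFrame:
    """Load a tip table fixture (or a user CSV with the same schema).

    Rows with a recovery class outside the closed vocabulary are rejected
    with a logged message.
    """
    if path is None:
        if which not in TIP_TABLES:
            raise KeyError(f"unknown tip table {which!r}; options: {sorted(TIP_TABLES)}")
        src = _data_path(TIP_TABLES[which])
    else:
        src = path
    df = pd.read_csv(src)
    bad = ~df["recovery_class"].isin(RECOVERY_CLASSES)
    if bad.any():
        for _, row in df[bad].iterrows():
            logger.warning("rejecting tip %s: unknown recovery class %r",
                           row.get("tip"), row["recovery_class"])
        df = df[~bad].reset_index(drop=True)
    return df


def summarize_D(table: pd.DataFrame, label: str | None = None,
                final_point: int | None = 200,
                geometry: str | None = "standard") -> dict:
    """Mean / min / max of D over the selected fit rows.

    The headline diffusion constants are obtained from the two-parameter
    fits to time point 200 with the standard model geometry, which is the
    default filter.
    """
    sel = table
    if label is not None:
        sel = sel[sel["label"] == label]
    if final_point is not None:
        sel = sel[sel["final_fitted_point"] == final_point]
    if geometry is not None:
        sel = sel[sel["geometry"] == geometry]
    if sel.empty:
        raise ValueError("selection matches no rows")
    d = sel["D_um2_per_s"].to_numpy(dtype=float)
    return {"mean": float(d.mean()), "min": float(d.min()),
            "max": float(d.max()), "n": int(d.size)}


def summarize_tips(table: pd.DataFrame, groups: list[str] | None = None) -> dict:
    """Per-group descriptive statistics of the tip metrics.

    Returns, per group: mean and sample SD (n-1) of the final normalized
    unbleached-minus-bleached difference, mean fractional recovery, n, and
    the recovery-class counts. A ``display`` entry holds values rounded to
    the tables' precision without altering the stored full-precision ones.
    """
    if groups is None:
        groups = list(dict.fromkeys(table["group"]))
    out = {}
    for g in groups:
        sel = table[table["group"] == g]
        if sel.empty:
            raise ValueError(f"group {g!r} matches no rows")
        fd = sel["final_unbleached_minus_bleached"].to_numpy(dtype=float)
        fr = sel["fractional_recovery"].to_numpy(dtype=float)
        counts = sel["recovery_class"].value_counts().to_dict()
        out[g] = {
            "mean_final_diff": float(fd.mean()),
            "sd_final_diff": float(fd.std(ddof=1)) if fd.size > 1 else 0.0,
            "mean_fractional_recovery": float(fr.mean()),
            "n": int(fd.size),
            "class_counts": counts,
            "display": {
                "mean_final_diff": round(float(fd.mean()), 2),
                "sd_final_diff": round(float(fd.std(ddof=1)), 2) if fd.size > 1 else 0.0,
            },
        }
    return out


def pearson_pairs(table: pd.DataFrame, label: str = "huDysGFP",
                  final_point: int = 200, geometry: str = "standard") -> dict:
    """Pearson R of same-cell (narrow D, wide D) pairs.

    Cells contributing a single experiment under the filter are excluded
    (logged). Requires at least 3 complete pairs.
    """
    sel = table[(table["label"] == label)
                & (table["final_fitted_point"] == final_point)
                & (table["geometry"] == geometry)]
    narrow, wide = [], []
    for cell, grp in sel.groupby("cell"):
        if len(grp) < 2:
            logger.info("cell %s has a single experiment; excluded from pairing", cell)
            continue
        grp = grp.sort_values("bleach_width_px")
        narrow.append(float(grp["D_um2_per_s"].iloc[0]))
        wide.append(float(grp["D_um2_per_s"].iloc[-1]))
    if len(narrow) < 3:
        raise ValueError("need at least 3 complete narrow/wide pairs")
    r = float(pearsonr(narrow, wide).statistic)
    return {"R": r, "n": len(narrow),
            "pairs": list(zip(narrow, wide))}
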