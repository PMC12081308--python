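"""Targeted-metabolomics post-processing.

The chain a targeted GC-MS / LC-MS workflow applies after peak
integration: analyte peak areas are divided by their mapped isotope-
labelled internal standard (removing per-sample instrument variation),
converted to concentrations against a dilution-series calibration curve,
divided by per-sample protein content (removing cell-amount variation),
and finally compared between groups as fold changes with unpaired
two-sided t-tests.

Tables are tidy DataFrames: one row per (sample, analyte) with columns
``sample``, ``group``, ``analyte``, ``area``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CalibrationCurve",
    "is_normalize",
    "calibrate_concentrations",
    "protein_normalize",
    "differential_metabolites",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float


def is_normalize(
    t: pd.DataFrame,
    is_map: Mapping[str, str],
    is_areas: pd.DataFrame,
) -> pd.DataFrame:
    """Divide each analyte area by its internal standard's area in the same sample.

    ``is_map`` maps analyte -> internal-standard id; ``is_areas`` is a tidy
    table (sample, standard, area). Zero IS areas propagate as missing
    values with a warning. The result is invariant to any global per-sample
    scaling of all areas.
    """
    missing = set(t["analyte"]) - set(is_map)
    if missing:
        raise ValueError(f"analytes without internal standard mapping: {sorted(missing)}")
    is_lookup = is_areas.set_index(["sample", "standard"])["area"]
    out = t.copy()
    std = out["analyte"].map(is_map)
    denom = pd.Series(
        [is_lookup.get((s, st), np.nan) for s, st in zip(out["sample"], std)],
        index=out.index,
        dtype=float,
    )
    if denom.isna().any():
        raise ValueError("internal-standard area missing for some (sample, standard) pairs")
    zero = denom == 0
    if zero.any():
        log.warning("%d rows have zero internal-standard area; set to missing", int(zero.sum()))
    out["normalized_area"] = np.where(zero, np.nan, out["area"] / denom.replace(0, np.nan))
    return out


def calibrate_concentrations(
    t: pd.DataFrame,
    standards: pd.DataFrame,
    value_col: str = "normalized_area",
    fit_intercept: bool = True,
) -> tuple[pd.DataFrame, dict[str, CalibrationCurve]]:
    """Concentrations from an ordinary-least-squares dilution-series fit.

    ``standards`` has columns (analyte, concentration, area) with >= 3
    levels per analyte. Concentration = (area - intercept) / slope;
    analytes whose fitted slope is <= 0 are rejected (their concentrations
    left missing). Samples outside the calibrated concentration range are
    flagged in an ``out_of_range`` column.
    """
    curves: dict[str, CalibrationCurve] = {}
    out = t.copy()
    out["concentration"] = np.nan
    out["out_of_range"] = False
    for analyte, grp in standards.groupby("analyte", sort=False):
        if len(grp) < 3:
            raise ValueError(f"dilution series for {analyte} has fewer than 3 levels")
        if fit_intercept:
            fit = stats.linregress(grp["concentration"], grp["area"])
            slope, intercept = float(fit.slope), float(fit.intercept)
            r2 = float(fit.rvalue**2)
        else:
            x = grp["concentration"].to_numpy(float)
            y = grp["area"].to_numpy(float)
            slope = float(x @ y / (x @ x))
            intercept = 0.0
            ss_res = float(((y - slope * x) ** 2).sum())
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if slope <= 0:
            log.warning("calibration rejected for %s: slope %.3g <= 0", analyte, slope)
            continue
        lo, hi = float(grp["concentration"].min()), float(grp["concentration"].max())
        curves[analyte] = CalibrationCurve(analyte, slope, intercept, r2, lo, hi)
        rows = out["analyte"] == analyte
        conc = (out.loc[rows, value_col] - intercept) / slope
        out.loc[rows, "concentration"] = conc
        out.loc[rows, "out_of_range"] = (conc < lo) | (conc > hi)
    return out, curves


def protein_normalize(
    t: pd.DataFrame,
    protein: Mapping[str, float],
    value_col: str = "normalized_area",
) -> pd.DataFrame:
    """Divide values by the sample's protein content (micrograms)."""
    missing = set(t["sample"]) - set(protein)
    if missing:
        raise ValueError(f"samples without protein measurement: {sorted(missing)}")
    bad = [s for s, p in protein.items() if p <= 0]
    if bad:
        raise ValueError(f"non-positive protein content for samples: {bad}")
    out = t.copy()
    out[value_col + "_per_protein"] = out[value_col] / out["sample"].map(protein)
    return out


def differential_metabolites(
    t: pd.DataFrame,
    control_group: str,
    value_col: str = "normalized_area",
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-analyte log2 fold change and two-sided unpaired t-test p value.

    Fold change is mean(treated)/mean(control) per analyte (the control
    group average is the reference). Equal-variance Student's t by default;
    ``welch=True`` selects the unequal-variance form. Analytes with fewer
    than two finite values in either group are skipped; control means <= 0
    leave the fold change missing with a warning. ``fdr=True`` appends
    Benjamini-Hochberg adjusted p values.
    """
    groups = t["group"].unique()
    treated_groups = [g for g in groups if g != control_group]
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present")
    if len(treated_groups) != 1:
        raise ValueError(f"expected exactly one treated group, found {treated_groups}")
    treated_group = treated_groups[0]
    records = []
    for analyte, grp in t.groupby("analyte", sort=False):
        ctrl = grp.loc[grp["group"] == control_group, value_col].dropna().to_numpy(float)
        trt = grp.loc[grp["group"] == treated_group, value_col].dropna().to_numpy(float)
        if len(ctrl) < 2 or len(trt) < 2:
            log.warning("analyte %s skipped: fewer than 2 finite values per group", analyte)
            continue
        cmean = ctrl.mean()
        if cmean <= 0:
            log.warning("analyte %s: control mean <= 0; fold change missing", analyte)
            log2fc = np.nan
        else:
            ratio = trt.mean() / cmean
            log2fc = np.log2(ratio) if ratio > 0 else np.nan
        res = stats.ttest_ind(trt, ctrl, equal_var=not welch)
        records.append(
            {
                "analyte": analyte,
                "mean_control": cmean,
                "mean_treated": trt.mean(),
                "log2fc": log2fc,
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame.from_records(
        records, columns=["analyte", "mean_control", "mean_treated", "log2fc", "p_value"]
    )
    if fdr and len(out):
        out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
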