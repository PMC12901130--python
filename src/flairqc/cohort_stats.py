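"""Cohort-level statistics: device effects on observed quality and the
correlation between observed quality and each technical QC parameter.

The cohort table has one row per rated study (device, estimate P with its
binomial SD, and the ten QC parameters).  Statistics follow standard
practice for a multi-scanner comparison: Shapiro-Wilk normality of P per
device, one-way fixed-effects ANOVA of P across devices, Tukey HSD for
pairwise device differences, and R^2 (squared Pearson correlation of a
simple linear fit) between P and each parameter, both per study and on
device medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: QC parameter columns correlated against estimate P, in report order
QC_PARAMS = [
    "qi",
    "contrast",
    "noise_sd",
    "cnr",
    "mtf10_fh",
    "mtf10_ap",
    "mtf10_rl",
    "mtf50_fh",
    "mtf50_ap",
    "mtf50_rl",
]


def build_table(ratings: pd.DataFrame, qc: pd.DataFrame) -> pd.DataFrame:
    """Join per-study ratings (study_id, device_id?, p, sd) with QC rows."""
    cols = [c for c in qc.columns if c != "device_id" or "device_id" not in ratings.columns]
    table = ratings.merge(qc[cols], on="study_id", how="inner")
    if table.empty:
        raise ValueError("no studies shared between ratings and QC tables")
    return table


def shapiro_per_device(table: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Shapiro-Wilk statistic and p for each device's P sample.

    Devices with fewer than ``min_n`` rated studies or zero variance are
    flagged and carry NaN statistics.
    """
    rows = []
    for device, grp in table.groupby("device_id", sort=True):
        p = grp["p"].to_numpy(dtype=float)
        flag = ""
        stat = pval = np.nan
        if p.size < min_n:
            flag = f"fewer than {min_n} rated studies"
        elif np.ptp(p) == 0:
            flag = "zero variance"
        else:
            stat, pval = stats.shapiro(p)
        rows.append({"device_id": device, "n": p.size, "w": stat, "p_value": pval, "flag": flag})
    return pd.DataFrame(rows)


def _device_samples(table: pd.DataFrame, min_per_group: int = 2):
    devices, samples = [], []
    for device, grp in table.groupby("device_id", sort=True):
        x = grp["p"].to_numpy(dtype=float)
        if x.size >= min_per_group:
            devices.append(device)
            samples.append(x)
    return devices, samples


def anova_by_device(table: pd.DataFrame) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA of estimate P across devices."""
    devices, samples = _device_samples(table)
    if len(devices) < 2:
        raise ValueError("ANOVA needs at least 2 devices with >= 2 rated studies each")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def tukey_hsd(table: pd.DataFrame) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for every device pair (symmetric matrix).

    Unequal group sizes use the Tukey-Kramer harmonic-mean form (as in
    :func:`scipy.stats.tukey_hsd`); the diagonal is NaN.
    """
    devices, samples = _device_samples(table)
    if len(devices) < 2:
        raise ValueError("Tukey HSD needs at least 2 devices with >= 2 rated studies each")
    res = stats.tukey_hsd(*samples)
    mat = pd.DataFrame(res.pvalue, index=devices, columns=devices)
    np.fill_diagonal(mat.values, np.nan)
    return mat


def r2_table(table: pd.DataFrame, level: str = "study") -> pd.Series:
    """R^2 between estimate P and each QC parameter.

    ``level='study'`` correlates per study; ``level='device_median'``
    collapses both variables to their within-device medians first.
    Non-finite parameter values (e.g. unmeasurable MTF thresholds) are
    excluded pairwise; constant parameters yield NaN.
    """
    if level not in ("study", "device_median"):
        raise ValueError("level must be 'study' or 'device_median'")
    out = {}
    for param in QC_PARAMS:
        if param not in table.columns:
            out[param] = np.nan
            continue
        sub = table[["device_id", "p", param]].replace([np.inf, -np.inf], np.nan).dropna()
        if level == "device_median":
            sub = sub.groupby("device_id", sort=True).median(numeric_only=True).reset_index()
        x = sub[param].to_numpy(dtype=float)
        y = sub["p"].to_numpy(dtype=float)
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[param] = np.nan
            continue
        r, _ = stats.pearsonr(x, y)
        out[param] = float(r * r)
    return pd.Series(out, name=f"r2_by_{level}")


@dataclass
class StatReport:
    """All cohort statistics; sections are None when not computable."""

    shapiro: pd.DataFrame
    anova_f: float | None
    anova_p: float | None
    tukey: pd.DataFrame | None
    r2: pd.DataFrame
    device_summary: pd.DataFrame
    study_scatter: pd.DataFrame
    device_scatter: pd.DataFrame


def build_report(table: pd.DataFrame) -> StatReport:
    """Assemble the full report from a cohort table.

    With a single device the ANOVA/Tukey sections and the device-median
    R^2 column are absent; everything else is still produced.
    """
    n_devices = table["device_id"].nunique()
    shapiro = shapiro_per_device(table)

    anova_f = anova_p = None
    tukey = None
    if n_devices >= 2:
        try:
            anova_f, anova_p = anova_by_device(table)
            tukey = tukey_hsd(table)
        except ValueError:
            pass

    r2_study = r2_table(table, "study")
    parts = {"r2_by_study": r2_study}
    if n_devices >= 3:
        parts["r2_by_device_median"] = r2_table(table, "device_median")
    r2 = pd.DataFrame(parts)
    r2.index.name = "qc_parameter"

    device_summary = (
        table.groupby("device_id", sort=True)["p"]
        .agg(median="median", q25=lambda x: x.quantile(0.25),
             q75=lambda x: x.quantile(0.75), min="min", max="max", n="size")
        .reset_index()
    )
    study_cols = ["study_id", "device_id", "p", "sd"] + [
        c for c in QC_PARAMS if c in table.columns
    ]
    study_scatter = table[study_cols].copy()
    device_scatter = (
        table[["device_id", "p"] + [c for c in QC_PARAMS if c in table.columns]]
        .replace([np.inf, -np.inf], np.nan)
        .groupby("device_id", sort=True)
        .median(numeric_only=True)
        .reset_index()
    )
    return StatReport(
        shapiro=shapiro,
        anova_f=anova_f,
        anova_p=anova_p,
        tukey=tukey,
        r2=r2,
        device_summary=device_summary,
        study_scatter=study_scatter,
        device_scatter=device_scatter,
    )


def write_report(report: StatReport, outdir: str | Path, header: str = "") -> list[Path]:
    """Render the report sections as deterministic CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        with open(path, "w") as f:
            if header:
                f.write(header if header.endswith("\n") else header + "\n")
            df.to_csv(f, index=index, float_format="%.8g", lineterminator="\n")
        written.append(path)

    _write(report.shapiro, "shapiro_by_device.csv")
    if report.anova_f is not None:
        _write(
            pd.DataFrame({"f_statistic": [report.anova_f], "p_value": [report.anova_p]}),
            "anova_by_device.csv",
        )
    if report.tukey is not None:
        _write(report.tukey, "tukey_pairwise_p.csv", index=True)
    _write(report.r2, "r2_table.csv", index=True)
    _write(report.device_summary, "device_p_summary.csv")
    _write(report.study_scatter, "scatter_by_study.csv")
    _write(report.device_scatter, "scatter_by_device.csv")
    return written
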