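"""Evaluation of targeted (SRM) quantification across a dilution gradient.

Takes a long-format quantification report (integrated peak area per run and
transition, including spiked-in QC-standard transitions), normalizes out
run-to-run instrument drift against the most stable QC transitions, and
screens each analyte transition for (a) detection across the dilution
series, (b) replicate reliability via the coefficient of variation, and
(c) linear response to the target-species dilution factor via Pearson
correlation against the analytic critical r.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

QUANT_COLUMNS = (
    "run",
    "replicate",
    "dilution_label",
    "dilution_factor",
    "transition_id",
    "is_qc",
    "area",
)


@dataclass
class NormalizationModel:
    """Per-run normalization factors from low-CV QC transitions."""

    qc_transitions: list[str]
    factors: dict[str, float]  # run -> mean QC area
    qc_cvs: dict[str, float] = field(default_factory=dict)


@dataclass
class ScreenReport:
    """Per-transition screening results plus summary fractions."""

    table: pd.DataFrame
    per_dilution_cv: pd.DataFrame  # transitions x dilution labels, CV%
    critical_r: float
    n_dilution_levels: int
    summary: dict[str, float] = field(default_factory=dict)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal round-half-up, the convention used for reported r values."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sd(n-1) / mean.

    Returns NaN (flagged missing) for fewer than two observations or a
    non-positive mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    mean = v.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def validate_quant_matrix(matrix: pd.DataFrame) -> None:
    missing = [c for c in QUANT_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"quant matrix missing columns: {missing}")
    dup = matrix.duplicated(subset=["run", "transition_id"])
    if dup.any():
        raise ValueError("duplicate (run, transition) rows in quant matrix")


def fit_normalization(
    matrix: pd.DataFrame, n_qc: int = 8, cv_threshold: float = 40.0
) -> NormalizationModel:
    """Select the most stable QC transitions and derive per-run factors.

    QC transitions are ranked by their across-run CV%; the ``n_qc`` lowest
    with CV below ``cv_threshold`` are selected. The factor for a run is the
    mean area of the selected QC transitions in that run.
    """
    validate_quant_matrix(matrix)
    qc = matrix[matrix["is_qc"].astype(bool)]
    if qc.empty:
        raise ValueError("no QC transitions in quant matrix")
    wide = qc.pivot(index="transition_id", columns="run", values="area")
    cvs = wide.apply(lambda row: cv_percent(row.to_numpy()), axis=1).sort_values()
    eligible = cvs[cvs < cv_threshold]
    if eligible.empty:
        raise ValueError(f"no QC transition has CV below {cv_threshold}%")
    if len(eligible) < n_qc:
        log.warning(
            "only %d QC transitions under CV threshold %.1f%% (wanted %d); using all",
            len(eligible), cv_threshold, n_qc,
        )
    selected = list(eligible.index[:n_qc])
    factors = wide.loc[selected].mean(axis=0)
    if (factors <= 0).any() or factors.isna().any():
        raise ValueError("non-positive or missing QC mean in some run")
    return NormalizationModel(
        qc_transitions=selected,
        factors={str(r): float(f) for r, f in factors.items()},
        qc_cvs={str(t): float(c) for t, c in cvs.items()},
    )


def normalize(matrix: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Divide each run's areas by that run's QC factor; missing stays missing."""
    validate_quant_matrix(matrix)
    runs = set(matrix["run"].astype(str))
    absent = runs - set(model.factors)
    if absent:
        raise ValueError(f"run(s) not in normalization model: {sorted(absent)}")
    out = matrix.copy()
    out["area"] = out["area"] / out["run"].astype(str).map(model.factors)
    return out


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson correlation for sample size n.

    r_crit = t / sqrt(n - 2 + t^2) with t the (1 - alpha/2) quantile of
    Student's t on n - 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("critical r needs n >= 3")
    t = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t / math.sqrt(n - 2 + t * t))


def screen_transitions(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    log_transform: bool = False,
    cv_high: float = 100.0,
) -> ScreenReport:
    """Screen normalized analyte transitions across the dilution gradient.

    Only rows with a finite dilution factor enter the correlation (pure
    endpoint cultures have no finite target:background ratio). Per
    transition: Pearson r between per-dilution mean area and dilution
    factor; pass iff r >= critical_r(#levels, alpha). Per-dilution CV% is
    computed across biological replicates. Missing areas are treated as
    absent, not zero; "detected" in a dilution requires at least one
    replicate with area > 0.
    """
    validate_quant_matrix(matrix)
    df = matrix[~matrix["is_qc"].astype(bool)].copy()
    df = df[np.isfinite(df["dilution_factor"].astype(float))]
    if df.empty:
        raise ValueError("no analyte rows with finite dilution factor")
    levels = (
        df[["dilution_label", "dilution_factor"]]
        .drop_duplicates()
        .sort_values("dilution_factor")
    )
    n_levels = len(levels)
    if n_levels < 3:
        raise ValueError("need >= 3 dilution levels to screen")
    rcrit = critical_r(n_levels, alpha)

    cv_wide = (
        df.groupby(["transition_id", "dilution_label"])["area"]
        .apply(lambda v: cv_percent(v.to_numpy()))
        .unstack()
        .reindex(columns=levels["dilution_label"])
    )

    rows = []
    for tid, grp in df.groupby("transition_id"):
        per_dil = grp.groupby("dilution_label").agg(
            mean_area=("area", "mean"),
            detected=("area", lambda v: bool((v.dropna() > 0).any())),
        )
        per_dil = per_dil.reindex(levels["dilution_label"])
        factors = levels.set_index("dilution_label")["dilution_factor"]
        mask = per_dil["mean_area"].notna()
        x = factors[mask].to_numpy(dtype=float)
        y = per_dil.loc[mask, "mean_area"].to_numpy(dtype=float)
        detected_all = bool(per_dil["detected"].map(lambda d: bool(d) if d == d else False).all())
        if log_transform:
            keep = (x > 0) & (y > 0)
            x, y = np.log10(x[keep]), np.log10(y[keep])
        if len(x) < 3:
            rows.append(
                {"transition_id": tid, "n_levels": len(x), "r": np.nan,
                 "passes": False, "evaluable": False, "detected_all": detected_all}
            )
            continue
        if np.std(y) == 0 or np.std(x) == 0:
            r = np.nan
            passes = False
        else:
            r = float(stats.pearsonr(x, y).statistic)
            passes = bool(r >= rcrit)
        rows.append(
            {"transition_id": tid, "n_levels": len(x), "r": r,
             "passes": passes, "evaluable": True, "detected_all": detected_all}
        )
    table = pd.DataFrame(rows).set_index("transition_id")

    evaluable = table[table["evaluable"]]
    high_cv_frac = {
        str(lab): float((cv_wide[lab] > cv_high).mean())
        for lab in cv_wide.columns
    }
    summary = {
        "n_transitions": int(len(table)),
        "n_detected_all_dilutions": int(table["detected_all"].sum()),
        "frac_detected_all_dilutions": float(table["detected_all"].mean()),
        "n_passing": int(table["passes"].sum()),
        "frac_passing": float(table["passes"].sum() / max(len(evaluable), 1)),
        "critical_r": rcrit,
        "per_dilution_frac_cv_above_threshold": high_cv_frac,
    }
    return ScreenReport(
        table=table,
        per_dilution_cv=cv_wide,
        critical_r=rcrit,
        n_dilution_levels=n_levels,
        summary=summary,
    )


def write_report(report: ScreenReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(out / "screen_report.csv")
    report.per_dilution_cv.to_csv(out / "per_dilution_cv.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2)
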