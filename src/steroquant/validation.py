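"""Bioanalytical method validation: accuracy, precision, carryover, stability.

Metrics follow the FDA bioanalytical guidance as applied to replicate QC sets
(n >= 6 per level and day at LLOQ/low/mid/high):

* ``rsd_percent``   — dispersion, 100 * sample SD / mean
* ``relative_error_percent`` — signed bias, 100 * (mean - nominal) / nominal

An analyte level passes when both metrics are within ±20% at the LLOQ and
±15% at every other level (inclusive thresholds); an analyte passes when all
four levels pass. Carryover in a post-ULOQ blank passes when the blank signal
is strictly below 20% of the LLOQ signal.

Note on report labels: some published validation tables head the RSD column
"Accuracy" and the relative-error column "Precision" — the reverse of the
conventional mapping. Internally everything is named by formula; the report
renderer offers a ``paper_labels`` mode that reproduces the swapped headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "rsd_percent",
    "relative_error_percent",
    "QCReplicateSet",
    "ValidationReport",
    "build_validation_table",
    "apply_fda_rules",
    "check_carryover",
    "determine_lloq",
    "stability_and_recovery",
    "recovery_percent",
    "load_reference_validation",
]

LLOQ_THRESHOLD = 20.0  # % at the LLOQ level (inclusive)
OTHER_THRESHOLD = 15.0  # % at low/mid/high (inclusive)
CARRYOVER_LIMIT = 20.0  # % of LLOQ signal (strict)
LEVEL_ORDER = ["LLOQ", "low", "mid", "high"]


def rsd_percent(measured) -> float:
    """Relative standard deviation, 100 * sample SD / mean."""
    x = np.asarray(measured, dtype=float)
    if x.size < 2:
        raise DataError("RSD needs >= 2 replicates")
    mean = x.mean()
    if mean <= 0:
        raise DataError("RSD undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def relative_error_percent(measured, nominal: float) -> float:
    """Signed bias, 100 * (mean(measured) - nominal) / nominal."""
    x = np.asarray(measured, dtype=float)
    if x.size == 0:
        raise DataError("relative error needs >= 1 replicate")
    if nominal <= 0:
        raise DataError("nominal concentration must be > 0")
    return float(100.0 * (x.mean() - nominal) / nominal)


@dataclass
class QCReplicateSet:
    """Replicate QC determinations of one analyte/level on one day."""

    analyte: str
    level_name: str  # {"LLOQ", "low", "mid", "high"}
    nominal: float  # nmol/L
    measured: list[float]  # nmol/L, n >= 6 by design
    day: int = 1

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise DataError(f"{self.analyte}/{self.level_name}: nominal must be > 0")
        if self.level_name not in LEVEL_ORDER:
            raise DataError(f"unknown QC level {self.level_name!r}")


def level_passes(level_name: str, rsd: float, re: float) -> bool:
    """FDA pass rule for one (analyte, level) metric pair."""
    limit = LLOQ_THRESHOLD if level_name == "LLOQ" else OTHER_THRESHOLD
    return abs(rsd) <= limit and abs(re) <= limit


def build_validation_table(qc: pd.DataFrame) -> pd.DataFrame:
    """Inter-day validation metrics from a tidy QC replicate table.

    ``qc`` columns: analyte, level_name, nominal, day, measured. Inter-day
    metrics pool all days' replicates per (analyte, level); intra-day metrics
    per day are obtainable by pre-filtering on ``day``.
    """
    required = {"analyte", "level_name", "nominal", "measured"}
    missing = required - set(qc.columns)
    if missing:
        raise DataError(f"QC table lacks columns: {sorted(missing)}")
    rows = []
    for (analyte, level), grp in qc.groupby(["analyte", "level_name"], sort=False):
        nominal = float(grp["nominal"].iloc[0])
        values = grp["measured"].to_numpy(dtype=float)
        rows.append(
            {
                "analyte": analyte,
                "level_name": level,
                "nominal": nominal,
                "n": values.size,
                "rsd_percent": rsd_percent(values),
                "relative_error_percent": relative_error_percent(values, nominal),
            }
        )
    return pd.DataFrame(rows)


def apply_fda_rules(table: pd.DataFrame, require_all_levels: bool = True) -> "ValidationReport":
    """Apply the pass rules to a long metrics table.

    ``table`` columns: analyte, level_name, rsd_percent, relative_error_percent.
    """
    df = table.copy()
    df["pass"] = [
        level_passes(lv, r, e)
        for lv, r, e in zip(df["level_name"], df["rsd_percent"], df["relative_error_percent"])
    ]
    per_analyte = {}
    for analyte, grp in df.groupby("analyte", sort=False):
        complete = set(LEVEL_ORDER) <= set(grp["level_name"])
        passed = bool(grp["pass"].all()) and (complete or not require_all_levels)
        per_analyte[analyte] = {
            "pass": passed,
            "incomplete": not complete,
            "n_levels": int(grp["level_name"].nunique()),
        }
    return ValidationReport(levels=df, analytes=per_analyte)


@dataclass
class ValidationReport:
    """Per-level metrics plus per-analyte FDA pass/fail decisions."""

    levels: pd.DataFrame
    analytes: dict[str, dict]

    @property
    def n_pass(self) -> int:
        return sum(1 for v in self.analytes.values() if v["pass"])

    @property
    def n_fail(self) -> int:
        return len(self.analytes) - self.n_pass

    def all_pass(self) -> bool:
        return self.n_fail == 0

    def max_metric(self, metric: str, level_name: str) -> float:
        sub = self.levels[self.levels["level_name"] == level_name]
        if sub.empty:
            raise DataError(f"no rows at level {level_name!r}")
        return float(sub[metric].abs().max())

    def to_markdown(self, paper_labels: bool = False) -> str:
        df = self.levels.copy()
        if paper_labels:
            df = df.rename(
                columns={
                    "rsd_percent": "Accuracy (RSD, %)",
                    "relative_error_percent": "Precision (relative error, %)",
                }
            )
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join("---" for _ in df.columns) + "|"
        body = [
            "| " + " | ".join(str(v) for v in row) + " |"
            for row in df.itertuples(index=False)
        ]
        summary = [
            "",
            f"Analytes passing: {self.n_pass}/{len(self.analytes)}",
        ]
        return "\n".join([header, sep, *body, *summary])


def check_carryover(blank_signal: float, lloq_signal: float) -> tuple[float, bool]:
    """Carryover blank signal as % of the LLOQ signal; pass when < 20%."""
    if lloq_signal <= 0:
        raise DataError("LLOQ signal must be > 0 for carryover assessment")
    if blank_signal < 0:
        raise DataError("blank signal must be non-negative")
    percent = 100.0 * blank_signal / lloq_signal
    return percent, percent < CARRYOVER_LIMIT


def determine_lloq(qc: pd.DataFrame, candidate_levels=None) -> float:
    """Lowest candidate level passing the ±20% rules on every validation day.

    ``qc`` columns: nominal, day, measured (one analyte). Returns the lowest
    nominal level whose per-day RSD and |relative error| are both <= 20%.
    """
    levels = sorted(qc["nominal"].unique()) if candidate_levels is None else sorted(candidate_levels)
    if len(levels) < 2:
        raise DataError("LLOQ determination needs >= 2 candidate levels")
    for level in levels:
        sub = qc[qc["nominal"] == level]
        if sub.empty:
            continue
        ok = True
        for _, day_grp in sub.groupby("day"):
            values = day_grp["measured"].to_numpy(dtype=float)
            try:
                if (
                    abs(rsd_percent(values)) > LLOQ_THRESHOLD
                    or abs(relative_error_percent(values, level)) > LLOQ_THRESHOLD
                ):
                    ok = False
                    break
            except DataError:
                ok = False
                break
        if ok:
            return float(level)
    raise DataError("no candidate level satisfies the LLOQ rules; assay range undefined")


def stability_and_recovery(reference, condition) -> dict[str, float]:
    """Condition-vs-reference stability deltas for a paired design.

    Returns the bias of the stressed condition relative to the reference mean
    (%), and the RSD of the condition replicates (%).
    """
    ref = np.asarray(reference, dtype=float)
    cond = np.asarray(condition, dtype=float)
    if ref.size == 0 or cond.size == 0 or ref.size != cond.size:
        raise DataError("stability needs paired reference/condition replicates")
    ref_mean = ref.mean()
    if ref_mean <= 0:
        raise DataError("reference mean must be > 0")
    return {
        "bias_percent": float(100.0 * (cond.mean() - ref_mean) / ref_mean),
        "rsd_percent": rsd_percent(cond),
    }


def recovery_percent(measured, spiked: float) -> float:
    """Extraction recovery, 100 * mean(measured) / spiked."""
    if spiked <= 0:
        raise DataError("spiked amount must be > 0")
    return float(100.0 * np.asarray(measured, dtype=float).mean() / spiked)


def load_reference_validation() -> pd.DataFrame:
    """Packaged inter-day validation results for the 17-analyte targeted assay.

    Wide format, one row per analyte: LLOQ/ULOQ (nmol/L) and RSD / relative
    error (%) at the high, mid, low and LLOQ levels.
    """
    ref = resources.files("steroquant.data").joinpath("interday_validation.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def reference_validation_long(wide: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reshape the packaged wide validation table to the long metrics format."""
    if wide is None:
        wide = load_reference_validation()
    rows = []
    for rec in wide.itertuples(index=False):
        for level in LEVEL_ORDER:
            key = level.lower() if level != "LLOQ" else "lloq"
            rows.append(
                {
                    "analyte": rec.analyte,
                    "level_name": level,
                    "rsd_percent": getattr(rec, f"rsd_{key}"),
                    "relative_error_percent": getattr(rec, f"re_{key}"),
                }
            )
    return pd.DataFrame(rows)
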