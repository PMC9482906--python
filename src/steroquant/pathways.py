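"""Apparent enzyme activities and menstrual-cycle-phase classifiers.

An apparent enzyme activity is the product-to-substrate concentration ratio
(e.g. CYP17A1 = 17OHP4/P4, HSD3B2 = P4/P5, HSD11B2 = cortisone/cortisol): a
proxy for steroidogenic flux that needs no absolute enzyme measurement.

The phase classifiers are univariate composite scores built from progesterone
metabolites and apparent activities:

* serum:      20aOHP4 / (CYP17A1 + HSD3B2)
* PF:         (5aDHP4 + 20aOHP4) / CYP17A1
* serum + PF: (serum 5aDHP4 + serum 20aOHP4 + PF 20aOHP4) / PF CYP17A1

They are composite scores compared across groups, not trained models. Any
constituent that is missing/below the LLOQ (NaN) makes the score undefined
(NaN) — never a silent zero. The serum and PF classifiers carry concentration
units (nmol/L) because the numerator is a concentration while the denominator
is a dimensionless ratio; values therefore scale with the concentration unit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .panel import EnzymeRatioDefinition, Panel

__all__ = [
    "enzyme_activity",
    "compute_activities",
    "serum_classifier",
    "pf_classifier",
    "serum_pf_classifier",
    "classify_cohort",
    "log_zscore",
    "group_compare",
    "significance_label",
]


def _defined(*values) -> bool:
    return all(v is not None and np.isfinite(v) for v in values)


def enzyme_activity(products, substrates) -> tuple[float, str | None]:
    """sum(products)/sum(substrates); (nan, reason) when undefined."""
    products = list(np.atleast_1d(products))
    substrates = list(np.atleast_1d(substrates))
    if not _defined(*products, *substrates):
        return float("nan"), "missing_constituent"
    denom = float(np.sum(substrates))
    if denom <= 0:
        return float("nan"), "non_positive_substrate"
    num = float(np.sum(products))
    if num < 0:
        return float("nan"), "negative_product"
    return num / denom, None


def compute_activities(cohort: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Per-sample apparent activities for every enzyme ratio of the panel.

    ``cohort`` is a wide concentration table (one row per sample, analyte
    columns in nmol/L, NaN = undefined/below LLOQ); id columns are preserved.
    """
    id_cols = [c for c in ("sample_id", "subject_id", "matrix", "phase") if c in cohort.columns]
    rows = []
    for _, rec in cohort.iterrows():
        out = {c: rec[c] for c in id_cols}
        for ratio in panel.enzyme_ratios:
            value, reason = _ratio_for_row(rec, ratio)
            out[ratio.name] = value
            if reason:
                out[f"{ratio.name}_missing_reason"] = reason
        rows.append(out)
    return pd.DataFrame(rows)


def _ratio_for_row(rec: pd.Series, ratio: EnzymeRatioDefinition) -> tuple[float, str | None]:
    try:
        products = [rec[a] for a in ratio.products]
        substrates = [rec[a] for a in ratio.substrates]
    except KeyError as exc:
        return float("nan"), f"analyte_absent:{exc.args[0]}"
    return enzyme_activity(products, substrates)


def serum_classifier(conc) -> float:
    """20aOHP4 / (CYP17A1 + HSD3B2), with CYP17A1 = 17OHP4/P4 and HSD3B2 = P4/P5."""
    try:
        p20a, ohp17, p4, p5 = (
            conc["20aOHP4"], conc["17OHP4"], conc["P4"], conc["P5"],
        )
    except KeyError:
        return float("nan")
    if not _defined(p20a, ohp17, p4, p5) or p4 <= 0 or p5 <= 0:
        return float("nan")
    denom = ohp17 / p4 + p4 / p5
    return p20a / denom if denom > 0 else float("nan")


def pf_classifier(conc) -> float:
    """(5aDHP4 + 20aOHP4) / CYP17A1 in peritoneal fluid."""
    try:
        dhp, p20a, ohp17, p4 = (
            conc["5aDHP4"], conc["20aOHP4"], conc["17OHP4"], conc["P4"],
        )
    except KeyError:
        return float("nan")
    if not _defined(dhp, p20a, ohp17, p4) or p4 <= 0 or ohp17 <= 0:
        return float("nan")
    return (dhp + p20a) / (ohp17 / p4)


def serum_pf_classifier(serum_conc, pf_conc) -> float:
    """(serum 5aDHP4 + serum 20aOHP4 + PF 20aOHP4) / PF CYP17A1 for a paired subject."""
    try:
        s_dhp, s_20a = serum_conc["5aDHP4"], serum_conc["20aOHP4"]
        p_20a, p_17, p_p4 = pf_conc["20aOHP4"], pf_conc["17OHP4"], pf_conc["P4"]
    except KeyError:
        return float("nan")
    if not _defined(s_dhp, s_20a, p_20a, p_17, p_p4) or p_p4 <= 0 or p_17 <= 0:
        return float("nan")
    return (s_dhp + s_20a + p_20a) / (p_17 / p_p4)


def classify_cohort(cohort: pd.DataFrame, paired_by: str = "subject_id") -> pd.DataFrame:
    """All phase classifiers for a cohort table.

    Single-matrix scores (P4_only, serum_combined, pf_combined) are computed
    per sample on the matching matrix; the combined serum+PF score per subject
    with both matrices present. Raises when the paired column is absent but a
    paired score is requested on mixed-matrix data.
    """
    required = {"matrix"}
    if missing := required - set(cohort.columns):
        raise DataError(f"cohort table lacks columns: {sorted(missing)}")
    rows = []
    serum = cohort[cohort["matrix"] == "serum"]
    pf = cohort[cohort["matrix"] == "PF"]
    for _, rec in serum.iterrows():
        rows.append(
            {
                "id": rec.get("sample_id", rec.get(paired_by)),
                "subject_id": rec.get(paired_by),
                "phase": rec.get("phase"),
                "classifier": "serum_combined",
                "value": serum_classifier(rec),
            }
        )
        rows.append(
            {
                "id": rec.get("sample_id", rec.get(paired_by)),
                "subject_id": rec.get(paired_by),
                "phase": rec.get("phase"),
                "classifier": "P4_only",
                "value": rec["P4"] if "P4" in rec else float("nan"),
            }
        )
    for _, rec in pf.iterrows():
        rows.append(
            {
                "id": rec.get("sample_id", rec.get(paired_by)),
                "subject_id": rec.get(paired_by),
                "phase": rec.get("phase"),
                "classifier": "pf_combined",
                "value": pf_classifier(rec),
            }
        )
    if paired_by in cohort.columns:
        pf_by_subject = {rec[paired_by]: rec for _, rec in pf.iterrows()}
        for _, rec in serum.iterrows():
            mate = pf_by_subject.get(rec[paired_by])
            if mate is None:
                continue
            rows.append(
                {
                    "id": rec[paired_by],
                    "subject_id": rec[paired_by],
                    "phase": rec.get("phase"),
                    "classifier": "serum_pf_combined",
                    "value": serum_pf_classifier(rec, mate),
                }
            )
    return pd.DataFrame(rows)


def log_zscore(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """log10-transform then z-score each variable (column).

    Non-positive and missing values are excluded before the log (they stay
    NaN), matching the pre-processing applied before pathway statistics.
    """
    out = df.copy()
    columns = list(columns) if columns is not None else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
    ]
    for col in columns:
        x = out[col].astype(float).where(out[col] > 0)
        logged = np.log10(x)
        sd = logged.std(ddof=1)
        out[col] = (logged - logged.mean()) / sd if sd and np.isfinite(sd) and sd > 0 else logged * 0.0
    return out


def significance_label(p: float) -> str:
    """Star label at the 0.05 / 0.01 / 0.001 / 0.0001 thresholds."""
    if not np.isfinite(p):
        return "Ns"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "Ns"


def group_compare(values, groups) -> dict:
    """Nonparametric group comparison of one variable across phases.

    log10 + z-score normalization, a Kruskal-Wallis test across all groups and
    pairwise two-sided Mann-Whitney tests with Benjamini-Hochberg adjustment.
    Returns the omnibus statistic/p and a pairwise DataFrame with adjusted
    p-values and star labels.
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    s = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    s = s[s["value"] > 0].dropna()
    order = list(dict.fromkeys(s["group"]))
    if len(order) < 2:
        raise DataError("group comparison needs >= 2 groups")
    by_group = {g: s.loc[s["group"] == g, "value"] for g in order}
    if any(len(v) < 3 for v in by_group.values()):
        raise DataError("each group needs >= 3 defined values")
    normalized = np.log10(s["value"])
    normalized = (normalized - normalized.mean()) / normalized.std(ddof=1)
    z_by_group = {g: normalized[s["group"] == g].to_numpy() for g in order}

    try:
        kw_stat, kw_p = stats.kruskal(*z_by_group.values())
    except ValueError:  # all values identical across every group
        kw_stat, kw_p = 0.0, 1.0

    pairs, raw_p, stats_u = [], [], []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            xa, xb = z_by_group[a], z_by_group[b]
            # exact null tables where feasible (small groups, no ties);
            # the normal approximation otherwise
            small = max(len(xa), len(xb)) <= 25
            no_ties = np.unique(np.concatenate([xa, xb])).size == len(xa) + len(xb)
            method = "exact" if (small and no_ties) else "asymptotic"
            try:
                u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            except ValueError:
                u, p = np.nan, 1.0
            pairs.append((a, b))
            raw_p.append(p)
            stats_u.append(u)
    adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "U": stats_u,
            "p_raw": raw_p,
            "p_adj": adj,
            "label": [significance_label(p) for p in adj],
        }
    )
    return {
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": pairwise,
    }
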