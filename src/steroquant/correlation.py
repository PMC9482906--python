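"""Spearman correlation matrices, cluster ordering and serum-vs-PF comparison.

Correlations are pairwise-complete Spearman rank coefficients with average
ranks for ties. Two-sided p-values come from the exact permutation null for
small samples (n <= 9, enumerating all rank permutations) and from the
t-approximation otherwise. Heat-map ordering uses average-linkage hierarchical
clustering on the distance ``d = 1 - rho``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError
from .panel import Panel

__all__ = [
    "CorrelationMatrix",
    "spearman_matrix",
    "cluster_order",
    "plot_heatmap",
    "serum_pf_compare",
    "EXACT_P_MAX_N",
]

EXACT_P_MAX_N = 9  # exact permutation p-value up to this sample size
MIN_PAIRS = 3


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        return float("nan")
    return float((xc * yc).sum() / (nx * ny))


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p: share of rank permutations with |rho| >= |observed|."""
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    xc = rx - rx.mean()
    yc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (yc @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_pair(x, y) -> tuple[float, float, int]:
    """Spearman rho, two-sided p and the complete-pair count for one pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < MIN_PAIRS:
        return float("nan"), float("nan"), n
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), float("nan"), n
    rx, ry = _rank(xs), _rank(ys)
    rho = _pearson(rx, ry)
    if n <= EXACT_P_MAX_N:
        p = _exact_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(xs, ys).pvalue)
    return rho, p, n


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1 :]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n": self.n_pairs.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def spearman_matrix(
    cohort: pd.DataFrame,
    variables=None,
    panel: Panel | None = None,
    class_filter: str | None = None,
    matrix_filter: str | None = None,
) -> CorrelationMatrix:
    """Pairwise-complete Spearman matrix over analyte columns.

    ``class_filter`` restricts to one steroid class of ``panel``;
    ``matrix_filter`` restricts rows to one matrix (serum or PF).
    """
    df = cohort
    if matrix_filter is not None:
        if "matrix" not in df.columns:
            raise DataError("cohort table has no 'matrix' column to filter on")
        df = df[df["matrix"] == matrix_filter]
    if variables is None:
        if class_filter is not None:
            if panel is None:
                raise DataError("class_filter requires a panel")
            wanted = [s.abbreviation for s in panel.by_class(class_filter)]
            variables = [v for v in wanted if v in df.columns]
        else:
            variables = [
                c
                for c in df.columns
                if c not in ("sample_id", "subject_id", "matrix", "phase")
                and pd.api.types.is_numeric_dtype(df[c])
            ]
    if len(variables) < 2:
        raise DataError("correlation needs >= 2 variables")
    k = len(variables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(df))
    for i in range(k):
        for j in range(i + 1, k):
            r, pv, npairs = spearman_pair(df[variables[i]], df[variables[j]])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
            n[i, j] = n[j, i] = npairs
    idx = list(variables)
    return CorrelationMatrix(
        variables=idx,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_pairs=pd.DataFrame(n, index=idx, columns=idx),
    )


def cluster_order(corr: CorrelationMatrix, linkage_method: str = "average"):
    """Leaf order of hierarchical clustering on d = 1 - rho.

    Undefined correlations are imputed as rho = 0 (maximal distance among
    observed values) and reported back via the ``imputed`` flag.
    """
    if len(corr.variables) < 2:
        raise DataError("clustering needs >= 2 variables")
    rho = corr.rho.to_numpy(dtype=float).copy()
    imputed = bool(np.isnan(rho).any())
    rho = np.nan_to_num(rho, nan=0.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    linkage = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    order = hierarchy.leaves_list(linkage)
    return [corr.variables[i] for i in order], linkage, imputed


def plot_heatmap(corr: CorrelationMatrix, path=None, order=None):
    """Render the correlation matrix as a clustered heat map (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if order is None:
        order, _, _ = cluster_order(corr)
    mat = corr.rho.loc[order, order]
    fig, ax = plt.subplots(figsize=(0.4 * len(order) + 2, 0.4 * len(order) + 2))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def serum_pf_compare(cohort: pd.DataFrame, paired_by: str = "subject_id") -> pd.DataFrame:
    """Per-analyte serum-vs-PF comparison on paired subjects.

    Returns medians per matrix, the serum/PF median ratio, and the OLS
    regression of PF on serum with its slope/intercept/p-value. Analytes with
    fewer than 3 complete pairs are reported with a skip reason.
    """
    for col in (paired_by, "matrix"):
        if col not in cohort.columns:
            raise DataError(f"cohort table lacks column {col!r}")
    serum = cohort[cohort["matrix"] == "serum"].set_index(paired_by)
    pf = cohort[cohort["matrix"] == "PF"].set_index(paired_by)
    subjects = serum.index.intersection(pf.index)
    analytes = [
        c
        for c in cohort.columns
        if c not in ("sample_id", "subject_id", "matrix", "phase")
        and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    rows = []
    for analyte in analytes:
        s = serum.loc[subjects, analyte].to_numpy(dtype=float)
        f = pf.loc[subjects, analyte].to_numpy(dtype=float)
        mask = np.isfinite(s) & np.isfinite(f)
        row = {"analyte": analyte, "n_pairs": int(mask.sum())}
        if mask.sum() < MIN_PAIRS:
            row["skip_reason"] = "fewer than 3 complete pairs"
            rows.append(row)
            continue
        s, f = s[mask], f[mask]
        med_s, med_f = float(np.median(s)), float(np.median(f))
        row.update(median_serum=med_s, median_pf=med_f)
        row["serum_pf_ratio"] = med_s / med_f if med_f > 0 else float("nan")
        if np.ptp(s) > 0:
            reg = stats.linregress(s, f)
            row.update(
                slope=float(reg.slope),
                intercept=float(reg.intercept),
                p_value=float(reg.pvalue),
            )
        else:
            row["skip_reason"] = "zero variance in serum"
        rows.append(row)
    return pd.DataFrame(rows)
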