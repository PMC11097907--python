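"""Condition contrasts, cross-measure correlation matrices, and study drivers.

The measure table is a long-format DataFrame with columns
``unit`` (subject or network id), ``condition``, ``measure``, ``value`` and
optional provenance columns; every (unit, condition, measure) key is unique.

Pairwise condition contrasts use the Wilcoxon signed-rank test (paired by
unit; the reported statistic W is the smaller signed-rank sum, exact p for
n <= 25). Cross-measure association uses Spearman's rank correlation with
non-significant cells masked. No multiple-comparison correction is applied by
default; Holm correction is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "make_measure_table",
    "spearman",
    "wilcoxon_signed_rank",
    "relative_change",
    "CorrelationMatrix",
    "correlation_matrix",
    "ContrastResult",
    "ConditionStudyResult",
    "run_condition_study",
    "run_ar_study",
]


def make_measure_table(records) -> pd.DataFrame:
    """Validate and normalize a long-format measure table."""
    table = pd.DataFrame(records)
    required = {"unit", "condition", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measure table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["unit", "condition", "measure"]).any():
        raise ValueError("duplicate (unit, condition, measure) keys")
    if not np.all(np.isfinite(table["value"])):
        raise ValueError("measure values must be finite")
    return table


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired values.

    Returns (W, p) where W is the smaller of the positive/negative signed-rank
    sums. Zero differences are removed first; requires >= 5 remaining pairs.
    Exact p-value for n <= 25, large-sample normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    method = "exact" if d.size <= 25 else "approx"
    res = sps.wilcoxon(d, method=method, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def relative_change(table: pd.DataFrame, baseline: str = "wake") -> pd.DataFrame:
    """Per-unit percent change from baseline, averaged with its standard error.

    Returns rows (measure, condition, pct_change, sem, n); change is
    (condition - baseline) / |baseline| * 100, paired by unit.
    """
    out = []
    for measure, sub in table.groupby("measure"):
        wide = sub.pivot(index="unit", columns="condition", values="value")
        if baseline not in wide.columns:
            raise ValueError(f"baseline condition {baseline!r} absent for {measure!r}")
        base = wide[baseline]
        if (base == 0).any():
            raise ValueError(f"zero baseline value for measure {measure!r}")
        for cond in wide.columns:
            if cond == baseline:
                continue
            pct = ((wide[cond] - base) / base.abs() * 100.0).dropna()
            if pct.empty:
                logger.warning("no paired units for %s / %s", measure, cond)
                continue
            out.append({"measure": measure, "condition": cond,
                        "pct_change": float(pct.mean()),
                        "sem": float(pct.sem()) if len(pct) > 1 else np.nan,
                        "n": int(len(pct))})
    return pd.DataFrame(out)


@dataclass
class CorrelationMatrix:
    """Measure x measure Spearman rho with p-values and a significance mask."""

    rho: pd.DataFrame
    p_values: pd.DataFrame
    mask: pd.DataFrame  # True where significant (p < alpha)
    alpha: float

    @property
    def masked_rho(self) -> pd.DataFrame:
        """Rho with non-significant correlations zeroed out."""
        return self.rho.where(self.mask, 0.0)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def correlation_matrix(wide: pd.DataFrame, alpha: float = 0.05,
                       holm: bool = False) -> CorrelationMatrix:
    """Pairwise Spearman correlation across the columns of a wide table."""
    cols = list(wide.columns)
    k = len(cols)
    rho = np.eye(k)
    p = np.zeros((k, k))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = wide[[cols[i], cols[j]]].dropna()
            r_ij, p_ij = spearman(sub[cols[i]], sub[cols[j]])
            rho[i, j] = rho[j, i] = r_ij
            p[i, j] = p[j, i] = p_ij
            pairs.append((i, j))
    if holm and pairs:
        adj = _holm(np.array([p[i, j] for i, j in pairs]))
        for (i, j), a in zip(pairs, adj):
            p[i, j] = p[j, i] = a
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationMatrix(rho=rho_df, p_values=p_df, mask=p_df < alpha, alpha=alpha)


@dataclass
class ContrastResult:
    measure: str
    conditions: tuple[str, str]       # (baseline, contrast)
    means: tuple[float, float]
    sems: tuple[float, float]
    statistic: float                  # W, the smaller signed-rank sum
    p_value: float
    pct_change: float
    n: int


@dataclass
class ConditionStudyResult:
    contrasts: pd.DataFrame
    correlations: CorrelationMatrix
    relative_changes: pd.DataFrame


def run_condition_study(table: pd.DataFrame, pci: pd.DataFrame | None = None,
                        baseline: str = "wake", alpha: float = 0.05,
                        holm: bool = False) -> ConditionStudyResult:
    """Condition contrasts plus the cross-measure correlation matrix.

    ``table`` is a long-format measure table. ``pci`` optionally supplies
    externally computed perturbational-complexity values as a long table with
    columns (unit, condition, value); they join the analysis as measure
    ``pci_st`` but are never computed here. Unpaired units are dropped from
    each contrast with a log entry.
    """
    table = make_measure_table(table)
    if pci is not None:
        pci = pci.rename(columns=str.lower).assign(measure="pci_st")
        table = pd.concat([table, make_measure_table(pci)], ignore_index=True)
    conditions = [c for c in table["condition"].unique() if c != baseline]
    if baseline not in set(table["condition"]):
        raise ValueError(f"baseline condition {baseline!r} not present")
    if not conditions:
        raise ValueError("need at least 2 conditions")

    rows = []
    for measure, sub in table.groupby("measure"):
        wide = sub.pivot(index="unit", columns="condition", values="value")
        for cond in conditions:
            if cond not in wide.columns or baseline not in wide.columns:
                continue
            paired = wide[[baseline, cond]].dropna()
            dropped = len(wide) - len(paired)
            if dropped:
                logger.info("%s %s vs %s: %d unpaired unit(s) dropped",
                            measure, baseline, cond, dropped)
            try:
                w, p = wilcoxon_signed_rank(paired[baseline], paired[cond])
            except ValueError as err:
                logger.warning("contrast %s %s: %s", measure, cond, err)
                continue
            base_vals, cond_vals = paired[baseline], paired[cond]
            rows.append({
                "measure": measure, "baseline": baseline, "condition": cond,
                "mean_baseline": float(base_vals.mean()),
                "sem_baseline": float(base_vals.sem()),
                "mean_condition": float(cond_vals.mean()),
                "sem_condition": float(cond_vals.sem()),
                "W": w, "p_value": p,
                "pct_change": float(((cond_vals - base_vals) / base_vals.abs())
                                    .mean() * 100.0),
                "n": int(len(paired)),
            })
    contrasts = pd.DataFrame(rows)

    wide_all = table.pivot_table(index=["unit", "condition"], columns="measure",
                                 values="value")
    corr = correlation_matrix(wide_all, alpha=alpha, holm=holm)
    rel = relative_change(table, baseline=baseline)
    return ConditionStudyResult(contrasts=contrasts, correlations=corr,
                                relative_changes=rel)


def run_ar_study(config=None, **kwargs):
    """Run the auto-regressive network model study (delegates to ar_model)."""
    from .ar_model import run_model_study

    return run_model_study(config, **kwargs)
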