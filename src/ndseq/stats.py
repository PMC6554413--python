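"""Comparison statistics: Spearman matrices, paired Wilcoxon tests and
matched-pairs rank-biserial effect sizes between observed and null values."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, unit diagonal, NaN where undefined
    constant_columns: tuple[str, ...]

    @property
    def absolute(self) -> np.ndarray:
        return np.abs(self.matrix)

    def offdiagonal_summary(self) -> tuple[float, float]:
        """Mean and SD of the absolute off-diagonal entries (defined only)."""
        k = len(self.labels)
        iu = np.triu_indices(k, 1)
        vals = np.abs(self.matrix[iu])
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def spearman_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations between the columns of ``table``.

    Average ranks are assigned to ties. Requires >= 3 rows. Entries
    involving a constant column are NaN and the column is flagged.
    """
    if len(table) < 3:
        raise ValueError("spearman_matrix needs at least 3 rows")
    labels = tuple(str(c) for c in table.columns)
    values = table.to_numpy(dtype=float)
    k = values.shape[1]
    constant = [labels[j] for j in range(k) if np.ptp(values[:, j]) == 0]
    out = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            if labels[a] in constant or labels[b] in constant:
                rho = np.nan
            else:
                rho = sps.spearmanr(values[:, a], values[:, b]).statistic
            out[a, b] = out[b, a] = rho
    if constant:
        logger.warning("constant column(s) flagged undefined: %s", constant)
    return CorrelationMatrix(labels=labels, matrix=out, constant_columns=tuple(constant))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: Optional[float]
    p_value: Optional[float]
    n_used: int
    n_zero_dropped: int
    degenerate: bool = False


def wilcoxon_paired(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original rule) and counted.
    ``method="auto"`` uses the exact null distribution for small tie-free
    samples and the continuity-corrected normal approximation otherwise;
    ``"exact"``/``"approx"`` force a branch. All-zero differences yield a
    degenerate flag instead of a p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    nz = d[d != 0]
    dropped = d.size - nz.size
    if nz.size == 0:
        return WilcoxonResult(None, None, 0, dropped, degenerate=True)
    res = sps.wilcoxon(
        nz,
        zero_method="wilcox",
        alternative="two-sided",
        method=method,
        correction=(method != "exact"),
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=int(nz.size),
        n_zero_dropped=int(dropped),
    )


def paired_rank_effect(x: Sequence[float], y: Sequence[float]) -> float:
    """Matched-pairs rank-biserial correlation, (W+ - W-) / (W+ + W-).

    Ranks the nonzero |x - y| (average ranks on ties); W+ sums the ranks of
    positive differences. +1 when every x exceeds its y, -1 in the opposite
    case, 0 when all differences are zero. Positive values mean x (the
    observed side) tends to exceed y (the null side).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return (w_plus - w_minus) / (w_plus + w_minus)


@dataclass(frozen=True)
class NullComparison:
    """Per-index observed-vs-null comparison over a corpus of networks."""

    table: pd.DataFrame  # index, stratum, n, median_diff, statistic, p, effect, flag
    min_n_for_test: int = 5
    notes: dict = field(default_factory=dict)


def compare_corpus(
    reports: pd.DataFrame,
    stratify_by: Optional[str] = None,
    min_n_for_test: int = 5,
) -> NullComparison:
    """Wilcoxon p and rank-biserial effect per index over a corpus.

    ``reports`` is long-format with columns ``network``, ``index``,
    ``observed``, ``null_mean`` and optionally a class-label column named
    by ``stratify_by``. Each network contributes one (observed, null-mean)
    pair per index. Strata smaller than ``min_n_for_test`` are reported
    descriptively (median difference only). Networks with a missing null
    summary are excluded with a log message.
    """
    required = {"network", "index", "observed", "null_mean"}
    missing = required - set(reports.columns)
    if missing:
        raise ValueError(f"reports is missing columns: {sorted(missing)}")
    df = reports.copy()
    n_bad = df["null_mean"].isna().sum() + df["observed"].isna().sum()
    if n_bad:
        logger.warning("excluding %d row(s) with missing observed/null values", n_bad)
        df = df.dropna(subset=["observed", "null_mean"])

    group_cols = ["index"] + ([stratify_by] if stratify_by else [])
    rows = []
    for keys, grp in df.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        x = grp["observed"].to_numpy(dtype=float)
        y = grp["null_mean"].to_numpy(dtype=float)
        row = {
            "index": keys[0],
            "stratum": keys[1] if stratify_by else "all",
            "n": len(grp),
            "median_diff": float(np.median(x - y)),
        }
        if len(grp) >= min_n_for_test:
            wr = wilcoxon_paired(x, y)
            row.update(
                statistic=wr.statistic,
                p_value=wr.p_value,
                effect=paired_rank_effect(x, y),
                flag="degenerate" if wr.degenerate else "",
            )
        else:
            row.update(statistic=None, p_value=None, effect=None, flag="descriptive")
        rows.append(row)
    return NullComparison(
        table=pd.DataFrame(rows),
        min_n_for_test=min_n_for_test,
        notes={"stratify_by": stratify_by},
    )
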