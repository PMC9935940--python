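"""Line-level trisomy association tests for cell-type proportions and organoid size.

All comparisons are 3 trisomic vs 3 disomic lines using Welch's t-test,
which does not assume equal variances — relevant because proportions near
zero have collapsed variance in one group. Multiple cell-types are corrected
by Bonferroni. Organoid sizes are reduced line-by-batch medians -> per-line
means before testing, so organoids and batches are never treated as
independent replicates of the trisomy effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(x, y) -> WelchResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Degenerate convention: when both groups have zero variance the test is
    decided by the means — equal means give p = 1, unequal means p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0)
        return WelchResult(t=np.inf if x.mean() > y.mean() else -np.inf,
                           df=float(nx + ny - 2), p=0.0)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def test_proportions(proportions: pd.DataFrame, trisomic: pd.Series) -> pd.DataFrame:
    """Per-cell-type Welch tests of line-level proportions, Bonferroni-adjusted.

    ``proportions`` has one row per line (estimated from that line's summed
    replicates); ``trisomic`` flags each line. The difference column is
    mean(disomic) - mean(trisomic), matching the reporting convention of the
    proportion table. A cell-type absent from every line is flagged and gets
    p = 1 by the degenerate zero-variance convention.
    """
    tri = trisomic.reindex(proportions.index).astype(bool)
    if tri.isna().any():
        raise ValueError("trisomy label missing for some lines")
    n_tests = proportions.shape[1]
    rows = []
    for ct in proportions.columns:
        d = proportions.loc[~tri, ct].to_numpy()
        t = proportions.loc[tri, ct].to_numpy()
        res = welch_t(d, t)
        rows.append(
            {
                "celltype": ct,
                "mean_disomic": float(d.mean()),
                "mean_trisomic": float(t.mean()),
                "difference": float(d.mean() - t.mean()),
                "p_value": res.p,
                "p_adj_bonferroni": min(1.0, res.p * n_tests),
                "degenerate": bool(d.var(ddof=1) == 0 and t.var(ddof=1) == 0),
            }
        )
    return pd.DataFrame(rows).set_index("celltype")


@dataclass
class SizeAnalysisResult:
    batch_medians: pd.DataFrame  # line_id, batch, median_area, trisomic
    line_means: pd.Series  # per-line mean of batch medians
    welch: WelchResult


def size_analysis(sizes: pd.DataFrame, trisomic: pd.Series | None = None) -> SizeAnalysisResult:
    """Median size per line x batch, mean per line, then a 3v3 Welch test.

    ``sizes`` needs columns line_id, batch, area (and trisomic unless passed
    separately). Medians of even counts use the midpoint convention.
    """
    if trisomic is None:
        trisomic = sizes.groupby("line_id")["trisomic"].first()
    med = (
        sizes.groupby(["line_id", "batch"])["area"].median().rename("median_area").reset_index()
    )
    med["trisomic"] = med["line_id"].map(trisomic).astype(bool)
    line_means = med.groupby("line_id")["median_area"].mean()
    tri = trisomic.reindex(line_means.index).astype(bool)
    res = welch_t(line_means[~tri].to_numpy(), line_means[tri].to_numpy())
    return SizeAnalysisResult(batch_medians=med, line_means=line_means, welch=res)
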