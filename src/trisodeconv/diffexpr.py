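"""Trisomy differential expression on collapsed counts with stratified FDR.

The pipeline mirrors a pseudoreplication-aware bulk RNA-seq comparison:
replicate pools and repeated differentiations of each cell line are summed to
one column per line (3 trisomic vs 3 disomic units), lowly expressed genes
are filtered (CPM >= 0.25 in at least half the samples), libraries are
normalized by the trimmed mean of M-values (TMM), and each gene is tested
with a negative-binomial log-linear model using a quasi-likelihood F test
whose denominator variance is empirically moderated across genes. Because
chr21 holds only ~1% of genes, a strong chr21-specific dosage signal is
diluted by a genome-wide FDR (and can drag unrelated genes along with it),
so Benjamini-Hochberg FDRs are additionally computed separately within the
chr21 and non-chr21 strata (FDR_chr21, FDR_non21).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

# ---------------------------------------------------------------------------
# collapsing & filtering


def collapse_replicates(
    counts: CountMatrix, meta: pd.DataFrame, unit: str = "line_id"
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sum counts of all samples belonging to the same biological unit.

    Summing (rather than averaging) keeps counts on the sequencing scale:
    library sizes add. Returns the collapsed matrix (one column per unit, in
    first-appearance order) and collapsed metadata carrying the trisomy flag.
    """
    if not set(counts.samples).issubset(meta.index):
        missing = set(counts.samples) - set(meta.index)
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    units = meta.loc[counts.samples, unit]
    if units.isna().any():
        raise ValueError(f"samples with undefined unit {unit!r}")
    order = units.drop_duplicates().tolist()
    collapsed = counts.counts.T.groupby(units, sort=False).sum().T[order]
    rows = []
    for u in order:
        members = meta.loc[counts.samples][units.eq(u).to_numpy()]
        tri = members["trisomic"].unique()
        if len(tri) != 1:
            raise ValueError(f"trisomy state not constant within unit {u!r}")
        rows.append({"unit": u, "trisomic": bool(tri[0]), "n_samples": len(members)})
    cmeta = pd.DataFrame(rows).set_index("unit")
    return CountMatrix(collapsed, counts.annotation), cmeta


def filter_low_expression(
    counts: CountMatrix, min_cpm: float = 0.25, min_fraction: float = 0.5
) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least ceil(min_fraction * N) samples."""
    n = counts.counts.shape[1]
    need = int(np.ceil(min_fraction * n))
    keep = (counts.cpm() >= min_cpm).sum(axis=1) >= need
    return counts.subset_genes(counts.genes[keep])


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> float:
    """Weighted trimmed mean of per-gene log2-ratios for one sample vs reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o, r = obs[ok].astype(float), ref[ok].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic binomial variance of M; genes are weighted by its inverse
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = m.size
    # rank-based double trimming, as in the original TMM definition
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean one.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile across samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


# ---------------------------------------------------------------------------
# vectorized negative-binomial GLM


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB2 deviance, rows = genes."""
    mu = np.maximum(mu, 1e-10)
    a = np.maximum(alpha, 1e-10)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    term2 = (y + 1.0 / a) * np.log((y + 1.0 / a) / (mu + 1.0 / a))
    return 2.0 * np.sum(term1 - term2, axis=1)


def _fit_nb_glm(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS fit of NB2 log-linear models for all genes at once.

    y: genes x samples, X: samples x p, offset: per-sample log effective
    library size, alpha: per-gene dispersion (0 allowed = Poisson).
    Returns (beta (genes x p), mu (genes x samples)).
    """
    G, n = y.shape
    p = X.shape[1]
    a = np.asarray(alpha, dtype=float)[:, None]
    # init from log counts
    z0 = np.log(y + 0.5) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # genes x p
    ridge = 1e-9 * np.eye(p)
    for _ in range(n_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        XtWX = np.einsum("gn,ni,nj->gij", W, X, X) + ridge[None, :, :]
        XtWz = np.einsum("gn,ni->gi", W * z, X)
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = new_beta - beta
        beta = new_beta
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
    return beta, np.exp(eta)


def _estimate_dispersion(y: np.ndarray, mu: np.ndarray, df_resid: int) -> np.ndarray:
    """Per-gene dispersion solving the Pearson estimating equation by bisection."""
    lo = np.full(y.shape[0], 1e-8)
    hi = np.full(y.shape[0], 50.0)

    def pearson(alpha: np.ndarray) -> np.ndarray:
        var = mu + alpha[:, None] * mu**2
        return np.sum((y - mu) ** 2 / np.maximum(var, 1e-12), axis=1) - df_resid

    at_floor = pearson(lo) <= 0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        too_small = pearson(mid) > 0
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    alpha = 0.5 * (lo + hi)
    alpha[at_floor] = 1e-8
    return alpha


def _shrink_dispersion(
    alpha: np.ndarray, mean_cpm: np.ndarray, weight_to_trend: float = 0.7
) -> np.ndarray:
    """Shrink log-dispersions toward a lowess trend on log mean CPM."""
    la = np.log(np.maximum(alpha, 1e-8))
    lx = np.log(np.maximum(mean_cpm, 1e-6))
    fit = lowess(la, lx, frac=0.4, return_sorted=False)
    # clamp raw estimates to a window around the trend before mixing: with few
    # residual df the per-gene estimator routinely collapses to ~0 by chance,
    # and an unclamped log-scale average would hand such genes a near-zero
    # dispersion and a wildly inflated test statistic
    la = np.clip(la, fit - 2.0, fit + 4.0)
    shrunk = weight_to_trend * fit + (1.0 - weight_to_trend) * la
    return np.exp(shrunk)


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _moderate_s2(s2: np.ndarray, df: int, prior_df_cap: float = 10.0) -> tuple[np.ndarray, float]:
    """Empirical-Bayes squeeze of per-gene QL dispersions toward a common value.

    Models s2 as scaled F around a prior (s0, d0); returns posterior values
    (d0*s0 + df*s2)/(d0+df) and the prior df d0. The prior df is capped so a
    gene's own deviance always retains weight in its denominator variance —
    with very few residual df the moment estimator often returns an infinite
    prior df, and fully pooling the denominator gives the test chi-square
    tails that are too aggressive for single-gene outliers.
    """
    s2 = np.maximum(s2, 1e-10)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    d0 = 2.0 * _inv_trigamma(evar) if evar > 1e-8 else np.inf
    d0 = float(min(d0, prior_df_cap))
    s0 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0


@dataclass
class DEResult:
    """Per-gene differential-expression table plus the volcano-plot cut-offs."""

    table: pd.DataFrame  # gene, chr21, logFC, PValue, FDR, FDR_chr21, FDR_non21, meanCPM
    p_cutoffs: dict[str, float] = field(default_factory=dict)
    covariate_used: str | None = None
    prior_df: float = float("nan")


def nb_test(
    counts: CountMatrix,
    design: pd.DataFrame,
    coef: str = "trisomy",
    prior_count: float = 2.0,
    tmm: pd.Series | None = None,
    dispersion_shrink: float = 0.7,
) -> pd.DataFrame:
    """Quasi-likelihood F test of one coefficient in a per-gene NB model.

    ``design`` rows must align with sample columns and include an intercept;
    the trisomy column must be binary. Dispersions are estimated per gene,
    shrunk toward a lowess mean-expression trend, and the deviance-based QL
    dispersion is moderated across genes, giving an F statistic with
    moderated denominator degrees of freedom. The reported log2 fold-change
    comes from a fit with ``prior_count`` pseudo-counts (scaled to each
    sample's effective library size) added to stabilize low counts.
    """
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full column rank")
    if coef not in design.columns:
        raise ValueError(f"coefficient {coef!r} not in design")
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    j = list(design.columns).index(coef)
    Xr = np.delete(X, j, axis=1)

    y = counts.counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if tmm is None:
        tmm = tmm_factors(counts)
    eff_lib = lib * tmm.loc[counts.samples].to_numpy()
    offset = np.log(eff_lib)
    mean_cpm = (y / lib[None, :] * 1e6).mean(axis=1)

    # dispersion: Poisson fit -> Pearson bisection -> trended shrinkage
    _, mu0 = _fit_nb_glm(y, X, offset, np.zeros(y.shape[0]))
    alpha_raw = _estimate_dispersion(y, mu0, max(n - p, 1))
    alpha = _shrink_dispersion(alpha_raw, mean_cpm, dispersion_shrink)

    _, mu_full = _fit_nb_glm(y, X, offset, alpha)
    _, mu_red = _fit_nb_glm(y, Xr, offset, alpha)
    dev_full = _nb_deviance(y, mu_full, alpha)
    dev_red = _nb_deviance(y, mu_red, alpha)

    df_resid = n - p
    s2 = dev_full / df_resid
    s2_post, d0 = _moderate_s2(s2, df_resid)
    F = np.maximum(dev_red - dev_full, 0.0) / np.maximum(s2_post, 1e-12)
    pvals = stats.f.sf(F, 1, df_resid + d0)

    # stabilized log2 fold-change via library-size-scaled prior counts
    prior = prior_count * eff_lib / eff_lib.mean()
    beta_aug, _ = _fit_nb_glm(y + prior[None, :], X, offset, alpha)
    logfc = beta_aug[:, j] / np.log(2.0)

    return pd.DataFrame(
        {
            "logFC": logfc,
            "PValue": pvals,
            "meanCPM": mean_cpm,
            "dispersion": alpha,
            "F": F,
        },
        index=counts.genes,
    ).assign(prior_df=d0)


# ---------------------------------------------------------------------------
# stratified FDR


def _bh(p: np.ndarray) -> np.ndarray:
    if p.size == 0:
        return p.astype(float)
    return multipletests(p, method="fdr_bh")[1]


def stratified_fdr(
    pvalues: pd.Series, chr21_flags: pd.Series, fdr_threshold: float = 0.1
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Genome-wide BH plus BH within the chr21 and non-chr21 strata.

    FDR_chr21 is defined only for chr21 genes (NaN elsewhere), FDR_non21 only
    for the complement; each equals BH applied to that stratum's p-values
    alone, so values in one stratum are unaffected by the other. The reported
    p-value cut-off for each column is the largest p-value achieving
    FDR < ``fdr_threshold``; when no gene in a stratum does, the Bonferroni
    cut-off ``fdr_threshold / N_stratum`` is reported instead.
    """
    p = pvalues.to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    flags = chr21_flags.reindex(pvalues.index).to_numpy(dtype=bool)
    out = pd.DataFrame(index=pvalues.index)
    out["FDR"] = _bh(p)
    out["FDR_chr21"] = np.nan
    out["FDR_non21"] = np.nan
    out.loc[flags, "FDR_chr21"] = _bh(p[flags])
    out.loc[~flags, "FDR_non21"] = _bh(p[~flags])

    def cutoff(pv: np.ndarray, fdr: np.ndarray) -> float:
        if pv.size == 0:
            return float("nan")
        passing = pv[fdr < fdr_threshold]
        if passing.size:
            return float(passing.max())
        return float(fdr_threshold / pv.size)

    cutoffs = {
        "p_cutoff": cutoff(p, out["FDR"].to_numpy()),
        "p_cutoff_chr21": cutoff(p[flags], out.loc[flags, "FDR_chr21"].to_numpy()),
        "p_cutoff_non21": cutoff(p[~flags], out.loc[~flags, "FDR_non21"].to_numpy()),
    }
    return out, cutoffs


# ---------------------------------------------------------------------------
# end-to-end DE


def choose_covariate_celltype(proportions: pd.DataFrame) -> str:
    """The cell-type with the largest interquartile range across units."""
    iqr = proportions.quantile(0.75) - proportions.quantile(0.25)
    return str(iqr.idxmax())


def run_de(
    counts: CountMatrix,
    meta: pd.DataFrame,
    collapse: str | None = "line_id",
    covariate_proportions: pd.DataFrame | None = None,
    min_cpm: float = 0.25,
    min_fraction: float = 0.5,
    prior_count: float = 2.0,
    dispersion_shrink: float = 0.7,
    fdr_threshold: float = 0.1,
) -> DEResult:
    """Collapse -> filter -> TMM -> NB QL test -> stratified FDR.

    With ``collapse=None`` every sample is treated as an independent unit —
    the pseudoreplication-prone analysis the collapsed design exists to
    avoid; it is provided for contrast, not for inference. If
    ``covariate_proportions`` (units x cell-types) is given, the cell-type
    with the largest interquartile range is added as an additive covariate.
    """
    if collapse is not None:
        collapsed, cmeta = collapse_replicates(counts, meta, unit=collapse)
    else:
        collapsed = counts
        cmeta = meta.loc[counts.samples, ["trisomic"]].copy()
        cmeta.index.name = "unit"
    n_tri = int(cmeta["trisomic"].sum())
    if n_tri < 2 or (len(cmeta) - n_tri) < 2:
        raise ValueError("need at least two units per trisomy group")

    filtered = filter_low_expression(collapsed, min_cpm=min_cpm, min_fraction=min_fraction)
    tmm = tmm_factors(filtered)
    design = pd.DataFrame(
        {"intercept": 1.0, "trisomy": cmeta["trisomic"].astype(float).to_numpy()},
        index=filtered.samples,
    )
    covariate_used = None
    if covariate_proportions is not None:
        props = covariate_proportions.loc[filtered.samples]
        covariate_used = choose_covariate_celltype(props)
        design[covariate_used] = props[covariate_used].to_numpy()

    table = nb_test(
        filtered,
        design,
        coef="trisomy",
        prior_count=prior_count,
        tmm=tmm,
        dispersion_shrink=dispersion_shrink,
    )
    chr21 = filtered.is_chr21()
    fdr, cutoffs = stratified_fdr(table["PValue"], chr21, fdr_threshold=fdr_threshold)
    table = table.join(fdr)
    table.insert(0, "chr21", chr21)
    prior_df = float(table.pop("prior_df").iloc[0])
    return DEResult(table=table, p_cutoffs=cutoffs, covariate_used=covariate_used, prior_df=prior_df)
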