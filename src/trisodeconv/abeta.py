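"""ELISA quantification of secreted amyloid-beta-40 and the trisomy fold-change.

A four-parameter log-logistic standard curve,

    OD(x) = c + (d - c) / (1 + exp(b * (ln x - ln e))),

is least-squares fitted to a seven-point calibration dilution series. Some
strongly secreting (trisomic) pools can exceed the largest calibration OD, so
their estimated concentrations depend on the upper asymptote d, which the
calibration points cannot pin down; fixing (clamping) d to a value modestly
above the observed ODs (3.0 by default) yields conservative extrapolations
that are insensitive to the exact clamp value. Sample ODs are inverted
through the fitted curve, multiplied by the media dilution factor, and the
trisomy effect is estimated on log2 concentrations after removing the fitted
effect of RNA concentration (a proxy for organoid cell count): per-line means
of normalized log2 values are compared 3 trisomic vs 3 disomic by Welch's
t-test, and the group difference is back-transformed to a fold-change with
its confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .group_tests import welch_t


def fourpl(x, slope: float, lower: float, upper: float, midpoint: float):
    x = np.asarray(x, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp(slope * (np.log(x) - np.log(midpoint))))


@dataclass
class StandardCurve:
    slope: float
    lower: float
    upper: float
    midpoint: float
    clamp_upper: float | None  # the value d was fixed to, or None for a free fit
    residuals: np.ndarray

    def predict(self, x):
        return fourpl(x, self.slope, self.lower, self.upper, self.midpoint)


def fit_standard_curve(
    concentrations, ods, clamp_upper: float | None = 3.0
) -> StandardCurve:
    """Least-squares 4PL fit, with the upper asymptote optionally clamped."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ods, dtype=float)
    if (x <= 0).any():
        raise ValueError("calibration concentrations must be positive")
    if len(set(x.tolist())) < 4:
        raise ValueError("need at least 4 distinct calibration concentrations")
    n_free = 3 if clamp_upper is not None else 4
    if x.size < n_free:
        raise ValueError("fewer calibration points than free parameters")

    lx = np.log(x)
    # data-driven starting values: slope sign from the OD-concentration trend
    c0 = float(y.min()) - 0.01
    d0 = clamp_upper if clamp_upper is not None else float(y.max()) + 0.5
    b0 = -1.0 if np.corrcoef(lx, y)[0, 1] > 0 else 1.0
    e0 = float(np.exp(np.median(lx)))

    if clamp_upper is not None:
        def resid(theta):
            b, c, loge = theta
            return fourpl(x, b, c, clamp_upper, np.exp(loge)) - y
        theta0 = [b0, c0, np.log(e0)]
    else:
        def resid(theta):
            b, c, d, loge = theta
            return fourpl(x, b, c, d, np.exp(loge)) - y
        theta0 = [b0, c0, d0, np.log(e0)]

    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"standard-curve fit did not converge: {sol.message}")
    if clamp_upper is not None:
        b, c, loge = sol.x
        d = float(clamp_upper)
    else:
        b, c, d, loge = sol.x
    curve = StandardCurve(
        slope=float(b),
        lower=float(c),
        upper=float(d),
        midpoint=float(np.exp(loge)),
        clamp_upper=clamp_upper,
        residuals=sol.fun,
    )
    if curve.upper <= curve.lower:
        raise RuntimeError("degenerate fit: upper asymptote below lower")
    return curve


def invert_curve(curve: StandardCurve, od) -> tuple[np.ndarray, np.ndarray]:
    """Concentrations for ODs via the closed-form inverse of the 4PL.

    Returns (concentration, flag) where flag is 0 for a regular inversion,
    -1 for ODs at/below the lower asymptote (concentration 0) and +1 for ODs
    at/above the upper asymptote (censored above; concentration inf). ODs
    above the largest calibration OD but below the asymptote invert to finite
    extrapolated values — conservative under a clamped upper asymptote.
    """
    od = np.atleast_1d(np.asarray(od, dtype=float))
    conc = np.empty_like(od)
    flag = np.zeros(od.shape, dtype=int)
    below = od <= curve.lower
    above = od >= curve.upper
    ok = ~below & ~above
    conc[below] = 0.0
    flag[below] = -1
    conc[above] = np.inf
    flag[above] = 1
    ratio = (curve.upper - curve.lower) / (od[ok] - curve.lower) - 1.0
    conc[ok] = curve.midpoint * ratio ** (1.0 / curve.slope)
    return conc, flag


@dataclass
class AbetaResult:
    pools: pd.DataFrame  # per-pool concentration, normalized log2, flags
    line_means: pd.Series  # per-line mean normalized log2 concentration
    line_geomeans: pd.Series  # back-transformed per-line geometric means
    fold_change: float
    ci_low: float
    ci_high: float
    p_value: float
    rna_coefficient: float
    rna_coefficient_p: float


def estimate_trisomy_effect(
    pools: pd.DataFrame,
    censored: str = "extrapolate",
) -> AbetaResult:
    """Line-level trisomy fold-change in Aβ after RNA-concentration normalization.

    ``pools`` needs columns concentration, rna_concentration, line_id,
    trisomic, batch (one row per pool). The RNA coefficient is estimated by a
    fixed-effect regression of log2 concentration on centred log2 RNA with
    trisomy and batch indicators; normalized values subtract the fitted RNA
    term. Per-line means of normalized log2 values are compared by a 3v3
    Welch test whose back-transformed difference and interval give the fold
    estimate and 95% CI. The default keeps conservative extrapolations for
    ODs above the calibration range; ``censored='strict'`` drops those pools
    instead. ODs at/beyond the asymptotes are unquantifiable and always
    excluded.
    """
    df = pools.copy()
    n_rna_missing = df["rna_concentration"].isna().sum()
    if n_rna_missing:
        df = df[df["rna_concentration"].notna()]
    if censored == "strict" and "above_calibration" in df.columns:
        df = df[~df["above_calibration"]]
    # ODs at/beyond the asymptotes carry no finite estimate in any mode
    df = df[np.isfinite(df["concentration"]) & (df["concentration"] > 0)]
    if df.groupby("line_id").size().min() < 2:
        raise ValueError("need at least two usable pools per line")

    y = np.log2(df["concentration"].to_numpy(dtype=float))
    rna = np.log2(df["rna_concentration"].to_numpy(dtype=float))
    rna_c = rna - rna.mean()
    batches = pd.get_dummies(df["batch"], drop_first=True, dtype=float)
    X = np.column_stack(
        [np.ones(len(df)), rna_c, df["trisomic"].astype(float).to_numpy(), batches.to_numpy()]
    )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(df) - rank
    s2 = resid @ resid / max(dof, 1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_rna = np.sqrt(s2 * XtX_inv[1, 1])
    coef_rna = float(beta[1])
    p_rna = float(2 * stats.t.sf(abs(coef_rna) / se_rna, dof)) if se_rna > 0 else 1.0

    norm_log2 = y - coef_rna * rna_c
    df = df.assign(log2_concentration=y, normalized_log2=norm_log2)
    line_means = df.groupby("line_id")["normalized_log2"].mean()
    tri = df.groupby("line_id")["trisomic"].first().astype(bool)
    x_tri = line_means[tri].to_numpy()
    x_dis = line_means[~tri].to_numpy()
    res = welch_t(x_tri, x_dis)
    diff = x_tri.mean() - x_dis.mean()
    se = np.sqrt(x_tri.var(ddof=1) / x_tri.size + x_dis.var(ddof=1) / x_dis.size)
    tcrit = stats.t.ppf(0.975, res.df) if np.isfinite(res.df) and res.df > 0 else np.nan
    return AbetaResult(
        pools=df,
        line_means=line_means,
        line_geomeans=2.0**line_means,
        fold_change=float(2.0**diff),
        ci_low=float(2.0 ** (diff - tcrit * se)),
        ci_high=float(2.0 ** (diff + tcrit * se)),
        p_value=res.p,
        rna_coefficient=coef_rna,
        rna_coefficient_p=p_rna,
    )


def quantify(
    calibration: pd.DataFrame,
    samples: pd.DataFrame,
    clamp_upper: float | None = 3.0,
    dilution_factor: float = 2.0,
    censored: str = "extrapolate",
) -> tuple[StandardCurve, AbetaResult]:
    """Full quantification: fit curve, invert sample ODs, estimate the fold.

    ``calibration`` has columns concentration and od; ``samples`` has od,
    rna_concentration, line_id, trisomic, batch. The media dilution factor
    (media diluted 1:2 before the assay by default) multiplies inverted
    concentrations.
    """
    curve = fit_standard_curve(
        calibration["concentration"], calibration["od"], clamp_upper=clamp_upper
    )
    conc, flag = invert_curve(curve, samples["od"].to_numpy())
    pools = samples.assign(
        concentration=conc * dilution_factor,
        flag=flag,
        above_calibration=samples["od"].to_numpy() > float(calibration["od"].max()),
    )
    result = estimate_trisomy_effect(pools, censored=censored)
    return curve, result
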