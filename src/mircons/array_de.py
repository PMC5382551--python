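"""Two-color array differential expression with empirical-Bayes moderation.

The stage order mirrors standard two-color practice:

1. *normexp background correction.*  Observed spot intensity is modeled as
   X = B + S with Gaussian background B ~ N(mu, sigma^2) and exponential
   signal S ~ Exp(mean alpha); the corrected intensity is the posterior mean
   E[S | X = x], which is strictly positive and strictly increasing in x.
2. *Control-RNA normalization* (optional): subtract the mean log-ratio of
   designated control probes per array (the role played by a small control
   RNA such as RNU6B).
3. *Within-array robust spline normalization* of M = log2(R/G) on
   A = mean log2 intensity: an iteratively Huber-reweighted cubic B-spline
   trend is removed.
4. *Between-array scaling*: each array's M is rescaled so all arrays share
   the same median absolute deviation (set to the geometric mean of MADs).
5. *Per-probe linear model* (OLS) and *variance moderation*: per-probe
   variances s_g^2 with d_g residual df are shrunk toward a prior s0^2 with
   d0 prior df estimated by matching the mean and variance of log s^2 to
   scaled-F theory (digamma/trigamma inversion).  The moderated t uses the
   posterior variance s2_post = (d0 s0^2 + d_g s_g^2)/(d0 + d_g) on
   d0 + d_g degrees of freedom.
6. *Multiple testing*: Bonferroni or Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.optimize as spo
import scipy.special as spsp
import scipy.stats as sps
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, EstimationError, ParameterError, ScalingError

logger = logging.getLogger(__name__)

TREATED, CONTROL = "treated", "control"


@dataclass(frozen=True)
class NormexpParams:
    """Normal background mean/sd and exponential signal mean, intensity units."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self):
        if not (self.sigma > 0 and self.alpha > 0):
            raise ParameterError("normexp requires sigma > 0 and alpha > 0")


@dataclass
class MAProfile:
    """Per-probe M = log2(R/G) and A = mean log2 intensity for one array."""

    M: np.ndarray
    A: np.ndarray


class LinearFit(NamedTuple):
    beta: np.ndarray             # probes x coefficients
    s2: np.ndarray               # residual variance per probe
    df_resid: int
    stdev_unscaled: np.ndarray   # sqrt(diag((X'X)^-1)), per coefficient


class ModeratedVariances(NamedTuple):
    d0: float
    s0_2: float
    s2_post: np.ndarray
    df_total: np.ndarray


@dataclass
class DEResult:
    """Per-probe moderated-t results plus the global prior (d0, s0^2)."""

    table: pd.DataFrame          # probe_id, log2fc, s2, t_mod, p, p_adj, rank, significant
    d0: float
    s0_2: float
    alpha: float
    adjust_method: str


# ---------------------------------------------------------------- normexp ---

def _normexp_nll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma, alpha = np.exp(log_sigma), np.exp(log_alpha)
    # log density of X = N(mu, sigma^2) + Exp(mean alpha)
    z = (x - mu) / sigma - sigma / alpha
    ll = (-np.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2)
          + sps.norm.logcdf(z))
    return -float(ll.sum())


def estimate_normexp_params(observed: Sequence[float]) -> NormexpParams:
    """Maximum-likelihood fit of the Normal+Exponential convolution.

    Starts from method-of-moments values (the exponential component carries
    all the skewness: its third central moment is 2 alpha^3) and refines by
    numerical likelihood maximization.
    """
    x = np.asarray(observed, dtype=float)
    if x.size < 50:
        raise EstimationError(f"need >= 50 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise EstimationError("constant input: normexp parameters unidentifiable")
    mean, var = x.mean(), x.var()
    m3 = np.mean((x - mean) ** 3)
    alpha0 = max((m3 / 2) ** (1 / 3) if m3 > 0 else np.sqrt(var) / 2, 1e-3 * np.sqrt(var))
    sigma0 = np.sqrt(max(var - alpha0**2, 1e-4 * var))
    mu0 = mean - alpha0
    theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    res = spo.minimize(_normexp_nll, theta0, args=(x,), method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8})
    mu, log_sigma, log_alpha = res.x
    return NormexpParams(float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha)))


def normexp_transform(x, params: NormexpParams):
    """Posterior mean signal E[S | X = x]; strictly positive and increasing.

    E[S|X=x] = mu_s + sigma * phi(mu_s/sigma) / Phi(mu_s/sigma) with
    mu_s = x - mu - sigma^2/alpha.  The inverse Mills ratio is evaluated via
    the scaled complementary error function, which is stable for
    mu_s/sigma << 0 (the naive ratio would return 0/0).
    """
    x_arr = np.asarray(x, dtype=float)
    mu_s = x_arr - params.mu - params.sigma**2 / params.alpha
    z = mu_s / params.sigma
    # phi(z)/Phi(z) = sqrt(2/pi) / erfcx(-z/sqrt(2))
    inv_mills = np.sqrt(2 / np.pi) / spsp.erfcx(-z / np.sqrt(2))
    out = mu_s + params.sigma * inv_mills
    out = np.maximum(out, np.finfo(float).tiny)
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------- normalization ---

def normalize_within_array(
    profile: MAProfile, spline_df: int = 5, iterations: int = 10
) -> MAProfile:
    """Remove a robust cubic B-spline trend of M on A.

    Knots sit at equally spaced A-quantiles; Huber weights (c = 1.345 on the
    MAD scale) are re-estimated for ``iterations`` rounds.  With fewer than
    ``5 * spline_df`` probes the fit is unreliable and the function falls
    back to median-centering with a logged warning.
    """
    if spline_df < 4:
        raise ParameterError("spline_df must be >= 4 for a cubic spline")
    M = np.asarray(profile.M, dtype=float)
    A = np.asarray(profile.A, dtype=float)
    n = M.size
    if n < 5 * spline_df:
        logger.warning(
            "only %d probes for spline_df=%d: falling back to median-centering",
            n, spline_df,
        )
        return MAProfile(M - np.median(M), A.copy())

    k = 3
    n_interior = spline_df - (k + 1)
    lo, hi = A.min(), A.max()
    if hi - lo <= 0:
        return MAProfile(M - np.median(M), A.copy())
    interior = np.quantile(A, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
    knots = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    X = BSpline.design_matrix(np.clip(A, lo, hi), knots, k).toarray()

    w = np.ones(n)
    coef = np.zeros(X.shape[1])
    for _ in range(iterations):
        Xw = X * w[:, None]
        coef, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ M, rcond=None)
        resid = M - X @ coef
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            break
        u = np.abs(resid) / scale
        w = np.minimum(1.0, 1.345 / np.maximum(u, 1e-12))
    trend = X @ coef
    return MAProfile(M - trend, A.copy())


def scale_between_arrays(M: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-array spread: divide by each array's MAD, rescale to the
    geometric mean of MADs.  After the operation all arrays share one MAD."""
    if M.shape[1] < 2:
        raise ParameterError("between-array scaling needs >= 2 arrays")
    mads = M.apply(lambda col: sps.median_abs_deviation(col.dropna()), axis=0)
    zero = mads.index[mads <= 0].tolist()
    if zero:
        raise ScalingError(f"zero-MAD array(s): {zero}")
    target = float(np.exp(np.mean(np.log(mads))))
    return M.div(mads, axis=1) * target


# ------------------------------------------------------------ statistics ---

def fit_linear_model(M: pd.DataFrame, design: pd.DataFrame) -> LinearFit:
    """Ordinary least squares per probe against the array x coefficient design."""
    X = design.to_numpy(dtype=float)
    n_arrays, n_coef = X.shape
    if np.linalg.matrix_rank(X) < n_coef:
        raise DesignError("design matrix is rank-deficient")
    if n_arrays < n_coef + 1:
        raise DesignError(
            f"need >= {n_coef + 1} arrays for {n_coef} coefficient(s), got {n_arrays}"
        )
    Y = M.to_numpy(dtype=float).T            # arrays x probes
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                 # coefficients x probes
    resid = Y - X @ beta
    df = n_arrays - n_coef
    s2 = (resid**2).sum(axis=0) / df
    return LinearFit(beta.T, s2, df, np.sqrt(np.diag(xtx_inv)))


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on x -> trigamma(x), as used for scaled-F moment matching
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = spsp.polygamma(1, x)
        dif = tri * (1 - tri / y) / spsp.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(
    s2: Sequence[float],
    df_resid: int | Sequence[int],
    d0_override: float | None = None,
) -> ModeratedVariances:
    """Estimate the variance prior (d0, s0^2) and posterior variances.

    Under the hierarchical model s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_{d_g}/d_g
    with 1/sigma_g^2 ~ chi2_{d0}/(d0 s0^2), the log sample variances follow a
    scaled-F distribution whose mean and variance involve digamma/trigamma
    functions of d_g/2 and d0/2; matching moments and inverting the trigamma
    yields (d0, s0^2).  ``d0_override=0`` disables pooling (ordinary t);
    ``d0_override=inf`` pools fully.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df_resid, dtype=float), s2.shape)
    if (s2 < 0).any():
        raise ParameterError("negative variances")
    pos = s2 > 0
    if pos.sum() < 10:
        raise EstimationError("need >= 10 probes with positive variance")

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            return ModeratedVariances(0.0, float(np.exp(np.mean(np.log(s2[pos])))),
                                      s2.copy(), df.copy())
    else:
        z = np.log(s2[pos])
        dd = df[pos]
        e = z - spsp.digamma(dd / 2) + np.log(dd / 2)
        emean = e.mean()
        evar = e.var(ddof=1) if e.size > 1 else 0.0
        if np.var(z) < 1e-12:
            # zero dispersion of log s2: fully pooled at the common value
            d0 = np.inf
            s0_2 = float(np.exp(np.mean(z)))
            s2_post = np.full_like(s2, s0_2)
            return ModeratedVariances(d0, s0_2, s2_post, np.full_like(s2, np.inf))
        evar_resid = evar - np.mean(spsp.polygamma(1, dd / 2))
        if evar_resid > 0:
            d0 = 2 * _trigamma_inverse(evar_resid)
            if not np.isfinite(d0):
                logger.warning("trigamma inversion non-convergent: pooling fully")
                d0 = np.inf
        else:
            d0 = np.inf

    if np.isinf(d0):
        z = np.log(s2[pos])
        dd = df[pos]
        e = z - spsp.digamma(dd / 2) + np.log(dd / 2)
        s0_2 = float(np.exp(e.mean()))
        s2_post = np.full_like(s2, s0_2)
        return ModeratedVariances(float(d0), s0_2, s2_post, np.full_like(s2, np.inf))

    z = np.log(s2[pos])
    dd = df[pos]
    e = z - spsp.digamma(dd / 2) + np.log(dd / 2)
    s0_2 = float(np.exp(e.mean() + spsp.digamma(d0 / 2) - np.log(d0 / 2)))
    s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    return ModeratedVariances(float(d0), s0_2, s2_post, d0 + df)


def moderated_t(
    beta: np.ndarray, stdev_unscaled: float, mod: ModeratedVariances
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p on d0 + d_g degrees of freedom."""
    se = stdev_unscaled * np.sqrt(mod.s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    df = mod.df_total
    p = np.where(np.isinf(df), 2 * sps.norm.sf(np.abs(t)),
                 2 * sps.t.sf(np.abs(t), df=np.where(np.isinf(df), 1, df)))
    return t, p


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Bonferroni (min(1, m p)) or Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ParameterError(f"unknown adjustment method {method!r}")


class DECall(NamedTuple):
    significant: pd.DataFrame
    top: pd.DataFrame


def call_de(results: DEResult, alpha: float = 1e-4, top_n: int = 100) -> DECall:
    """Significant probes at adjusted p < alpha, and the top_n ranking.

    Ranking: ascending adjusted p, ties broken by |log2fc| descending, then
    probe id lexicographic.
    """
    tab = results.table.copy()
    tab["_abs"] = tab["log2fc"].abs()
    tab = tab.sort_values(["p_adj", "_abs", "probe_id"],
                          ascending=[True, False, True], kind="mergesort")
    tab = tab.drop(columns="_abs").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab["significant"] = tab["p_adj"] < alpha
    return DECall(tab[tab["significant"]].copy(), tab.head(top_n).copy())


# ------------------------------------------------------------ full chain ---

def de_analysis(
    sim,
    normalize_to_controls: bool = True,
    spline_df: int = 5,
    adjust: str = "bonferroni",
    alpha: float = 1e-4,
    top_n: int = 100,
    d0_override: float | None = None,
) -> tuple[DEResult, DECall]:
    """Run the full two-color DE chain on an ArraySimulation-like object.

    Expects attributes foreground_red/foreground_green (probe x array
    DataFrames), probe_ids, control_probe_ids and group_labels.  Background
    correction estimates normexp parameters per array and channel on the
    observed foreground intensities.
    """
    fg_r, fg_g = sim.foreground_red, sim.foreground_green
    arrays = list(fg_r.columns)
    probes = list(fg_r.index)
    M_cols, A_cols = {}, {}
    for a in arrays:
        r = normexp_transform(fg_r[a].to_numpy(),
                              estimate_normexp_params(fg_r[a].to_numpy()))
        g = normexp_transform(fg_g[a].to_numpy(),
                              estimate_normexp_params(fg_g[a].to_numpy()))
        M = np.log2(r) - np.log2(g)
        A = (np.log2(r) + np.log2(g)) / 2
        if normalize_to_controls and len(sim.control_probe_ids):
            ctrl = [probes.index(p) for p in sim.control_probe_ids]
            M = M - M[ctrl].mean()
        prof = normalize_within_array(MAProfile(M, A), spline_df=spline_df)
        M_cols[a], A_cols[a] = prof.M, prof.A
    M = pd.DataFrame(M_cols, index=probes)
    M = scale_between_arrays(M)

    groups = sim.group_labels.reindex(arrays)
    design = pd.DataFrame(
        {"intercept": 1.0, "treated": (groups == TREATED).astype(float)},
        index=arrays,
    )
    fit = fit_linear_model(M, design)
    mod = moderate_variances(fit.s2, fit.df_resid, d0_override=d0_override)
    beta = fit.beta[:, 1]
    t, p = moderated_t(beta, fit.stdev_unscaled[1], mod)
    p_adj = adjust_pvalues(p, method=adjust)
    table = pd.DataFrame(
        {"probe_id": probes, "log2fc": beta, "s2": fit.s2,
         "df_resid": fit.df_resid, "t_mod": t, "p": p, "p_adj": p_adj}
    )
    result = DEResult(table, mod.d0, mod.s0_2, alpha, adjust)
    return result, call_de(result, alpha=alpha, top_n=top_n)
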