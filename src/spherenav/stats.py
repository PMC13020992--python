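"""Inferential machinery for the navigation analyses.

Covers the full analysis path used on the behavioral (here: synthetic)
data: interquartile-range outlier filtering, linear mixed models with
by-participant random intercepts and slopes compared through
BIC-approximated Bayes factors (BF ≈ exp(ΔBIC / 2)), per-participant
ordinary R², a sweep over spherical-model radii, the short/long
object-location contrast with a default-prior (JZS) Bayesian paired
t-test, and the Bayes-factor design analysis used for sample-size
planning.

Mixed models are fitted by full maximum likelihood (not REML): the
models being compared differ in their fixed effects, and ΔBIC is only
meaningful on full likelihoods.  The BIC parameter count includes fixed
effects, the unique random-effect (co)variances and the residual
variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .geometry import Geometry, PLANE
from .triangle import TriangleShape, ideal_inbound

__all__ = [
    "DISTANCE_THRESHOLD_DEG",
    "DEFAULT_PRIOR_SCALE",
    "ModelFit",
    "ComparisonResult",
    "TTestResult",
    "attach_ideal_predictors",
    "predictor_column",
    "filter_outliers_triangle",
    "filter_outliers_position",
    "fit_geometry_lmm",
    "bf_from_bic",
    "compare_geometries",
    "per_participant_r2",
    "radius_sweep_analysis",
    "split_short_long",
    "interaction_ttest",
    "jzs_bf10",
    "bfda_power",
]

#: Short/long split for object-location start–target distances.
DISTANCE_THRESHOLD_DEG = 110.0
#: Default Cauchy prior scale of the Bayesian t-test, r = sqrt(2)/2.
DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass
class ModelFit:
    """A fitted mixed (or degenerate) model, with its BIC ingredients."""

    predictor: str
    dv: str
    loglik: float
    n_obs: int
    k_params: int
    bic: float
    fe_params: dict
    re_cov: np.ndarray | None
    resid_var: float
    singular: bool = False
    converged: bool = True


@dataclass
class ComparisonResult:
    bf: float
    log_bf: float
    winner: str
    fits: dict
    per_participant_r2: dict


@dataclass
class TTestResult:
    bf10: float
    t_statistic: float
    df: int
    cohens_d: float
    prior_scale: float = DEFAULT_PRIOR_SCALE
    n: int = 0
    mean_diff: float = float("nan")


# ------------------------------------------------------------ predictors

def predictor_column(predictor, dv: str) -> str:
    """Column name of an ideal-response predictor.

    ``predictor`` is ``"planar"``, ``"spherical"`` (scale 1) or a tuple
    ``("spherical", scale)``; ``dv`` is ``"turn"`` or ``"distance"``.
    """
    if dv not in ("turn", "distance"):
        raise ValueError("dv must be 'turn' or 'distance'")
    tag = "turn" if dv == "turn" else "dist"
    if predictor == "planar":
        return f"ideal_{tag}_planar"
    if predictor == "spherical":
        return f"ideal_{tag}_sphere"
    if isinstance(predictor, tuple) and predictor[0] == "spherical":
        scale = float(predictor[1])
        if scale == 1.0:
            return f"ideal_{tag}_sphere"
        return f"ideal_{tag}_sphere_{scale:g}"
    raise ValueError(f"unknown predictor {predictor!r}")


def attach_ideal_predictors(
    trials: pd.DataFrame,
    design: list[TriangleShape],
    scales: tuple[float, ...] = (),
) -> pd.DataFrame:
    """Join ideal planar and spherical turn/distance predictors by shape.

    The planar predictor always uses plane trigonometry regardless of
    the environment; spherical predictors use great-circle geometry at
    the requested radius scales (scale 1 is always included).
    """
    rows = []
    for shape in design:
        if shape.side != "right":
            continue  # pooled predictors: one row per base shape
        rec = {"shape_id": shape.shape_id}
        pl = ideal_inbound(shape, PLANE)
        rec["ideal_turn_planar"] = pl.pooled_turn
        rec["ideal_dist_planar"] = pl.distance
        for s in (1.0, *scales):
            sol = ideal_inbound(shape, Geometry("spherical", s))
            suffix = "" if s == 1.0 else f"_{s:g}"
            rec[f"ideal_turn_sphere{suffix}"] = sol.pooled_turn
            rec[f"ideal_dist_sphere{suffix}"] = sol.distance
        rows.append(rec)
    pred = pd.DataFrame(rows).drop_duplicates("shape_id")
    return trials.merge(pred, on="shape_id", how="left", validate="m:1")


# -------------------------------------------------------------- outliers

def _iqr_fences(x: np.ndarray) -> tuple[float, float]:
    """Tukey fences with linearly interpolated (type-7) quartiles."""
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def filter_outliers_triangle(
    trials: pd.DataFrame,
    turn_col: str = "response_turn_deg",
    dist_col: str = "response_distance_deg",
    group_col: str = "shape_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove trials whose turn OR distance falls outside 1.5×IQR fences
    computed across all participants within each triangle shape.

    Returns ``(kept, removed)``.  Shape groups with fewer than 4 trials
    are skipped (kept in full) with a warning.
    """
    keep_mask = pd.Series(True, index=trials.index)
    for shape, grp in trials.groupby(group_col):
        if len(grp) < 4:
            warnings.warn(
                f"shape group {shape!r} has {len(grp)} trials; "
                "outlier rule skipped", stacklevel=2,
            )
            continue
        lo_t, hi_t = _iqr_fences(grp[turn_col].to_numpy())
        lo_d, hi_d = _iqr_fences(grp[dist_col].to_numpy())
        bad = (
            (grp[turn_col] < lo_t) | (grp[turn_col] > hi_t)
            | (grp[dist_col] < lo_d) | (grp[dist_col] > hi_d)
        )
        keep_mask.loc[grp.index[bad]] = False
    return trials[keep_mask], trials[~keep_mask]


def filter_outliers_position(
    trials: pd.DataFrame,
    value_col: str = "position_error_deg",
    group_col: str = "participant_id",
) -> pd.DataFrame:
    """Remove object-location trials with a position error outside the
    1.5×IQR fences computed within each participant."""
    keep_mask = pd.Series(True, index=trials.index)
    for pid, grp in trials.groupby(group_col):
        if len(grp) < 4:
            warnings.warn(
                f"participant {pid!r} has {len(grp)} trials; "
                "outlier rule skipped", stacklevel=2,
            )
            continue
        lo, hi = _iqr_fences(grp[value_col].to_numpy())
        bad = (grp[value_col] < lo) | (grp[value_col] > hi)
        keep_mask.loc[grp.index[bad]] = False
    return trials[keep_mask]


# ---------------------------------------------------------- mixed models

_DV_COLS = {"turn": "response_turn_deg", "distance": "response_distance_deg"}


def _fit_best(model, free=None):
    """Run the ML fit under two optimizers and keep the higher likelihood.

    The marginal likelihood's variance-parameter profile can be flat;
    L-BFGS converges sharply on well-conditioned problems while Powell
    is more robust on noisy ones, so the better of the two is kept.
    """
    best = None
    # Nelder-Mead ignores the `free` restriction mask in statsmodels, so
    # it is only used for unrestricted fits
    methods = ("lbfgs", "powell") if free is not None else \
        ("lbfgs", "powell", "nm")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in methods:
            try:
                res = model.fit(reml=False, method=method, maxiter=2000,
                                free=free)
            except Exception:
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
    if best is None:
        raise RuntimeError("mixed-model fit failed under all optimizers")
    return best


def fit_geometry_lmm(
    trials: pd.DataFrame,
    predictor,
    dv: str = "turn",
) -> ModelFit:
    """Fit ``dv ~ ideal predictor`` with by-participant random intercept
    and slope, by full maximum likelihood.

    ``predictor`` may be ``"planar"``, ``"spherical"``, a
    ``("spherical", scale)`` tuple, or ``"combined"`` (both planar and
    spherical predictors, each with fixed and random slopes).  Singular
    random-effect covariances are refitted with a diagonal structure and
    flagged.  BIC = k·ln(n) − 2·logLik with k = fixed effects + unique
    random (co)variances + residual variance.
    """
    dvcol = _DV_COLS[dv]
    if trials["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if trials["shape_id"].nunique() < 2:
        raise ValueError("need at least 2 triangle shapes")
    if predictor == "combined":
        xcols = [predictor_column("planar", dv),
                 predictor_column("spherical", dv)]
        label = "combined"
    else:
        xcols = [predictor_column(predictor, dv)]
        label = (
            predictor if isinstance(predictor, str)
            else f"spherical(x{predictor[1]:g})"
        )
    y = trials[dvcol].to_numpy(dtype=float)
    X = sm.add_constant(trials[xcols].to_numpy(dtype=float))
    groups = trials["participant_id"].to_numpy()
    n = len(y)

    # perfectly deterministic data (zero residual anywhere) makes the ML
    # likelihood unbounded; report the exact least-squares solution
    ols = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ ols[0]) ** 2))
    if sse / n < 1e-18 * max(1.0, float(np.var(y))):
        fe = {c: v for c, v in zip(["const", *xcols], ols[0])}
        q = X.shape[1]
        k = q + q * (q + 1) // 2 + 1
        return ModelFit(
            predictor=label, dv=dv, loglik=math.inf, n_obs=n, k_params=k,
            bic=-math.inf, fe_params=fe, re_cov=np.zeros((q, q)),
            resid_var=0.0, singular=True, converged=True,
        )

    model = sm.MixedLM(y, X, groups=groups, exog_re=X)
    res = _fit_best(model)
    q = X.shape[1]
    cov_re = np.asarray(res.cov_re)
    ev = np.linalg.eigvalsh(cov_re)
    singular = bool(ev.min() < 1e-8 * max(ev.max(), 1e-12))
    n_recov = q * (q + 1) // 2
    if singular:
        # diagonal random-effect covariance fallback
        free = MixedLMParams.from_components(
            fe_params=np.ones(q), cov_re=np.eye(q)
        )
        res = _fit_best(model, free=free)
        cov_re = np.asarray(res.cov_re)
        n_recov = q
    k = q + n_recov + 1
    llf = float(res.llf)
    bic = k * math.log(n) - 2.0 * llf
    fe = {c: float(v) for c, v in zip(["const", *xcols], res.fe_params)}
    return ModelFit(
        predictor=label, dv=dv, loglik=llf, n_obs=n, k_params=k, bic=bic,
        fe_params=fe, re_cov=cov_re, resid_var=float(res.scale),
        singular=singular, converged=bool(res.converged),
    )


def bf_from_bic(fit_a: ModelFit, fit_b: ModelFit) -> float:
    """Bayes factor for model a over model b, approximated as
    exp((BIC_b − BIC_a) / 2).  Requires fits on the same observations."""
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("fits are not on the same observations")
    if fit_a.dv != fit_b.dv:
        raise ValueError("fits have different dependent variables")
    delta = fit_b.bic - fit_a.bic
    if delta > 1400:
        return math.inf
    return math.exp(delta / 2.0)


def per_participant_r2(
    trials: pd.DataFrame, predictor, dv: str = "turn"
) -> tuple[dict, float, float]:
    """Ordinary least-squares R² of the response on the ideal predictor,
    per participant, plus the mean ± sd summary."""
    dvcol = _DV_COLS[dv]
    xcol = predictor_column(predictor, dv)
    out = {}
    for pid, grp in trials.groupby("participant_id"):
        if len(grp) < 3:
            warnings.warn(f"participant {pid!r}: fewer than 3 trials, skipped",
                          stacklevel=2)
            continue
        x = grp[xcol].to_numpy(dtype=float)
        y = grp[dvcol].to_numpy(dtype=float)
        if np.var(x) < 1e-12:
            warnings.warn(
                f"participant {pid!r}: zero-variance predictor, R² undefined",
                stacklevel=2,
            )
            continue
        sxy = np.cov(x, y, bias=True)
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst < 1e-18:
            out[pid] = 1.0
            continue
        beta = sxy[0, 1] / sxy[0, 0]
        alpha = y.mean() - beta * x.mean()
        sse = float(np.sum((y - alpha - beta * x) ** 2))
        out[pid] = 1.0 - sse / sst
    vals = np.array(list(out.values()))
    return out, float(vals.mean()), float(vals.std(ddof=1))


def compare_geometries(
    trials: pd.DataFrame, dv: str = "turn"
) -> ComparisonResult:
    """Planar vs. spherical mixed-model comparison for one response
    variable, with BF = exp(ΔBIC/2) evidence for the planar model."""
    fit_p = fit_geometry_lmm(trials, "planar", dv)
    fit_s = fit_geometry_lmm(trials, "spherical", dv)
    delta = fit_s.bic - fit_p.bic
    bf = bf_from_bic(fit_p, fit_s)
    r2 = {
        "planar": per_participant_r2(trials, "planar", dv),
        "spherical": per_participant_r2(trials, "spherical", dv),
    }
    return ComparisonResult(
        bf=bf,
        log_bf=delta / 2.0,
        winner="planar" if bf > 1 else "spherical",
        fits={"planar": fit_p, "spherical": fit_s},
        per_participant_r2=r2,
    )


def radius_sweep_analysis(
    trials: pd.DataFrame,
    scales: tuple[float, ...],
    dv: str = "turn",
) -> tuple[pd.DataFrame, pd.Series]:
    """Spherical models across radii, against the planar model.

    Returns a table with one row per radius scale (group-level BIC and
    the BF of the planar model over that spherical model) and a Series
    mapping each participant to their best-fitting radius scale by
    individual ordinary regression.
    """
    if 1.0 not in scales:
        raise ValueError("scales must include 1.0")
    fit_p = fit_geometry_lmm(trials, "planar", dv)
    rows = []
    per_part: dict = {}
    for s in sorted(scales):
        fit_s = fit_geometry_lmm(trials, ("spherical", s), dv)
        rows.append(
            {
                "radius_scale": s,
                "bic": fit_s.bic,
                "n_obs": fit_s.n_obs,
                "bf_planar_over_sphere": bf_from_bic(fit_p, fit_s),
            }
        )
        r2map, _, _ = per_participant_r2(trials, ("spherical", s), dv)
        for pid, r2 in r2map.items():
            per_part.setdefault(pid, {})[s] = r2
    table = pd.DataFrame(rows)
    best = pd.Series(
        {pid: max(r2s, key=r2s.get) for pid, r2s in per_part.items()},
        name="best_radius_scale",
    )
    return table, best


# ------------------------------------------------- object-location tests

def split_short_long(
    trials: pd.DataFrame,
    distance_col: str = "distance_deg",
    threshold: float = DISTANCE_THRESHOLD_DEG,
) -> pd.DataFrame:
    """Label trials short/long by start–target distance (> threshold →
    long; the threshold itself is short)."""
    out = trials.copy()
    out["condition"] = np.where(
        out[distance_col] > threshold, "long", "short"
    )
    return out


def jzs_bf10(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """One-sample JZS Bayes factor (alternative over null) for a t
    statistic from n paired observations.

    The effect-size prior is Cauchy(0, r), expressed as the scale
    mixture δ | g ~ N(0, g r²), g ~ InverseGamma(1/2, 1/2); the Bayes
    factor is evaluated by adaptive quadrature of the resulting
    one-dimensional integral.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if math.isinf(t):
        return math.inf  # degenerate data: evidence saturates
    nu = n - 1

    def integrand(g: float) -> float:
        a = 1.0 + n * g * r * r
        log_m = (
            -0.5 * math.log(a)
            - 0.5 * (nu + 1) * math.log1p(t * t / (a * nu))
        )
        log_pi = (
            -0.5 * math.log(2.0 * math.pi)
            - 1.5 * math.log(g)
            - 1.0 / (2.0 * g)
        )
        return math.exp(log_m + log_pi)

    num, _ = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-8, limit=200)
    log_den = -0.5 * (nu + 1) * math.log1p(t * t / nu)
    return num / math.exp(log_den)


def interaction_ttest(
    trials: pd.DataFrame,
    value_col: str = "direction_error_deg",
    two_sided: bool = True,
) -> TTestResult:
    """Distance × environment interaction on per-participant cell means.

    For each participant computes (long − short) on the sphere minus
    (long − short) on the plane, then a paired JZS Bayesian t-test
    (Cauchy prior scale √2/2) plus the classical t and Cohen's d.
    Participants missing any of the four cells are dropped with a
    warning.
    """
    diffs = []
    for pid, grp in trials.groupby("participant_id"):
        cells = grp.groupby(["environment", "condition"])[value_col].mean()
        try:
            d = (
                cells[("sphere", "long")] - cells[("sphere", "short")]
            ) - (cells[("plane", "long")] - cells[("plane", "short")])
        except KeyError:
            warnings.warn(f"participant {pid!r} missing cells; dropped",
                          stacklevel=2)
            continue
        diffs.append(d)
    x = np.asarray(diffs, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 complete participants")
    sd = x.std(ddof=1)
    if sd < 1e-12:
        t = 0.0 if abs(x.mean()) < 1e-12 else math.copysign(math.inf, x.mean())
        d = 0.0 if t == 0.0 else math.copysign(math.inf, x.mean())
    else:
        t = x.mean() / (sd / math.sqrt(n))
        d = x.mean() / sd
    bf = jzs_bf10(t, n)
    return TTestResult(
        bf10=bf, t_statistic=float(t), df=n - 1, cohens_d=float(d),
        n=n, mean_diff=float(x.mean()),
    )


# ------------------------------------------------------- power analysis

def bfda_power(
    d: float,
    n: int = 20,
    iterations: int = 1000,
    threshold: float = 3.0,
    seed: int = 0,
    r: float = DEFAULT_PRIOR_SCALE,
) -> tuple[float, float]:
    """Bayes-factor design analysis for the paired t-test.

    Simulates ``iterations`` experiments of ``n`` paired differences
    drawn from Normal(d, 1), computes the JZS Bayes factor of each, and
    returns ``(hit_rate, false_positive_rate)`` in percent: the share of
    simulations with BF₁₀ ≥ threshold under the stated effect size and
    under the null (d = 0) respectively.
    """
    if n < 2 or iterations < 1:
        raise ValueError("need n >= 2 and iterations >= 1")
    rng = np.random.default_rng(seed)

    def rate(effect: float) -> float:
        hits = 0
        for _ in range(iterations):
            x = rng.normal(effect, 1.0, size=n)
            t = x.mean() / (x.std(ddof=1) / math.sqrt(n))
            if jzs_bf10(float(t), n, r) >= threshold:
                hits += 1
        return 100.0 * hits / iterations

    return rate(d), rate(0.0)
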