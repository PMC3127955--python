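"""Weighted least-squares fitting and nested F-test comparison.

Trial tables are aggregated per condition (optionally collapsing mirror
pairs of orientations across the vertical axis), each model's kernel
parameters are estimated by minimizing the weighted residual sum of squares
(WRSS) with inverse-variance weights, and nested models are compared with

    F = ((WRSS_1 - WRSS_2) / (p_2 - p_1)) / (WRSS_2 / (n - p_2)),

where model 1 is the restricted model, p_i are free-parameter counts and
``n`` is the number of underlying trials (so the default design gives F
degrees of freedom (2, 1078), (4, 1074) and (15, 1062) for the three
canonical comparisons).

Identifiability note: the predicted bias depends on a kernel only through
the covariance *difference* ``a_v**2 - a_h**2`` (and the covariance term
``r``), so the mean-bias objective is exactly flat along the ridge of
kernels sharing that difference and cannot pin down the absolute kernel
scale.  :func:`fit_model` therefore selects the point on the ridge in a
second stage, from the within-condition response dispersion: the rounder
the smoothed profile, the noisier the adjustment, and that roundness —
unlike the bias — depends on the absolute scale.  WRSS, F tests and
explained variances are unaffected by the second stage (the ridge is flat);
only the reported radii are.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .angles import canonical_orientation, wrap_bias
from .bias_model import (
    ConditionGrid,
    ModelSpec,
    predict_for_conditions,
)

__all__ = [
    "VARIANCE_FLOOR",
    "AggregationError",
    "NonConvergenceError",
    "AggregatedConditions",
    "FitResult",
    "FTestResult",
    "aggregate_pairs",
    "aggregate_conditions",
    "wls_objective",
    "trial_wrss",
    "fit_model",
    "nested_f_test",
    "explained_variance",
    "systematic_ceiling",
]

#: Per-condition variance floor, degrees squared.  One probe step is 1 deg,
#: so quantization alone bounds the resolvable variance; flooring at
#: (0.5 deg)^2 keeps inverse-variance weights finite.
VARIANCE_FLOOR = 0.25

#: Finite penalty returned by the objective for infeasible kernel
#: parameters; ordered above every feasible objective value.
_PENALTY = 1e12

#: Start-grid range (degrees) for the multistart optimizer.
_START_RANGE = (0.1, 6.0)
_BOUNDS_A = (1e-3, 20.0)
_BOUNDS_RHO = (-0.99, 0.99)

#: Nesting partial order (restricted kind -> kinds it is nested in).
_NESTED_IN = {
    "isotropic": {
        "homogeneous",
        "homogeneous_oriented",
        "radial_heterogeneous",
        "angular_heterogeneous",
    },
    "homogeneous": {
        "homogeneous_oriented",
        "radial_heterogeneous",
        "angular_heterogeneous",
    },
    "homogeneous_oriented": {"angular_heterogeneous"},
}


class AggregationError(ValueError):
    """The trial table cannot be collapsed onto mirror pairs."""


class NonConvergenceError(RuntimeError):
    """Every optimizer start failed; carries per-start diagnostics."""


def _circ_mean(biases) -> float:
    """Mean bias on the 180-degree orientation circle.

    Orientation biases live on a periodic interval (-90, 90]; near-wrap
    distributions (large bias plus noise) make the arithmetic mean
    meaningless, so means are taken circularly.
    """
    return float(stats.circmean(np.asarray(biases, dtype=float), low=-90.0, high=90.0))


def _circ_var(biases) -> float:
    """Unbiased-ish circular variance (degrees^2) on the orientation circle."""
    x = np.asarray(biases, dtype=float)
    n = x.size
    sd = float(stats.circstd(x, low=-90.0, high=90.0))
    return sd**2 * n / max(n - 1, 1)


def _circ_wmean(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted circular mean on the 180-degree orientation circle."""
    ang = np.asarray(values, dtype=float) * np.pi / 90.0
    w = np.asarray(weights, dtype=float)
    s = float(np.sum(w * np.sin(ang)))
    c = float(np.sum(w * np.cos(ang)))
    return wrap_bias(np.degrees(np.arctan2(s, c)) * 0.5)


def _pooled(group: pd.DataFrame) -> pd.Series:
    dof = (group["_count"] - 1).sum()
    pooled_var = (
        ((group["_count"] - 1) * group["_var"]).sum() / dof if dof > 0 else np.nan
    )
    return pd.Series(
        {
            "mean_bias": _circ_wmean(
                group["_mean"].to_numpy(), group["_count"].to_numpy()
            ),
            "variance": max(pooled_var, VARIANCE_FLOOR),
            "n": int(group["_count"].sum()),
            "within_ss": float(((group["_count"] - 1) * group["_var"]).sum()),
        }
    )


def aggregate_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial table onto mirror-pair x aspect-ratio conditions.

    Orientations theta and 180 - theta are mirror images across the
    vertical axis; under the smoothing model their biases are equal and
    opposite, so the signed biases (bias at theta, -bias at 180 - theta)
    are averaged onto the canonical member theta in (0, 90).  Variances are
    pooled within pairs and floored at :data:`VARIANCE_FLOOR`; counts are
    summed.  Twelve raw orientations collapse to six.

    Means and variances are circular (period-180): where the model bias is
    large, response noise straddles the +/-90 wrap of bias space and
    arithmetic moments would be badly distorted.

    Raises :class:`AggregationError` if a non-cardinal orientation lacks
    its mirror partner in the table.
    """
    theta = table["orientation_deg"].to_numpy(dtype=float)
    uniq = np.unique(np.round(theta, 6))
    for o in uniq:
        mirror = (180.0 - o) % 180.0
        if not np.isclose(o, mirror) and not np.any(np.isclose(uniq, mirror)):
            raise AggregationError(
                f"orientation {o} deg has no mirror partner {mirror} deg"
            )

    canon, sign = canonical_orientation(theta)
    work = pd.DataFrame(
        {
            "orientation_deg": np.round(canon, 6),
            "aspect_ratio": table["aspect_ratio"].to_numpy(dtype=float),
            "_member": np.round(theta, 6),
            "_signed": sign * table["bias_deg"].to_numpy(dtype=float),
        }
    )
    members = (
        work.groupby(["orientation_deg", "aspect_ratio", "_member"])["_signed"]
        .agg(_mean=_circ_mean, _var=_circ_var, _count="count")
        .reset_index()
    )
    out = (
        members.groupby(["orientation_deg", "aspect_ratio"])
        .apply(_pooled, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out.sort_values(["orientation_deg", "aspect_ratio"]).reset_index(drop=True)


def aggregate_conditions(table: pd.DataFrame) -> pd.DataFrame:
    """Per raw (orientation, aspect ratio) condition means and variances.

    No mirror pairing; circular (period-180) moments, variances floored at
    :data:`VARIANCE_FLOOR`.
    """
    out = (
        table.groupby(["orientation_deg", "aspect_ratio"])["bias_deg"]
        .agg(mean_bias=_circ_mean, variance=_circ_var, n="count")
        .reset_index()
    )
    out["within_ss"] = (out["n"] - 1) * out["variance"]
    out["variance"] = out["variance"].clip(lower=VARIANCE_FLOOR)
    return out.sort_values(["orientation_deg", "aspect_ratio"]).reset_index(drop=True)


#: alias documenting the aggregated-condition table contract
AggregatedConditions = pd.DataFrame


def _feasibility_violation(model: ModelSpec, params: np.ndarray) -> float:
    """0 for feasible kernel parameters, else the magnitude of the violation."""
    ppg = model.params_per_group
    if ppg == 0:
        return 0.0
    violation = 0.0
    for g in range(len(model.group_labels)):
        block = params[g * ppg : (g + 1) * ppg]
        a_h, a_v = block[0], block[1]
        violation += max(0.0, -a_h) + max(0.0, -a_v)
        if a_h <= 0 or a_v <= 0:
            continue
        if ppg == 3:
            violation += max(0.0, abs(block[2]) - 0.99 * a_h * a_v)
    return violation


def wls_objective(
    model: ModelSpec, params: np.ndarray, conditions: pd.DataFrame
) -> float:
    """Weighted residual sum of squares of ``model`` at ``params``.

    ``sum((mean_bias - predicted)**2 / variance)`` over condition cells.
    Parameter vectors violating positivity or kernel positive-definiteness
    return a large finite penalty that exceeds every feasible value.
    """
    params = np.asarray(params, dtype=float)
    violation = _feasibility_violation(model, params)
    if violation > 0.0:
        return _PENALTY * (1.0 + violation)
    fitted = ModelSpec(
        kind=model.kind,
        group_labels=model.group_labels,
        major_radius=model.major_radius,
        canonical=model.canonical,
        params=params if model.params_per_group else None,
    )
    pred = predict_for_conditions(
        fitted,
        conditions["orientation_deg"].to_numpy(),
        conditions["aspect_ratio"].to_numpy(),
    )
    resid = wrap_bias(conditions["mean_bias"].to_numpy() - pred)
    return float(np.sum(resid**2 / conditions["variance"].to_numpy()))


def trial_wrss(model: ModelSpec, params: np.ndarray, conditions: pd.DataFrame) -> float:
    """Trial-level weighted residual sum of squares.

    Decomposes over condition cells as

        sum_j [ n_j * (mean_j - pred_j)**2 + within_ss_j ] / var_j,

    where ``within_ss_j`` is the within-cell sum of squared deviations.
    The within term is constant in the parameters, so minimizing the
    cell-level objective :func:`wls_objective` minimizes this too (for
    balanced cell counts); but the F test's degrees of freedom count
    trials, so the F denominator needs the trial-level quantity.
    """
    params = np.asarray(params, dtype=float)
    if _feasibility_violation(model, params) > 0.0:
        return _PENALTY
    fitted = ModelSpec(
        kind=model.kind,
        group_labels=model.group_labels,
        major_radius=model.major_radius,
        canonical=model.canonical,
        params=params if model.params_per_group else None,
    )
    pred = predict_for_conditions(
        fitted,
        conditions["orientation_deg"].to_numpy(),
        conditions["aspect_ratio"].to_numpy(),
    )
    resid = wrap_bias(conditions["mean_bias"].to_numpy() - pred)
    n = conditions["n"].to_numpy(dtype=float)
    var = conditions["variance"].to_numpy(dtype=float)
    if "within_ss" in conditions:
        within = conditions["within_ss"].to_numpy(dtype=float)
    else:
        within = (n - 1.0) * var
    return float(np.sum((n * resid**2 + within) / var))


@dataclass
class FitResult:
    """Outcome of one weighted least-squares model fit.

    ``wrss`` is the trial-level weighted residual sum of squares (see
    :func:`trial_wrss`); ``cell_wrss`` is the aggregated-cell objective
    that was minimized (:func:`wls_objective`)."""

    model: ModelSpec
    params: np.ndarray
    wrss: float
    n_free: int
    n_obs: int
    converged: bool
    n_starts: int
    cell_wrss: float = 0.0
    identifiable: bool = True
    explained_variance: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.model.kind,
                "group_labels": list(self.model.group_labels),
                "canonical": self.model.canonical,
                "major_radius": self.model.major_radius,
                "params": np.asarray(self.params).tolist(),
                "wrss": self.wrss,
                "cell_wrss": self.cell_wrss,
                "n_free": self.n_free,
                "n_obs": self.n_obs,
                "converged": self.converged,
                "n_starts": self.n_starts,
                "identifiable": self.identifiable,
                "explained_variance": self.explained_variance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        data = json.loads(text)
        labels = tuple(
            lab if isinstance(lab, str) else float(lab)
            for lab in data["group_labels"]
        )
        model = ModelSpec(
            kind=data["kind"],
            group_labels=labels,
            major_radius=data["major_radius"],
            canonical=data["canonical"],
            params=np.asarray(data["params"]) if data["params"] else None,
        )
        return cls(
            model=model,
            params=np.asarray(data["params"]),
            wrss=data["wrss"],
            n_free=data["n_free"],
            n_obs=data["n_obs"],
            converged=data["converged"],
            n_starts=data["n_starts"],
            cell_wrss=data.get("cell_wrss", 0.0),
            identifiable=data["identifiable"],
            explained_variance=data["explained_variance"],
        )


@dataclass
class FTestResult:
    """Nested-model F test."""

    F: float
    df1: int
    df2: int
    p_value: float


def _grid_from_conditions(conditions: pd.DataFrame) -> ConditionGrid:
    cells = tuple(
        (float(o), float(a))
        for o, a in zip(conditions["orientation_deg"], conditions["aspect_ratio"])
    )
    aggregated = bool(np.all(conditions["orientation_deg"].to_numpy() <= 90.0))
    return ConditionGrid(cells=cells, aggregated=aggregated)


def _group_starts(
    ppg: int, n_starts: int, rng: np.random.Generator
) -> list[np.ndarray]:
    lo, hi = _START_RANGE
    hs = np.geomspace(lo, hi, n_starts)
    vs = rng.permutation(np.geomspace(lo, hi, n_starts))
    if ppg == 2:
        return [np.array([h, v]) for h, v in zip(hs, vs)]
    return [np.array([h, v, 0.0]) for h, v in zip(hs, vs)]


def _internal_to_kernel(x: np.ndarray, ppg: int) -> np.ndarray:
    """(a_h, a_v[, rho]) optimizer coordinates -> (a_h, a_v[, r])."""
    if ppg == 2:
        return x.copy()
    return np.array([x[0], x[1], x[2] * x[0] * x[1]])


def _kernel_to_internal(p: np.ndarray, ppg: int) -> np.ndarray:
    if ppg == 2:
        return p.copy()
    rho = p[2] / (p[0] * p[1])
    return np.array([p[0], p[1], np.clip(rho, *_BOUNDS_RHO)])


def _fit_group(
    model: ModelSpec,
    subconditions: pd.DataFrame,
    starts: list[np.ndarray],
) -> tuple[np.ndarray, float, bool, list]:
    """Minimize the WRSS of a single kernel group over its conditions."""
    ppg = model.params_per_group
    sub_model = ModelSpec(
        kind="homogeneous" if ppg == 2 else "homogeneous_oriented",
        group_labels=("all",),
        major_radius=model.major_radius,
        canonical=model.canonical,
    )
    bounds = [_BOUNDS_A, _BOUNDS_A] + ([_BOUNDS_RHO] if ppg == 3 else [])

    def objective(x: np.ndarray) -> float:
        return wls_objective(sub_model, _internal_to_kernel(x, ppg), subconditions)

    results = []
    for x0 in starts:
        res = optimize.minimize(
            objective,
            _kernel_to_internal(np.asarray(x0, dtype=float), ppg),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        results.append(res)
    ok = [r for r in results if np.isfinite(r.fun)]
    if not ok:
        raise NonConvergenceError(
            f"all {len(starts)} starts failed: "
            + "; ".join(str(r.message) for r in results)
        )
    fmin = min(r.fun for r in ok)
    # starts tied at the minimum (the objective has an exactly flat ridge,
    # so many starts coincide); prefer a cleanly terminated one
    tied = [r for r in ok if r.fun <= fmin + 1e-9 + 1e-8 * abs(fmin)]
    best = next((r for r in tied if r.success), tied[0])
    success = any(r.success for r in tied) or len(tied) >= 2
    return (
        _internal_to_kernel(best.x, ppg),
        float(best.fun),
        success,
        results,
    )


def _glp_second_moments(
    theta_deg: np.ndarray, ratio: np.ndarray, major: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(cxx, cyy, cxy) of the stimulus covariance per condition."""
    th = np.radians(theta_deg)
    major2 = major**2
    minor2 = (ratio * major) ** 2
    c, s = np.cos(th), np.sin(th)
    cxx = major2 * c**2 + minor2 * s**2
    cyy = major2 * s**2 + minor2 * c**2
    cxy = (major2 - minor2) * c * s
    return cxx, cyy, cxy


def _roundness(cxx, cyy, cxy, a_h: float, delta: float, r: float) -> np.ndarray:
    """Eigenvalue ratio lambda_min/lambda_max of the smoothed covariance."""
    sxx = cxx + a_h**2
    syy = cyy + a_h**2 + delta
    sxy = cxy + r
    half_tr = 0.5 * (sxx + syy)
    root = np.sqrt(0.25 * (sxx - syy) ** 2 + sxy**2)
    return np.clip((half_tr - root) / (half_tr + root), 1e-12, 1.0 - 1e-6)


def _dispersion_sse(
    a_h: float, cxx, cyy, cxy, delta: float, r: float, log_sd, kappa: float
) -> float:
    """Misfit of the two-factor dispersion law at kernel scale ``a_h``.

    Under the observer model ``sd = sigma_base * q**kappa * (1 - q)**(-1/2)``
    with the roundness profile q of the smoothed covariance; ``kappa`` is a
    structural constant of the dispersion law while the per-participant
    noise scale ``sigma_base`` is profiled out (it only shifts log SDs).
    """
    q = _roundness(cxx, cyy, cxy, a_h, delta, r)
    y = log_sd + 0.5 * np.log1p(-q) - kappa * np.log(q)
    return float(np.sum((y - y.mean()) ** 2))


def _select_scale(
    params: np.ndarray, subconditions: pd.DataFrame, major: float, kappa: float
) -> np.ndarray:
    """Pick the kernel on the flat bias ridge that best explains dispersion.

    The bias objective fixes ``delta = a_v**2 - a_h**2`` and ``r`` but not
    the absolute scale; the observed per-condition response SDs do.  A 1-D
    bounded search over ``a_h`` (with ``a_v = sqrt(a_h**2 + delta)``)
    minimizes the profiled log-SD misfit.  Groups with fewer than three
    cells keep the stage-1 point.
    """
    if len(subconditions) < 3:
        return params
    a_h0, a_v0 = params[0], params[1]
    r = params[2] if params.size == 3 else 0.0
    delta = a_v0**2 - a_h0**2
    if delta < 0:  # horizontally elongated kernel: search over a_v instead
        return params
    cxx, cyy, cxy = _glp_second_moments(
        subconditions["orientation_deg"].to_numpy(dtype=float),
        subconditions["aspect_ratio"].to_numpy(dtype=float),
        major,
    )
    # remove the 1-degree probe lattice's quantization variance (1/12 deg^2),
    # which otherwise inflates the flattest (small-SD) cells the most
    var = subconditions["variance"].to_numpy(dtype=float) - 1.0 / 12.0
    log_sd = 0.5 * np.log(np.clip(var, 1e-4, None))
    # keep |r| <= 0.98 * a_h * a_v, inside the 0.99 feasibility margin
    r_eff = abs(r) / 0.98
    lo2 = 0.5 * (-delta + np.sqrt(delta**2 + 4.0 * r_eff**2))
    lo = min(max(_BOUNDS_A[0], np.sqrt(lo2) if lo2 > 0 else 0.0), _BOUNDS_A[1] - 0.1)
    res = optimize.minimize_scalar(
        _dispersion_sse,
        bounds=(lo, _BOUNDS_A[1]),
        args=(cxx, cyy, cxy, delta, r, log_sd, kappa),
        method="bounded",
        options={"xatol": 1e-6},
    )
    a_h = float(res.x)
    out = params.copy()
    out[0] = a_h
    out[1] = np.sqrt(a_h**2 + delta)
    return out


def fit_model(
    kind: str,
    conditions: pd.DataFrame,
    n_starts: int = 8,
    seed: int = 0,
    select_scale: bool = True,
    dispersion_kappa: float = 0.5,
) -> FitResult:
    """Fit one smoothing model to aggregated conditions by bounded WLS.

    Multi-start bounded minimization per kernel group (the objective is
    separable across groups): ``n_starts`` starts on a log-spaced
    (a_h, a_v) grid over [0.1, 6] degrees with r started at 0, plus — for
    the heterogeneous models — the best-fit kernel of the nested
    homogeneous model as an extra start, which guarantees
    ``wrss(heterogeneous) <= wrss(homogeneous)`` numerically.

    With ``select_scale=True`` (default) the absolute kernel scale of each
    group — which the bias objective leaves free along an exactly flat
    ridge — is then chosen from the per-condition response dispersion (see
    module docstring); this changes the reported radii but not the WRSS.
    """
    grid = _grid_from_conditions(conditions)
    model = ModelSpec.for_grid(kind, grid)
    n_obs = int(conditions["n"].sum())
    if n_obs <= model.n_free:
        raise ValueError(
            f"{n_obs} observations cannot identify {model.n_free} parameters"
        )

    if kind == "isotropic":
        cell_wrss = float(
            np.sum(
                conditions["mean_bias"].to_numpy() ** 2
                / conditions["variance"].to_numpy()
            )
        )
        model.params = None
        return FitResult(
            model=model,
            params=np.empty(0),
            wrss=trial_wrss(model, np.empty(0), conditions),
            n_free=0,
            n_obs=n_obs,
            converged=True,
            n_starts=0,
            cell_wrss=cell_wrss,
        )

    ppg = model.params_per_group
    rng = np.random.default_rng(seed)

    extra_starts: list[np.ndarray] = []
    if kind in ("radial_heterogeneous", "angular_heterogeneous"):
        restricted_kind = "homogeneous" if ppg == 2 else "homogeneous_oriented"
        restricted = fit_model(restricted_kind, conditions, n_starts=n_starts, seed=seed)
        extra_starts = [np.asarray(restricted.params)]

    params = np.empty(model.n_free)
    converged = True
    for g, label in enumerate(model.group_labels):
        if kind == "radial_heterogeneous":
            mask = np.isclose(conditions["aspect_ratio"], label)
        elif kind == "angular_heterogeneous":
            mask = np.isclose(conditions["orientation_deg"], label)
        else:
            mask = np.ones(len(conditions), dtype=bool)
        sub = conditions[mask].reset_index(drop=True)
        starts = _group_starts(ppg, n_starts, rng) + extra_starts
        best_params, _, success, _ = _fit_group(model, sub, starts)
        if select_scale:
            best_params = _select_scale(
                best_params, sub, model.major_radius, dispersion_kappa
            )
        params[g * ppg : (g + 1) * ppg] = best_params
        converged = converged and success

    model.params = params
    cell_wrss = wls_objective(model, params, conditions)
    pred = predict_for_conditions(
        model,
        conditions["orientation_deg"].to_numpy(),
        conditions["aspect_ratio"].to_numpy(),
    )
    # a fit whose best predictions are all ~0 is isotropic-degenerate:
    # any a_h = a_v kernel does equally well
    identifiable = bool(np.max(np.abs(pred)) > 1e-6)
    return FitResult(
        model=model,
        params=params,
        wrss=trial_wrss(model, params, conditions),
        n_free=model.n_free,
        n_obs=n_obs,
        converged=converged,
        n_starts=n_starts,
        cell_wrss=cell_wrss,
        identifiable=identifiable,
    )


def nested_f_test(
    restricted: FitResult, full: FitResult, n: int | None = None
) -> FTestResult:
    """F test of a restricted model against a full model nesting it.

    ``n`` defaults to the trial-level observation count carried by the
    fits (the sum of per-condition trial counts), which reproduces the
    conventional degrees of freedom of the design even though the WRSS is
    evaluated on aggregated cells.  The statistic is invariant under a
    uniform rescaling of the weights.
    """
    if full.model.kind not in _NESTED_IN.get(restricted.model.kind, set()):
        raise ValueError(
            f"{restricted.model.kind!r} is not nested in {full.model.kind!r}"
        )
    if restricted.n_obs != full.n_obs:
        raise ValueError("fits were computed on different observation counts")
    p1, p2 = restricted.n_free, full.n_free
    if p2 <= p1:
        raise ValueError("full model must have more free parameters")
    n = restricted.n_obs if n is None else int(n)
    df1, df2 = p2 - p1, n - p2
    if df2 <= 0:
        raise ValueError("non-positive denominator degrees of freedom")
    wrss1, wrss2 = restricted.wrss, full.wrss
    if wrss2 > wrss1:
        warnings.warn(
            f"full-model WRSS {wrss2:.6g} exceeds restricted WRSS {wrss1:.6g}; "
            "optimizer failure suspected, F clipped at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return FTestResult(F=0.0, df1=df1, df2=df2, p_value=1.0)
    f_stat = ((wrss1 - wrss2) / df1) / (wrss2 / df2) if wrss2 > 0 else np.inf
    p = float(stats.f.sf(f_stat, df1, df2))
    return FTestResult(F=float(f_stat), df1=df1, df2=df2, p_value=p)


def _trial_predictions(fit: FitResult, table: pd.DataFrame) -> np.ndarray:
    return predict_for_conditions(
        fit.model,
        table["orientation_deg"].to_numpy(dtype=float),
        table["aspect_ratio"].to_numpy(dtype=float),
    )


def explained_variance(
    fit: FitResult, table: pd.DataFrame, weighted: bool = False
) -> float:
    """Fraction of trial-level bias variance explained by the model.

    Plain (unweighted) R-squared of the trial biases against the model's
    per-condition predictions, comparable with :func:`systematic_ceiling`.
    ``weighted=True`` uses inverse per-condition-variance weights instead
    (a diagnostic matching the fitting objective's weighting).
    """
    bias = table["bias_deg"].to_numpy(dtype=float)
    pred = _trial_predictions(fit, table)
    return _r_squared(table, bias, pred, weighted)


def systematic_ceiling(table: pd.DataFrame, weighted: bool = False) -> float:
    """Maximal explainable variance given within-condition noise.

    R-squared obtained when each condition's own mean response bias is used
    as its prediction — the saturated-mean model, eliminating all variance
    within conditions.  Any smoothing model's explained variance is bounded
    above by this ceiling.
    """
    bias = table["bias_deg"].to_numpy(dtype=float)
    means = table.groupby(["orientation_deg", "aspect_ratio"])["bias_deg"].transform(
        _circ_mean
    )
    return _r_squared(table, bias, means.to_numpy(), weighted)


def _r_squared(
    table: pd.DataFrame, bias: np.ndarray, pred: np.ndarray, weighted: bool
) -> float:
    """R-squared with period-180 wrapped residuals."""
    if weighted:
        var = (
            table.groupby(["orientation_deg", "aspect_ratio"])["bias_deg"]
            .transform(_circ_var)
            .to_numpy()
        )
        w = 1.0 / np.clip(var, VARIANCE_FLOOR, None)
    else:
        w = np.ones_like(bias)
    center = _circ_wmean(bias, w)
    tss = float(np.sum(w * wrap_bias(bias - center) ** 2))
    if tss == 0.0:
        raise ValueError("total variance of biases is zero")
    rss = float(np.sum(w * wrap_bias(bias - pred) ** 2))
    return 1.0 - rss / tss
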