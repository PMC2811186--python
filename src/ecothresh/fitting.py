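"""Least-squares fitting, AICc model competition and bootstrap uncertainty.

Each candidate form is fitted to a ``(pressure, value)`` response curve by
least squares.  Forms that are linear in their coefficients conditional on
one nonlinear parameter (the broken-stick breakpoint ``Pt``, the negative
exponential rate ``a2``) are fitted by a deterministic profile: conditional
linear least squares on a fixed grid of the nonlinear parameter followed by
bounded scalar refinement around the best grid cell.  The sigmoid is fitted
by bounded trust-region least squares from a fixed multi-start grid.  All
fits are deterministic given the data and options.

Candidates are compared with the small-sample-corrected Akaike information
criterion (AICc), counting the error variance as a parameter.  Across an
ensemble of Monte Carlo datasets the winning form is chosen by majority
vote of per-dataset AICc winners.  Parameter and threshold uncertainty come
from a nonparametric bootstrap (case resampling of pressure-value pairs by
default; residual resampling behind a flag).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .forms import (
    FORM_ORDER,
    PARAM_COUNT,
    LinearParams,
    NegExpParams,
    ParabolicParams,
    PiecewiseParams,
    ResponseModel,
    SigmoidParams,
)

__all__ = [
    "ResponseCurve",
    "FitOptions",
    "ModelFit",
    "BootstrapResult",
    "ModelSelection",
    "aicc",
    "fit_model",
    "select_model",
    "bootstrap_fit",
    "threshold_is_significant",
]

_PERFECT_RSS = 1e-24  # below this a fit is treated as numerically exact


@dataclass(frozen=True)
class ResponseCurve:
    """A (pressure, value) series for one attribute or indicator."""

    pressure: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pressure", np.asarray(self.pressure, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.pressure.shape != self.values.shape or self.pressure.ndim != 1:
            raise ValueError("pressure and values must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.pressure)) and np.all(np.isfinite(self.values))):
            raise ValueError("pressure and values must be finite")

    @property
    def n(self) -> int:
        return self.pressure.size


@dataclass(frozen=True)
class FitOptions:
    """Numerical settings for the deterministic fitters.

    ``grid_size`` controls the breakpoint / rate profile resolution;
    ``refine`` turns on bounded scalar refinement of the profiled parameter
    around the winning grid cell; ``boot_grid_size`` is the (coarser)
    profile used inside bootstrap refits, where grid resolution is far
    below the sampling noise in the draws.
    """

    grid_size: int = 201
    refine: bool = True
    boot_grid_size: int = 201
    negexp_rate_limit: float = 25.0
    sigmoid_multistart: int = 24


DEFAULT_OPTIONS = FitOptions()


@dataclass
class ModelFit:
    """One candidate model fitted to one response curve."""

    model: Optional[ResponseModel]
    rss: float
    n: int
    k: int
    aicc: float
    converged: bool
    diagnostics: Dict[str, object] = field(default_factory=dict)

    @property
    def form(self) -> Optional[str]:
        return self.model.form if self.model is not None else None


@dataclass
class BootstrapResult:
    """Percentile bootstrap distribution of one model's parameters.

    ``significant[p]`` is True iff the 95% interval of parameter ``p``
    excludes zero.  ``threshold_draws`` holds the per-replicate utility
    threshold for forms that define one (breakpoint / inflection).
    """

    reps: int
    param_draws: Dict[str, np.ndarray]
    ci95: Dict[str, Tuple[float, float]]
    significant: Dict[str, bool]
    threshold_draws: Optional[np.ndarray] = None
    n_redraws: int = 0
    n_failed: int = 0


@dataclass
class ModelSelection:
    """Outcome of the per-dataset AICc vote."""

    winner: str
    tally: Dict[str, int]
    n_datasets: int
    per_dataset_winner: List[Optional[str]]
    excluded: List[int] = field(default_factory=list)
    tie_breaks: int = 0

    def tally_string(self) -> str:
        return f"{self.winner.capitalize()} ({self.tally.get(self.winner, 0)}/{self.n_datasets})"


# ----------------------------------------------------------------------
def aicc(rss: float, n: int, k: int) -> float:
    """AICc = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1), with ``k`` counting the
    error variance.  Undefined for n <= k+1 (the correction blows up)."""
    if rss <= 0:
        raise ValueError("rss must be positive (a perfect fit has no finite AICc)")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _aicc_or_neg_inf(rss: float, n: int, k: int) -> float:
    """AICc with numerically perfect fits mapped to -inf (they win)."""
    if rss <= _PERFECT_RSS:
        return -math.inf
    return aicc(rss, n, k)


# ----------------------------------------------------------------------
# conditional linear least squares helpers
def _lstsq(F: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(F, y, rcond=None)
    resid = y - F @ beta
    return beta, float(resid @ resid)


def _piecewise_design(P: np.ndarray, Pt: float) -> np.ndarray:
    return np.column_stack([np.ones_like(P), np.minimum(P, Pt), np.clip(P - Pt, 0.0, None)])


def _piecewise_profile_rss(P: np.ndarray, y: np.ndarray, Pt: float) -> float:
    _, rss = _lstsq(_piecewise_design(P, Pt), y)
    return rss


def _breakpoint_bounds(P: np.ndarray) -> Tuple[float, float]:
    """Breakpoint search range: [second-smallest, second-largest] distinct
    pressure, so both segments always contain data."""
    u = np.unique(P)
    if u.size < 4:
        raise ValueError("breakpoint fit needs at least 4 distinct pressure levels")
    return float(u[1]), float(u[-2])


def _fit_piecewise(P, y, options: FitOptions) -> Tuple[ResponseModel, float, dict]:
    lo, hi = _breakpoint_bounds(P)
    grid = np.linspace(lo, hi, options.grid_size)
    best_rss, best_Pt = math.inf, grid[0]
    for Pt in grid:
        rss = _piecewise_profile_rss(P, y, Pt)
        if rss < best_rss:  # strict: ties keep the smaller breakpoint
            best_rss, best_Pt = rss, Pt
    if options.refine:
        i = int(np.argmin(np.abs(grid - best_Pt)))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid.size - 1)]
        if b > a:
            res = minimize_scalar(
                lambda t: _piecewise_profile_rss(P, y, t),
                bounds=(a, b),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun < best_rss:
                best_rss, best_Pt = float(res.fun), float(res.x)
    beta, rss = _lstsq(_piecewise_design(P, best_Pt), y)
    model = ResponseModel(
        "piecewise", PiecewiseParams(Pt=float(best_Pt), b1=beta[0], m1=beta[1], m2=beta[2])
    )
    scale = max(abs(beta[1]), abs(beta[2]), 1e-12)
    diag = {"degenerate_breakpoint": bool(abs(beta[1] - beta[2]) < 1e-6 * scale)}
    return model, rss, diag


def _negexp_design(P: np.ndarray, a2: float) -> np.ndarray:
    return np.column_stack([np.ones_like(P), np.exp(np.clip(a2 * P, -700.0, 700.0))])


def _fit_negexp(P, y, options: FitOptions) -> Tuple[ResponseModel, float, dict]:
    scale = max(float(np.max(np.abs(P))), 1e-12)
    lim = options.negexp_rate_limit / scale
    grid = np.linspace(-lim, lim, options.grid_size)

    def profile(a2):
        _, rss = _lstsq(_negexp_design(P, a2), y)
        return rss

    rss_grid = np.array([profile(a2) for a2 in grid])
    i = int(np.argmin(rss_grid))
    best_a2, best_rss = float(grid[i]), float(rss_grid[i])
    if options.refine:
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        if b > a:
            res = minimize_scalar(profile, bounds=(a, b), method="bounded", options={"xatol": 1e-12})
            if res.fun < best_rss:
                best_rss, best_a2 = float(res.fun), float(res.x)
    beta, rss = _lstsq(_negexp_design(P, best_a2), y)
    model = ResponseModel("negexp", NegExpParams(a0=beta[0], a1=beta[1], a2=best_a2))
    return model, rss, {}


def _sigmoid_residuals(theta, P, y):
    c0, c1, lc2, lc3 = theta
    e = np.exp(np.clip(lc2 + np.exp(lc3) * P, -700.0, 700.0))
    return c1 + (c0 - c1) / (1.0 + e) - y


def _sigmoid_jac(theta, P, y):
    c0, c1, lc2, lc3 = theta
    e = np.exp(np.clip(lc2 + np.exp(lc3) * P, -700.0, 700.0))
    inv = 1.0 / (1.0 + e)
    core = -(c0 - c1) * e * inv * inv
    return np.column_stack([inv, 1.0 - inv, core, core * P * np.exp(lc3)])


def _fit_sigmoid(
    P, y, options: FitOptions, starts: Optional[Sequence[np.ndarray]] = None
) -> Tuple[Optional[ResponseModel], float, dict]:
    span = float(np.max(P) - np.min(P)) or 1.0
    if starts is None:
        y_lo = float(np.mean(y[P <= np.quantile(P, 0.25)]))
        y_hi = float(np.mean(y[P >= np.quantile(P, 0.75)]))
        fracs = (0.2, 0.4, 0.6, 0.8)
        rates = (4.0, 10.0, 20.0)
        starts = []
        for frac in fracs:
            x0 = float(np.min(P)) + frac * span
            for c3 in rates:
                c3s = c3 / span
                starts.append(np.array([y_lo, y_hi, -c3s * x0, math.log(c3s)]))
        starts = starts[: options.sigmoid_multistart]
    lb = np.array([-np.inf, -np.inf, -60.0, math.log(1e-2 / span)])
    ub = np.array([np.inf, np.inf, 60.0, math.log(1e3 / span)])
    best = None
    for th0 in starts:
        th0 = np.clip(th0, lb + 1e-9, ub - 1e-9)
        try:
            res = least_squares(
                _sigmoid_residuals,
                th0,
                jac=_sigmoid_jac,
                args=(P, y),
                bounds=(lb, ub),
                method="trf",
                xtol=1e-12,
                max_nfev=200,
            )
        except Exception:
            continue
        rss = float(res.fun @ res.fun)
        if best is None or rss < best[0] * (1.0 - 1e-12):
            best = (rss, res.x)
    if best is None:
        return None, math.inf, {"message": "all sigmoid starts failed"}
    rss, th = best
    c0, c1, lc2, lc3 = th
    model = ResponseModel("sigmoidal", SigmoidParams(c0=c0, c1=c1, c2=math.exp(lc2), c3=math.exp(lc3)))
    return model, rss, {}


def _fit_polynomial(P, y, form: str) -> Tuple[ResponseModel, float, dict]:
    if form == "linear":
        F = np.column_stack([np.ones_like(P), P])
        beta, rss = _lstsq(F, y)
        model = ResponseModel("linear", LinearParams(b0=beta[0], m0=beta[1]))
    else:
        F = np.column_stack([np.ones_like(P), P, P * P])
        beta, rss = _lstsq(F, y)
        model = ResponseModel("parabolic", ParabolicParams(d0=beta[0], d1=beta[1], d2=beta[2]))
    return model, rss, {}


# ----------------------------------------------------------------------
def fit_model(
    curve: ResponseCurve, form: str, options: FitOptions = DEFAULT_OPTIONS
) -> ModelFit:
    """Least-squares fit of one candidate ``form`` to ``curve``.

    Deterministic given the curve and options.  Non-convergence (possible
    only for the sigmoid) is reported via ``converged=False`` rather than
    raised, so a model competition can proceed with the survivors.
    """
    if form not in FORM_ORDER:
        raise ValueError(f"unknown form {form!r}")
    k = PARAM_COUNT[form]
    n = curve.n
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} observations to fit {form!r}, got {n}")
    P, y = curve.pressure, curve.values
    try:
        if form in ("linear", "parabolic"):
            model, rss, diag = _fit_polynomial(P, y, form)
        elif form == "piecewise":
            model, rss, diag = _fit_piecewise(P, y, options)
        elif form == "negexp":
            model, rss, diag = _fit_negexp(P, y, options)
        else:
            model, rss, diag = _fit_sigmoid(P, y, options)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        return ModelFit(None, math.inf, n, k, math.inf, False, {"message": str(exc)})
    if model is None:
        return ModelFit(None, math.inf, n, k, math.inf, False, diag)
    return ModelFit(model, rss, n, k, _aicc_or_neg_inf(rss, n, k), True, diag)


def fit_all(
    curve: ResponseCurve,
    forms: Sequence[str] = FORM_ORDER,
    options: FitOptions = DEFAULT_OPTIONS,
) -> Dict[str, ModelFit]:
    """Fit every candidate in ``forms`` to ``curve``."""
    return {form: fit_model(curve, form, options) for form in forms}


# ----------------------------------------------------------------------
def _winner_key(form: str, fit: ModelFit):
    # lowest AICc; ties broken by fewest parameters, then fixed form order
    return (fit.aicc, fit.k, FORM_ORDER.index(form))


def select_model(fits_by_dataset: Sequence[Mapping[str, ModelFit]]) -> ModelSelection:
    """Majority vote over per-dataset AICc winners.

    Per dataset the winner is the converged candidate with the lowest AICc
    (ties: fewest parameters, then fixed form order).  Datasets on which no
    candidate converged are excluded and recorded.  The overall winner is
    the modal per-dataset winner, with the same deterministic tie-break.
    """
    tally: Counter = Counter()
    per_dataset: List[Optional[str]] = []
    excluded: List[int] = []
    tie_breaks = 0
    for i, fits in enumerate(fits_by_dataset):
        ok = {f: m for f, m in fits.items() if m.converged}
        if not ok:
            excluded.append(i)
            per_dataset.append(None)
            continue
        ranked = sorted(ok.items(), key=lambda kv: _winner_key(*kv))
        if len(ranked) > 1 and ranked[0][1].aicc == ranked[1][1].aicc:
            tie_breaks += 1
        winner = ranked[0][0]
        tally[winner] += 1
        per_dataset.append(winner)
    if not tally:
        raise ValueError("every dataset was excluded: no converged fits")
    best = sorted(
        tally.items(), key=lambda kv: (-kv[1], PARAM_COUNT[kv[0]], FORM_ORDER.index(kv[0]))
    )[0][0]
    return ModelSelection(
        winner=best,
        tally=dict(tally),
        n_datasets=len(fits_by_dataset) - len(excluded),
        per_dataset_winner=per_dataset,
        excluded=excluded,
        tie_breaks=tie_breaks,
    )


# ----------------------------------------------------------------------
# bootstrap
def _batched_lls(F: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Batched linear least squares via ridge-stabilized normal equations.

    F: (..., n, p), Y: (..., n).  The tiny ridge (1e-10 relative) guards
    against singular resample designs; its effect on RSS is far below
    bootstrap sampling noise.
    """
    A = np.einsum("...ni,...nj->...ij", F, F)
    c = np.einsum("...ni,...n->...i", F, Y)
    p = A.shape[-1]
    tr = np.einsum("...ii->...", A) / p
    A = A + (1e-10 * (tr[..., None, None] + 1.0)) * np.eye(p)
    beta = np.linalg.solve(A, c[..., None])[..., 0]
    resid = Y - np.einsum("...ni,...i->...n", F, beta)
    rss = np.einsum("...n,...n->...", resid, resid)
    return beta, rss


def _row_second_extremes(P: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-row second-smallest and second-largest *distinct* values."""
    S = np.sort(P, axis=1)
    gt_min = S > S[:, [0]]
    lo = S[np.arange(S.shape[0]), np.argmax(gt_min, axis=1)]
    R = S[:, ::-1]
    lt_max = R < R[:, [0]]
    hi = R[np.arange(R.shape[0]), np.argmax(lt_max, axis=1)]
    return lo, hi


def _resample_indices(
    rng: np.random.Generator, P: np.ndarray, reps: int, min_distinct: int
) -> Tuple[np.ndarray, int]:
    """Case-resampling index matrix, redrawing replicates whose pressure
    set is too degenerate to fit (< min_distinct distinct levels)."""
    n = P.size
    idx = rng.integers(0, n, size=(reps, n))
    redraws = 0
    for _ in range(100):
        distinct = np.array([np.unique(P[row]).size for row in idx])
        bad = distinct < min_distinct
        nbad = int(bad.sum())
        if nbad == 0:
            break
        redraws += nbad
        idx[bad] = rng.integers(0, n, size=(nbad, n))
    return idx, redraws


def _piecewise_boot(P_b, Y_b, grid_size: int):
    G = grid_size
    lo, hi = _row_second_extremes(P_b)
    glo, ghi = float(lo.min()), float(hi.max())
    grid = np.linspace(glo, ghi, G)
    F1 = np.minimum(P_b[:, None, :], grid[None, :, None])
    F2 = np.clip(P_b[:, None, :] - grid[None, :, None], 0.0, None)
    ones = np.ones_like(F1)
    F = np.stack([ones, F1, F2], axis=-1)  # (B, G, n, 3)
    beta, rss = _batched_lls(F, Y_b[:, None, :])
    valid = (grid[None, :] >= lo[:, None]) & (grid[None, :] <= hi[:, None])
    rss_masked = np.where(valid, rss, np.inf)
    none_valid = ~np.isfinite(rss_masked).any(axis=1)
    rss_masked[none_valid] = rss[none_valid]
    best = np.argmin(rss_masked, axis=1)
    rows = np.arange(P_b.shape[0])
    b = beta[rows, best]
    return {
        "Pt": grid[best],
        "b1": b[:, 0],
        "m1": b[:, 1],
        "m2": b[:, 2],
    }, grid[best]


def _negexp_boot(P_b, Y_b, grid_size: int, rate_limit: float):
    scale = max(float(np.max(np.abs(P_b))), 1e-12)
    grid = np.linspace(-rate_limit / scale, rate_limit / scale, grid_size)
    E = np.exp(np.clip(grid[None, :, None] * P_b[:, None, :], -700.0, 700.0))
    F = np.stack([np.ones_like(E), E], axis=-1)
    beta, rss = _batched_lls(F, Y_b[:, None, :])
    best = np.argmin(rss, axis=1)
    rows = np.arange(P_b.shape[0])
    b = beta[rows, best]
    return {"a0": b[:, 0], "a1": b[:, 1], "a2": grid[best]}, None


def _polynomial_boot(P_b, Y_b, form: str):
    ones = np.ones_like(P_b)
    if form == "linear":
        F = np.stack([ones, P_b], axis=-1)
        names = ("b0", "m0")
    else:
        F = np.stack([ones, P_b, P_b * P_b], axis=-1)
        names = ("d0", "d1", "d2")
    beta, _ = _batched_lls(F, Y_b)
    return {nm: beta[:, j] for j, nm in enumerate(names)}, None


def bootstrap_fit(
    curve: ResponseCurve,
    form: str,
    reps: int,
    seed: int = 0,
    options: FitOptions = DEFAULT_OPTIONS,
    method: str = "case",
) -> BootstrapResult:
    """Nonparametric bootstrap of one model's parameters on one curve.

    ``method='case'`` resamples (pressure, value) pairs with replacement —
    the assumption-free default; ``method='residual'`` keeps the pressure
    design fixed and resamples the residuals of the full-data fit.  95%
    intervals are the 2.5th/97.5th percentiles of the replicate estimates,
    and a parameter is flagged significant iff its interval excludes zero.
    Reproducible given ``seed``.
    """
    if reps < 100:
        raise ValueError("bootstrap needs at least 100 replicates")
    if method not in ("case", "residual"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    k = PARAM_COUNT[form]
    n = curve.n
    P, y = curve.pressure, curve.values
    rng = np.random.default_rng(seed)

    full = fit_model(curve, form, options)
    if method == "residual":
        if not full.converged:
            raise ValueError("residual bootstrap requires a converged full-data fit")
        fitted = full.model.evaluate(P)
        resid = y - fitted
        idx = rng.integers(0, n, size=(reps, n))
        P_b = np.broadcast_to(P, (reps, n)).copy()
        Y_b = fitted[None, :] + resid[idx]
        redraws = 0
    else:
        idx, redraws = _resample_indices(rng, P, reps, min_distinct=k + 2)
        P_b = P[idx]
        Y_b = y[idx]

    n_failed = 0
    if form == "piecewise":
        draws, thr = _piecewise_boot(P_b, Y_b, options.boot_grid_size)
    elif form == "negexp":
        draws, thr = _negexp_boot(P_b, Y_b, options.boot_grid_size, options.negexp_rate_limit)
    elif form in ("linear", "parabolic"):
        draws, thr = _polynomial_boot(P_b, Y_b, form)
    else:  # sigmoidal: warm-started trust-region refit per replicate
        if full.converged:
            p = full.model.params
            warm = np.array([p.c0, p.c1, math.log(p.c2), math.log(p.c3)])
        else:
            warm = None
        c0s, c1s, c2s, c3s = [], [], [], []
        for r in range(reps):
            starts = [warm] if warm is not None else None
            model, rss, _ = _fit_sigmoid(P_b[r], Y_b[r], options, starts=starts)
            if model is None:
                model, rss, _ = _fit_sigmoid(P_b[r], Y_b[r], options)
            if model is None:
                n_failed += 1
                continue
            pp = model.params
            c0s.append(pp.c0)
            c1s.append(pp.c1)
            c2s.append(pp.c2)
            c3s.append(pp.c3)
        draws = {
            "c0": np.array(c0s),
            "c1": np.array(c1s),
            "c2": np.array(c2s),
            "c3": np.array(c3s),
        }
        with np.errstate(divide="ignore"):
            thr = np.log(1.0 / draws["c2"]) / draws["c3"]

    ci95 = {}
    significant = {}
    for name, arr in draws.items():
        lo, hi = np.percentile(arr, [2.5, 97.5])
        ci95[name] = (float(lo), float(hi))
        significant[name] = not (lo <= 0.0 <= hi)
    return BootstrapResult(
        reps=reps,
        param_draws=draws,
        ci95=ci95,
        significant=significant,
        threshold_draws=None if thr is None else np.asarray(thr, dtype=float),
        n_redraws=redraws,
        n_failed=n_failed,
    )


# ----------------------------------------------------------------------
_COMPANIONS = {
    "piecewise": ("b1", "m1", "m2"),
    "sigmoidal": ("c0", "c1", "c2", "c3"),
}


def threshold_is_significant(form: str, boot: BootstrapResult) -> bool:
    """A utility threshold counts as significant when its own bootstrap
    interval excludes zero and the companion parameters of the winning
    model are not *all* statistically indistinguishable from zero (a model
    whose every other coefficient straddles zero describes no believable
    response to the pressure)."""
    if form not in _COMPANIONS:
        return False
    if boot.threshold_draws is None or boot.threshold_draws.size == 0:
        return False
    lo, hi = np.percentile(boot.threshold_draws, [2.5, 97.5])
    if lo <= 0.0 <= hi:
        return False
    companions = _COMPANIONS[form]
    return any(boot.significant.get(c, False) for c in companions)
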