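"""Weighted nonlinear least squares with bounds, multistart and diagnostics.

This is the engine behind SRTM, 2TCM and delay fitting.  A fit minimises
``sum_i w_i (C_i - model_i)^2`` subject to box bounds, using a trust-region
reflective solver.  Because compartmental objectives can carry local minima
(under-fitting ligands push rate constants toward bounds), a seeded
multistart wrapper refits from starting vectors drawn uniformly within the
bounds and keeps the solution with the lowest weighted SSR.

Estimates that land within ``1e-6 * (upper - lower)`` of a bound raise a
``bound_hit`` warning on the result, the cue to widen bounds or use
multistart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_data import ConvergenceError, TimeActivityCurve, ValidationError

#: fraction of the bound range within which an estimate counts as "at bound"
BOUND_HIT_TOL = 1e-6
#: default number of multistart iterations
DEFAULT_MULTISTART_ITER = 100


@dataclass(frozen=True)
class ParamSpec:
    """Name, starting value and box bounds for one fitted parameter."""

    name: str
    start: float
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValidationError(f"ParamSpec {self.name}: lower must be < upper")
        if not (self.lower <= self.start <= self.upper):
            raise ValidationError(f"ParamSpec {self.name}: start outside bounds")


@dataclass
class FitWarning:
    """A diagnostic attached to a fit: bound hit or convergence trouble."""

    kind: str            # "bound_hit" | "convergence" | "non_reversible" | "delay_bound"
    param: str | None = None
    which: str | None = None  # "lower" | "upper"
    message: str = ""


@dataclass
class FitResult:
    """Outcome of one (multi)start nonlinear fit.

    ``residuals`` are unweighted (data - fitted); ``ssr`` is the weighted
    sum of squared residuals actually minimised.
    """

    estimates: dict[str, float]
    ssr: float
    fitted: np.ndarray
    residuals: np.ndarray
    n_starts_used: int = 1
    warnings: list[FitWarning] = field(default_factory=list)
    success: bool = True

    def has_warning(self, kind: str, param: str | None = None) -> bool:
        return any(w.kind == kind and (param is None or w.param == param)
                   for w in self.warnings)


def _data_vector(y) -> np.ndarray:
    if isinstance(y, TimeActivityCurve):
        return y.activity
    return np.asarray(y, dtype=float)


def _bound_warnings(x: np.ndarray, specs: list[ParamSpec]) -> list[FitWarning]:
    out = []
    for xi, s in zip(x, specs):
        tol = BOUND_HIT_TOL * (s.upper - s.lower)
        if xi - s.lower <= tol:
            out.append(FitWarning("bound_hit", s.name, "lower",
                                  f"{s.name} at lower bound {s.lower:g}"))
        elif s.upper - xi <= tol:
            out.append(FitWarning("bound_hit", s.name, "upper",
                                  f"{s.name} at upper bound {s.upper:g}"))
    return out


def nls_fit(model_fn, y, weights=None, specs: list[ParamSpec] = None,
            start: np.ndarray | None = None) -> FitResult:
    """Weighted bounded nonlinear least squares from a single start.

    ``model_fn`` maps a parameter vector (in ``specs`` order) to the
    predicted curve at the data's sample points.
    """
    data = _data_vector(y)
    if specs is None or not specs:
        raise ValidationError("nls_fit: parameter specs required")
    w = np.ones_like(data) if weights is None else np.asarray(weights, float)
    if w.size != data.size:
        raise ValidationError("nls_fit: weights length must match data")
    if np.any(w < 0):
        raise ValidationError("nls_fit: weights must be >= 0")
    sw = np.sqrt(w)
    lo = np.array([s.lower for s in specs])
    hi = np.array([s.upper for s in specs])
    x0 = np.array([s.start for s in specs]) if start is None else np.asarray(start, float)
    x0 = np.clip(x0, lo, hi)

    def resid(x):
        return sw * (model_fn(x) - data)

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", x_scale="jac")
    if sol.status <= 0:
        raise ConvergenceError(f"nls_fit: solver failed (status {sol.status})",
                               best=None)
    fitted = model_fn(sol.x)
    warnings = _bound_warnings(sol.x, specs)
    if not sol.success:  # pragma: no cover - trf rarely reports this with status>0
        warnings.append(FitWarning("convergence", message=sol.message))
    return FitResult(
        estimates={s.name: float(xi) for s, xi in zip(specs, sol.x)},
        ssr=float(np.sum(w * (data - fitted) ** 2)),
        fitted=fitted,
        residuals=data - fitted,
        warnings=warnings,
        success=sol.success,
    )


@dataclass
class RegressionSummary:
    """Weighted linear regression result used by the linearised models."""

    params: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    names: list[str] = field(default_factory=list)

    @property
    def max_rel_resid(self) -> float:
        """Largest |residual| / |fitted| over included points, in percent."""
        denom = np.maximum(np.abs(self.fitted), 1e-12)
        return float(np.max(np.abs(self.residuals) / denom) * 100.0)


def wls_regression(X: np.ndarray, y: np.ndarray, weights=None,
                   intercept: bool = False,
                   names: list[str] | None = None) -> RegressionSummary:
    """Weighted least-squares regression via statsmodels.

    ``X`` is (n, p) without the constant column; with ``intercept`` the
    constant is prepended and reported first.  Raises
    ``DegenerateInputError`` on a singular design.
    """
    import statsmodels.api as sm

    from .core_data import DegenerateInputError

    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float)
    w = np.ones(y.size) if weights is None else np.asarray(weights, float)
    design = sm.add_constant(X, has_constant="add") if intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateInputError("wls_regression: singular design matrix")
    res = sm.WLS(y, design, weights=w).fit()
    fitted = np.asarray(res.fittedvalues, float)
    r2 = float(res.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0
    r2 = min(max(r2, 0.0), 1.0)
    if names is None:
        names = [f"g{i+1}" for i in range(X.shape[1])]
    if intercept:
        names = ["intercept"] + list(names)
    return RegressionSummary(
        params=np.asarray(res.params, float),
        fitted=fitted,
        residuals=y - fitted,
        r2=r2,
        names=list(names),
    )


def multistart_fit(model_fn, y, weights=None, specs: list[ParamSpec] = None,
                   n_iter: int = DEFAULT_MULTISTART_ITER, seed: int = 0,
                   starts: list | None = None,
                   include_default: bool = True) -> FitResult:
    """Random-restart fitting: refit from many starts, keep the lowest SSR.

    Starting vectors are drawn uniformly within the bounds from a seeded
    generator, so results are a pure function of (data, specs, n_iter, seed).
    The spec-declared default start is included among the candidates (so the
    multistart SSR can never exceed the single-start SSR) unless
    ``include_default=False``.  Pass ``starts`` to force explicit starting
    vectors instead of sampling.
    """
    if specs is None or not specs:
        raise ValidationError("multistart_fit: parameter specs required")
    if starts is None:
        if n_iter < 1:
            raise ValidationError("multistart_fit: n_iter must be >= 1")
        rng = np.random.default_rng(seed)
        lo = np.array([s.lower for s in specs])
        hi = np.array([s.upper for s in specs])
        start_list = list(rng.uniform(lo, hi, size=(n_iter, len(specs))))
        if include_default:
            start_list.append(np.array([s.start for s in specs]))
    else:
        start_list = [np.asarray(s, float) for s in starts]
    best = None
    n_ok = 0
    for x0 in start_list:
        try:
            fit = nls_fit(model_fn, y, weights, specs, start=x0)
        except ConvergenceError:
            continue
        n_ok += 1
        if best is None or fit.ssr < best.ssr:
            best = fit
    if best is None:
        raise ConvergenceError("multistart_fit: every start failed", best=None)
    best.n_starts_used = n_ok
    return best
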