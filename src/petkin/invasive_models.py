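"""Arterial-input quantification: 2TCM, invasive Logan plot and MA1.

The main outcome is the total volume of distribution V_T.  The driving input
is the metabolite-corrected arterial plasma curve (AIF); the measured TAC is
modelled as a blood-volume mixture

    C_PET(t) = (1 - v_B) C_tissue(t) + v_B C_wholeblood(t)

with v_B fixed at 0.05 for the 2TCM and 0 for the graphical methods (Logan,
MA1), matching common software defaults.

2TCM
    Analytic solution of the two-tissue compartment model with rate constants
    K1 (mL/cm^3/min) and k2, k3, k4 (min^-1):
        alpha_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2
        C_tissue = K1/(a2-a1) [(k3+k4-a1) e^(-a1 t) + (a2-k3-k4) e^(-a2 t)] (x) C_P
    V_T = (K1/k2)(1 + k3/k4).
Invasive Logan plot
    Int C_T / C_T regressed on Int C_P / C_T beyond t*; slope = V_T.
MA1
    C_T(T) = b1 Int C_P + b2 Int C_T beyond t*; V_T = -b1/b2.

The delay between tissue and blood curves is fitted once per measurement by
the 2TCM on the whole-brain TAC (search window +/- 30 s) and stored on the
BloodSet; it shifts plasma and whole blood together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core_data import (BloodSet, DegenerateInputError, FineGrid,
                        TimeActivityCurve, ValidationError, aif_curve,
                        conv_trapz, cumint)
from .fitting import (FitResult, FitWarning, ParamSpec, RegressionSummary,
                      multistart_fit, nls_fit, wls_regression)
from .reference_models import MIN_POINTS

#: default fractional blood volume for the 2TCM
DEFAULT_VB = 0.05
#: default delay search half-window, minutes (30 s)
DELAY_WINDOW_MIN = 0.5


def default_2tcm_specs() -> list[ParamSpec]:
    """Default 2TCM starts and bounds (configurable per study)."""
    return [
        ParamSpec("K1", 0.1, 1e-4, 2.0),
        ParamSpec("k2", 0.1, 1e-4, 1.0),
        ParamSpec("k3", 0.05, 1e-4, 1.0),
        ParamSpec("k4", 0.05, 1e-4, 1.0),
    ]


@dataclass
class InvasiveModelResult:
    """Outcome of one arterial-input model on one target TAC."""

    model: str
    vt: float
    K1: float | None = None
    k2: float | None = None
    k3: float | None = None
    k4: float | None = None
    vB: float | None = None
    delay: float = 0.0
    coefficients: np.ndarray | None = None
    tstar_index: int | None = None
    fit: FitResult | RegressionSummary | None = None
    warnings: list = field(default_factory=list)


@dataclass
class DelayResult:
    """Fitted tissue-blood delay, minutes (positive = blood shifted later)."""

    delay: float
    ssr: float
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# 2TCM forward model
# ---------------------------------------------------------------------------

def twotcm_model(K1: float, k2: float, k3: float, k4: float, vB: float,
                 grid: FineGrid, frame_mid: np.ndarray) -> np.ndarray:
    """2TCM prediction at frame midtimes from fine-grid blood curves.

    ``grid`` must carry the curves ``"aif"`` and ``"whole_blood"`` (as built
    by :func:`petkin.core_data.aif_curve`).
    """
    t = grid.t
    aif = grid["aif"]
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    root = np.sqrt(max(disc, 0.0))
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < 1e-12:
        # degenerate 1TC limit (k3 = 0 and k2 = k4)
        irf = K1 * np.exp(-k2 * t)
    else:
        irf = (K1 / (a2 - a1)) * ((k3 + k4 - a1) * np.exp(-a1 * t)
                                  + (a2 - k3 - k4) * np.exp(-a2 * t))
    tissue = conv_trapz(t, aif, irf)
    pred = (1.0 - vB) * tissue + vB * grid["whole_blood"]
    return np.interp(frame_mid, t, pred)


def _blood_grid(target: TimeActivityCurve, blood: BloodSet,
                delay: float | None = None) -> FineGrid:
    b = blood if delay is None else blood.with_delay(delay)
    return aif_curve(b, t_end=float(target.frame_end[-1]))


def fit_2tcm(target: TimeActivityCurve, blood: BloodSet, weights=None,
             specs: list[ParamSpec] | None = None, vB=DEFAULT_VB,
             multistart: bool = False, n_iter: int = 100,
             seed: int = 0) -> InvasiveModelResult:
    """Fit the 2TCM by weighted NLS; V_T = (K1/k2)(1 + k3/k4).

    ``vB`` is either a fixed fraction (default 0.05) or the string ``"fit"``
    to estimate it alongside the rate constants.
    """
    specs = list(specs) if specs else default_2tcm_specs()
    fit_vb = isinstance(vB, str)
    if fit_vb:
        if vB != "fit":
            raise ValidationError(f"fit_2tcm: vB must be a number or 'fit', got {vB!r}")
        specs.append(ParamSpec("vB", DEFAULT_VB, 0.0, 1.0))
    grid = _blood_grid(target, blood)
    mid = target.frame_mid

    def model_fn(x):
        vb = x[4] if fit_vb else float(vB)
        return twotcm_model(x[0], x[1], x[2], x[3], vb, grid, mid)

    if multistart:
        fit = multistart_fit(model_fn, target, weights, specs,
                             n_iter=n_iter, seed=seed)
    else:
        fit = nls_fit(model_fn, target, weights, specs)
    e = fit.estimates
    vt = (e["K1"] / e["k2"]) * (1.0 + e["k3"] / e["k4"])
    vb_out = e["vB"] if fit_vb else float(vB)
    return InvasiveModelResult(
        model="2tcm", vt=float(vt), K1=e["K1"], k2=e["k2"], k3=e["k3"],
        k4=e["k4"], vB=vb_out, delay=blood.delay, fit=fit,
        warnings=list(fit.warnings),
    )


# ---------------------------------------------------------------------------
# delay fitting
# ---------------------------------------------------------------------------

def fit_delay(wholebrain: TimeActivityCurve, blood: BloodSet, weights=None,
              specs: list[ParamSpec] | None = None, vB=DEFAULT_VB,
              window: float = DELAY_WINDOW_MIN,
              coarse_step: float = 1.0 / 12.0) -> DelayResult:
    """Fit the tissue-blood delay with the 2TCM on the whole-brain TAC.

    The delay tau shifts plasma and whole blood together; the 2TCM is refit
    at each candidate tau (coarse 5-s grid over +/- ``window`` minutes, then
    bounded scalar refinement) and the tau with the lowest weighted SSR wins.
    The returned value is meant to be stored on the BloodSet and reused for
    every region of the measurement.
    """
    specs = list(specs) if specs else default_2tcm_specs()
    mid = wholebrain.frame_mid

    def ssr_at(tau: float) -> float:
        grid = _blood_grid(wholebrain, blood, delay=blood.delay + tau)

        def model_fn(x):
            return twotcm_model(x[0], x[1], x[2], x[3], float(vB), grid, mid)

        return nls_fit(model_fn, wholebrain, weights, specs).ssr

    taus = np.arange(-window, window + 1e-12, coarse_step)
    ssrs = np.array([ssr_at(tau) for tau in taus])
    i = int(np.argmin(ssrs))
    lo = taus[max(i - 1, 0)]
    hi = taus[min(i + 1, taus.size - 1)]
    res = minimize_scalar(ssr_at, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    tau = float(res.x)
    warnings = []
    if window - abs(tau) < 1e-3:
        warnings.append(FitWarning("delay_bound", param="delay",
                                   which="upper" if tau > 0 else "lower",
                                   message=f"delay {tau:.3f} min at search bound"))
    return DelayResult(delay=tau, ssr=float(res.fun), warnings=warnings)


# ---------------------------------------------------------------------------
# graphical / multilinear methods
# ---------------------------------------------------------------------------

def _invasive_frames(target: TimeActivityCurve, blood: BloodSet, tstar: float):
    """Frame-level series for the linearised invasive models.

    Int C_P is accumulated on the fine grid (the AIF peak is much sharper
    than the frame schedule) and interpolated at frame midtimes; Int C_T uses
    frame midtimes with the (0, 0) anchor.
    """
    mid = target.frame_mid
    ct = target.activity
    grid = _blood_grid(target, blood)
    icp_fine = cumint(grid.t, grid["aif"])
    icp = np.interp(mid, grid.t, icp_fine)
    ict = cumint(mid, ct)
    mask = mid >= tstar
    if mask.sum() < MIN_POINTS:
        raise ValidationError(
            f"t* = {tstar:g} min leaves {int(mask.sum())} frames; need >= {MIN_POINTS}"
        )
    return mid, ct, ict, icp, mask


def _subw(weights, mask):
    return None if weights is None else np.asarray(weights, float)[mask]


def fit_logan(target: TimeActivityCurve, blood: BloodSet, weights=None,
              tstar: float = 0.0) -> InvasiveModelResult:
    """Invasive Logan plot; slope = V_T (no blood-volume correction)."""
    mid, ct, ict, icp, mask = _invasive_frames(target, blood, tstar)
    if np.any(ct[mask] <= 0):
        raise ValidationError("logan: non-positive target activity after t*")
    y = ict[mask] / ct[mask]
    x = icp[mask] / ct[mask]
    reg = wls_regression(x, y, _subw(weights, mask), intercept=True,
                         names=["vt"])
    return InvasiveModelResult(model="logan", vt=float(reg.params[1]), vB=0.0,
                               delay=blood.delay, coefficients=reg.params,
                               tstar_index=int(np.argmax(mask)), fit=reg)


def fit_ma1(target: TimeActivityCurve, blood: BloodSet, weights=None,
            tstar: float = 0.0) -> InvasiveModelResult:
    """Ichise's MA1: C_T(T) = b1 Int C_P + b2 Int C_T; V_T = -b1/b2."""
    mid, ct, ict, icp, mask = _invasive_frames(target, blood, tstar)
    X = np.column_stack([icp[mask], ict[mask]])
    reg = wls_regression(X, ct[mask], _subw(weights, mask), names=["b1", "b2"])
    b1, b2 = reg.params
    warnings = []
    if b2 >= 0:
        warnings.append(FitWarning(
            "non_reversible", param="b2",
            message="MA1 b2 >= 0: kinetics look irreversible; V_T unreliable"))
    if b2 == 0:
        raise DegenerateInputError("ma1: b2 = 0, V_T undefined")
    return InvasiveModelResult(model="ma1", vt=float(-b1 / b2), vB=0.0,
                               delay=blood.delay, coefficients=reg.params,
                               tstar_index=int(np.argmax(mask)), fit=reg,
                               warnings=warnings)
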