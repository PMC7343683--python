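"""Non-invasive quantification against a reference region.

Four estimators of the non-displaceable binding potential BP_ND from a target
TAC C_T and a reference-region TAC C_R (a region devoid of specific binding,
e.g. cerebellum):

SRTM
    Nonlinear: C_T(t) = R1 C_R(t) + (k2 - R1 k2a) [C_R (x) e^(-k2a t)](t)
    with k2a = k2 / (1 + BP_ND); fitted by (multistart) weighted NLS.
MRTM1
    Multilinear: C_T(T) = g1 Int C_R + g2 C_R(T) + g3 Int C_T over frames
    with midtime >= t*; yields k2' = g1/g2 and BP_ND = -(g1/g3 + 1).  Fitted
    on a high-binding region to estimate the reference efflux constant k2',
    which is then reused for all regions of that subject.
MRTM2
    As MRTM1 with k2' fixed: C_T(T) = g1 [Int C_R + C_R(T)/k2'] + g3 Int C_T;
    BP_ND = -(g1/g3 + 1).
Non-invasive Logan plot
    Int C_T / C_T regressed on [Int C_R + C_R/k2'] / C_T for frames beyond
    t*; the slope is the distribution-volume ratio DVR and BP_ND = DVR - 1.

Cumulative integrals use frame midtimes with a (0, 0) anchor; t* inclusion is
closed (frames with midtime >= t*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import (DegenerateInputError, FineGrid, TimeActivityCurve,
                        ValidationError, conv_trapz, cumint, interp_with_anchor)
from .fitting import (FitResult, ParamSpec, RegressionSummary, multistart_fit,
                      nls_fit, wls_regression)

MIN_POINTS = 4  # minimum frames in any linearised regression


def default_srtm_specs() -> list[ParamSpec]:
    """Default SRTM starts and bounds (configurable per study)."""
    return [
        ParamSpec("r1", 1.0, 0.0, 10.0),
        ParamSpec("k2", 0.1, 1e-4, 1.0),
        ParamSpec("bp_nd", 1.5, 0.0, 15.0),
    ]


@dataclass
class RefModelResult:
    """Outcome of one reference-tissue model on one target TAC."""

    model: str
    bp_nd: float
    r1: float | None = None
    k2: float | None = None
    k2prime: float | None = None
    dvr: float | None = None
    coefficients: np.ndarray | None = None
    tstar_index: int | None = None
    fit: FitResult | RegressionSummary | None = None
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# SRTM
# ---------------------------------------------------------------------------

def srtm_model(r1: float, k2: float, bp_nd: float, grid: FineGrid,
               frame_mid: np.ndarray, ref_key: str = "ref") -> np.ndarray:
    """SRTM forward model sampled at frame midtimes."""
    ref = grid[ref_key]
    k2a = k2 / (1.0 + bp_nd)
    conv = conv_trapz(grid.t, ref, np.exp(-k2a * grid.t))
    ct = r1 * ref + (k2 - r1 * k2a) * conv
    return np.interp(frame_mid, grid.t, ct)


def _ref_grid(target: TimeActivityCurve, ref: TimeActivityCurve) -> FineGrid:
    if not (np.array_equal(target.frame_start, ref.frame_start)
            and np.array_equal(target.frame_end, ref.frame_end)):
        raise ValidationError("target and reference TACs must share frame timing")
    grid = FineGrid.make(float(target.frame_end[-1]))
    grid["ref"] = interp_with_anchor(ref.frame_mid, ref.activity, grid.t)
    return grid


def fit_srtm(target: TimeActivityCurve, ref: TimeActivityCurve, weights=None,
             specs: list[ParamSpec] | None = None, multistart: bool = False,
             n_iter: int = 100, seed: int = 0) -> RefModelResult:
    """Fit SRTM by weighted NLS; returns R1, k2 and BP_ND."""
    specs = specs or default_srtm_specs()
    grid = _ref_grid(target, ref)
    mid = target.frame_mid

    def model_fn(x):
        return srtm_model(x[0], x[1], x[2], grid, mid)

    if multistart:
        fit = multistart_fit(model_fn, target, weights, specs,
                             n_iter=n_iter, seed=seed)
    else:
        fit = nls_fit(model_fn, target, weights, specs)
    est = fit.estimates
    return RefModelResult(model="srtm", bp_nd=est["bp_nd"], r1=est["r1"],
                          k2=est["k2"], fit=fit, warnings=list(fit.warnings))


# ---------------------------------------------------------------------------
# linearised models
# ---------------------------------------------------------------------------

def _linear_frames(target: TimeActivityCurve, ref: TimeActivityCurve,
                   tstar: float):
    """Frame-level series and the t* inclusion mask (midtime >= t*, closed)."""
    if not np.array_equal(target.frame_mid, ref.frame_mid):
        raise ValidationError("target and reference TACs must share frame timing")
    mid = target.frame_mid
    ct, cr = target.activity, ref.activity
    ict = cumint(mid, ct)
    icr = cumint(mid, cr)
    mask = mid >= tstar
    if mask.sum() < MIN_POINTS:
        raise ValidationError(
            f"t* = {tstar:g} min leaves {int(mask.sum())} frames; need >= {MIN_POINTS}"
        )
    return mid, ct, cr, ict, icr, mask


def _subw(weights, mask):
    return None if weights is None else np.asarray(weights, float)[mask]


def fit_mrtm1(target: TimeActivityCurve, ref: TimeActivityCurve, weights=None,
              tstar: float = 0.0) -> RefModelResult:
    """MRTM1: multilinear fit yielding k2' and BP_ND."""
    mid, ct, cr, ict, icr, mask = _linear_frames(target, ref, tstar)
    X = np.column_stack([icr[mask], cr[mask], ict[mask]])
    try:
        reg = wls_regression(X, ct[mask], _subw(weights, mask),
                             names=["g1", "g2", "g3"])
    except DegenerateInputError:
        raise
    g1, g2, g3 = reg.params
    if g2 == 0 or g3 == 0:
        raise DegenerateInputError("mrtm1: zero coefficient, cannot form outcomes")
    return RefModelResult(model="mrtm1", bp_nd=float(-(g1 / g3 + 1.0)),
                          k2prime=float(g1 / g2), coefficients=reg.params,
                          tstar_index=int(np.argmax(mask)), fit=reg)


def fit_mrtm2(target: TimeActivityCurve, ref: TimeActivityCurve, weights=None,
              k2prime: float = None, tstar: float = 0.0) -> RefModelResult:
    """MRTM2: as MRTM1 with the reference efflux constant k2' fixed."""
    if k2prime is None or k2prime <= 0:
        raise ValidationError("mrtm2: k2prime must be positive")
    mid, ct, cr, ict, icr, mask = _linear_frames(target, ref, tstar)
    X = np.column_stack([icr[mask] + cr[mask] / k2prime, ict[mask]])
    reg = wls_regression(X, ct[mask], _subw(weights, mask), names=["g1", "g3"])
    g1, g3 = reg.params
    if g3 == 0:
        raise DegenerateInputError("mrtm2: zero coefficient, cannot form BP_ND")
    return RefModelResult(model="mrtm2", bp_nd=float(-(g1 / g3 + 1.0)),
                          k2prime=float(k2prime), coefficients=reg.params,
                          tstar_index=int(np.argmax(mask)), fit=reg)


def fit_ref_logan(target: TimeActivityCurve, ref: TimeActivityCurve,
                  weights=None, k2prime: float = None,
                  tstar: float = 0.0) -> RefModelResult:
    """Non-invasive Logan plot; slope = DVR, BP_ND = DVR - 1."""
    if k2prime is None or k2prime <= 0:
        raise ValidationError("ref_logan: k2prime must be positive")
    mid, ct, cr, ict, icr, mask = _linear_frames(target, ref, tstar)
    if np.any(ct[mask] <= 0):
        raise ValidationError("ref_logan: non-positive target activity after t*")
    y = ict[mask] / ct[mask]
    x = (icr[mask] + cr[mask] / k2prime) / ct[mask]
    reg = wls_regression(x, y, _subw(weights, mask), intercept=True,
                         names=["dvr"])
    dvr = float(reg.params[1])
    return RefModelResult(model="reflogan", bp_nd=dvr - 1.0, dvr=dvr,
                          k2prime=float(k2prime), coefficients=reg.params,
                          tstar_index=int(np.argmax(mask)), fit=reg)
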