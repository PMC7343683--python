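"""Synthetic PET data generation.

Provides the test substrate for every model in the package: a parametric
arterial input function, compartmental forward simulation with frame-based
sampling and count-dependent noise, and two-session test-retest cohorts with
controlled between- and within-subject variance.

Input function
    Plasma activity follows a linear-rise/tri-exponential form standard in
    the compartmental-modelling literature:
        C_P(t) = 0                                          for t < t0
        C_P(t) = (A1 (t-t0) - A2 - A3) e^(-L1 (t-t0))
                 + A2 e^(-L2 (t-t0)) + A3 e^(-L3 (t-t0))    otherwise,
    continuous at t0.  Whole blood is plasma divided by a constant
    plasma-to-blood ratio (default 1.2); the parent fraction declines with a
    Hill-type curve tau^h / (t^h + tau^h).

Noise
    Frame noise is zero-mean Gaussian with SD proportional to the square
    root of decay-uncorrected counts per unit time:
        SD_i = noise_scale * sqrt(max(C_i, 0) e^(lambda mid_i) / dur_i),
    the same premise as the counts weighting scheme.  ``noise_scale = 0``
    returns the exact model curve.

All defaults (input constants, 25-frame/63-min schedule, rate constants) are
artifact choices emulating a carbon-11 receptor-ligand acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (C11_HALFLIFE_MIN, BloodSet, FineGrid,
                        TimeActivityCurve, ValidationError, aif_curve,
                        conv_trapz, interp_with_anchor)
from .invasive_models import twotcm_model
from .reference_models import srtm_model

#: default plasma-to-blood ratio
DEFAULT_PB_RATIO = 1.2
#: default Hill parent-fraction parameters (power, half-time in minutes)
DEFAULT_HILL = (2.0, 35.0)
#: default scan length, minutes
DEFAULT_SCAN_MIN = 63.0


@dataclass
class InputFnParams:
    """Parameters of the parametric arterial plasma input.

    Amplitudes A1..A3 in kBq/mL (A1 per minute of rise), decay rates
    L1 > L2 > L3 > 0 in min^-1, appearance delay t0 in minutes.
    """

    A1: float = 60.0
    A2: float = 2.5
    A3: float = 1.0
    L1: float = 4.0
    L2: float = 0.45
    L3: float = 0.012
    t0: float = 0.5

    def __post_init__(self):
        if not (self.L1 > self.L2 > self.L3 > 0):
            raise ValidationError("InputFnParams: need L1 > L2 > L3 > 0")
        if self.A1 <= 0:
            raise ValidationError("InputFnParams: need A1 > 0")


def plasma_input(params: InputFnParams, t) -> np.ndarray:
    """Closed-form plasma activity of the parametric input at times ``t``."""
    t = np.asarray(t, dtype=float)
    s = t - params.t0
    rise = (params.A1 * s - params.A2 - params.A3) * np.exp(-params.L1 * s)
    tail = (params.A2 * np.exp(-params.L2 * s)
            + params.A3 * np.exp(-params.L3 * s))
    return np.where(s < 0, 0.0, rise + tail)


def default_blood_times(t_end: float = DEFAULT_SCAN_MIN) -> np.ndarray:
    """A typical arterial sampling schedule: autosampler-dense early (the
    input peak is sharp), manual sparse samples late."""
    return np.unique(np.concatenate([
        np.arange(0.0, 2.0, 1.0 / 60.0),     # autosampler: every 1 s over the peak
        np.arange(2.0, 5.0, 1.0 / 6.0),      # every 10 s
        np.arange(5.0, 20.0, 0.5),
        np.arange(20.0, t_end + 1e-9, 2.5),
        [t_end],
    ]))


def make_input(params: InputFnParams | None = None, t=None,
               t_end: float = DEFAULT_SCAN_MIN,
               pb_ratio: float = DEFAULT_PB_RATIO,
               hill: tuple[float, float] = DEFAULT_HILL) -> BloodSet:
    """Build a BloodSet from the parametric input sampled at times ``t``."""
    params = params or InputFnParams()
    t = default_blood_times(t_end) if t is None else np.asarray(t, float)
    plasma = plasma_input(params, t)
    h, t50 = hill
    parent = t50 ** h / (t ** h + t50 ** h)
    return BloodSet(time=t, whole_blood=plasma / pb_ratio, plasma=plasma,
                    parent_fraction=parent)


def default_frames(scan_min: float = DEFAULT_SCAN_MIN) -> tuple[np.ndarray, np.ndarray]:
    """Frame schedule with durations growing from 15 s to 6.4 min.

    The default 63-min schedule has 25 frames, the style of a carbon-11
    receptor-ligand acquisition.  Longer scans (e.g. ``scan_min=120`` for
    slowly equilibrating ligands, where the graphical methods need a late
    t*) extend the tail with 6.4-min frames.
    """
    dur = [0.25] * 4 + [0.5] * 4 + [1.0] * 4 + [2.0] * 4 + [4.0] * 4
    if scan_min < sum(dur) + 6.4:
        raise ValidationError("default_frames: scan_min too short for the schedule")
    while sum(dur) + 6.4 <= scan_min + 1e-9:
        dur.append(6.4)
    dur = np.array(dur)
    end = np.cumsum(dur)
    return end - dur, end


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

_MODELS = ("1tc", "2tcm", "srtm")


def simulate_tac(model: str, truth: dict, *, blood: BloodSet | None = None,
                 ref: TimeActivityCurve | None = None, frames=None,
                 noise_scale: float = 0.0, vB: float = 0.0,
                 seed: int | None = None, region_name: str = "sim",
                 halflife: float = C11_HALFLIFE_MIN):
    """Simulate one TAC; returns ``(tac, truth_record)``.

    ``truth`` holds the model parameters: ``{"K1", "k2"}`` for 1tc,
    ``{"K1", "k2", "k3", "k4"}`` for 2tcm (blood-driven), or
    ``{"r1", "k2", "bp_nd"}`` for srtm (driven by a reference TAC).
    """
    if model not in _MODELS:
        raise ValidationError(f"simulate_tac: unknown model '{model}'")
    if frames is None:
        start, end = default_frames()
    else:
        start, end = np.asarray(frames[0], float), np.asarray(frames[1], float)
    mid = 0.5 * (start + end)
    dur = end - start

    if model == "srtm":
        if ref is None:
            raise ValidationError("simulate_tac: srtm needs a reference TAC")
        grid = FineGrid.make(float(end[-1]))
        grid["ref"] = interp_with_anchor(ref.frame_mid, ref.activity, grid.t)
        clean = srtm_model(truth["r1"], truth["k2"], truth["bp_nd"], grid, mid)
    else:
        if blood is None:
            raise ValidationError(f"simulate_tac: {model} needs blood data")
        grid = aif_curve(blood, t_end=float(end[-1]))
        if model == "1tc":
            tissue = truth["K1"] * conv_trapz(
                grid.t, grid["aif"], np.exp(-truth["k2"] * grid.t))
            fine = (1.0 - vB) * tissue + vB * grid["whole_blood"]
            clean = np.interp(mid, grid.t, fine)
        else:
            clean = twotcm_model(truth["K1"], truth["k2"], truth["k3"],
                                 truth["k4"], vB, grid, mid)

    activity = clean
    if noise_scale > 0:
        lam = np.log(2.0) / halflife
        sd = noise_scale * np.sqrt(np.maximum(clean, 0.0) * np.exp(lam * mid) / dur)
        rng = np.random.default_rng(seed)
        activity = clean + rng.normal(0.0, 1.0, size=clean.size) * sd
    record = dict(truth)
    record.update({"model": model, "noise_scale": noise_scale, "vB": vB,
                   "region_name": region_name})
    return TimeActivityCurve(region_name, start, end, activity), record


# ---------------------------------------------------------------------------
# test-retest cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-session test-retest cohort design.

    Subject-level true binding ~ Normal(mean, between_sd^2); each session's
    truth adds Normal(0, within_sd^2).  The implied population ICC is
    between_sd^2 / (between_sd^2 + within_sd^2).
    """

    n_subjects: int = 20
    sessions: int = 2
    true_binding_mean: float = 1.5
    between_sd: float = 0.3
    within_sd: float = 0.3
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("CohortSpec: n_subjects must be >= 2")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValidationError("CohortSpec: SDs must be >= 0")

    @property
    def true_icc(self) -> float:
        tot = self.between_sd ** 2 + self.within_sd ** 2
        return self.between_sd ** 2 / tot if tot > 0 else float("nan")


# fixed reference-region kinetics shared by every simulated subject
_REF_K1 = 0.10
_REF_K2PRIME = 0.10
_SRTM_R1 = 1.0


@dataclass
class SimulatedCohort:
    """Cohort output: TACs per (subject, session) plus the truth table."""

    spec: CohortSpec
    tacs: dict = field(default_factory=dict)   # (subject, session) -> {"ref","target"}
    blood: BloodSet | None = None
    truth: pd.DataFrame | None = None

    @property
    def true_icc(self) -> float:
        return self.spec.true_icc

    def estimates_long(self, fit_fn, region: str = "target",
                       model: str = "srtm") -> pd.DataFrame:
        """Apply ``fit_fn(ref_tac, target_tac) -> float`` per session TAC and
        return the long-format estimate table used by the reliability module."""
        rows = []
        for (subject, session), pair in sorted(self.tacs.items()):
            est = fit_fn(pair["ref"], pair["target"])
            rows.append({"subject": subject, "session": session,
                         "region": region, "model": model, "estimate": est})
        return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a two-session reference-tissue cohort.

    All subjects share the arterial input and reference-region kinetics
    (1TC with k2' = 0.1 min^-1); target TACs follow SRTM with R1 = 1 and the
    drawn session-level BP_ND truth (floored at 0.01).  The truth table
    carries the drawn values and the implied population ICC.
    """
    rng = np.random.default_rng(spec.seed)
    blood = make_input()
    cohort = SimulatedCohort(spec=spec, blood=blood)
    # the SRTM generator is driven by the true (noise-free) reference curve;
    # the observed reference TAC carries its own measurement noise
    clean_ref, _ = simulate_tac("1tc", {"K1": _REF_K1, "k2": _REF_K2PRIME},
                                blood=blood, noise_scale=0.0, region_name="ref")
    rows = []
    subj_true = rng.normal(spec.true_binding_mean, spec.between_sd,
                           size=spec.n_subjects)
    for i in range(spec.n_subjects):
        for s in range(1, spec.sessions + 1):
            bp = subj_true[i] + (rng.normal(0.0, spec.within_sd)
                                 if spec.within_sd > 0 else 0.0)
            bp = max(bp, 0.01)
            ref_seed = int(rng.integers(2 ** 31))
            tgt_seed = int(rng.integers(2 ** 31))
            if spec.noise_scale > 0:
                ref, _ = simulate_tac(
                    "1tc", {"K1": _REF_K1, "k2": _REF_K2PRIME}, blood=blood,
                    noise_scale=spec.noise_scale, seed=ref_seed,
                    region_name="ref")
            else:
                ref = clean_ref
            truth = {"r1": _SRTM_R1, "k2": _SRTM_R1 * _REF_K2PRIME, "bp_nd": bp}
            target, _ = simulate_tac(
                "srtm", truth, ref=clean_ref, noise_scale=spec.noise_scale,
                seed=tgt_seed, region_name="target")
            cohort.tacs[(i + 1, s)] = {"ref": ref, "target": target}
            rows.append({"subject": i + 1, "session": s,
                         "true_bp_nd": bp, "true_r1": _SRTM_R1,
                         "true_k2": _SRTM_R1 * _REF_K2PRIME,
                         "true_icc": spec.true_icc})
    cohort.truth = pd.DataFrame(rows)
    return cohort
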