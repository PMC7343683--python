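"""t* selection for the linearised models.

Graphical/multilinear methods (Logan, reference Logan, MA1, MRTM2) rely on an
asymptotic linearity that only holds after some time t*.  Including frames
before t* biases the slope; excluding too many inflates variance.  The scan
below fits the chosen model at every candidate start frame (each candidate
keeps the frames from that midtime onward, and at least 4 points) and records
two linearity metrics per candidate: the regression R^2 and the largest
relative residual (|residual| / |fitted|, percent) over the included frames.

Two selection policies are offered:

``tstar_auto``
    Per-measurement automatic choice: the earliest candidate whose maximum
    relative residual is within a threshold (default 10%) — maximising the
    number of frames subject to the linearity criterion.
``tstar_fixed``
    One t* shared across a study: the smallest candidate time at which every
    subject's scan passes the threshold, which by construction is never
    earlier than any subject's automatic choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (ConfigurationError, DegenerateInputError,
                        ValidationError)
from .fitting import wls_regression
from .invasive_models import fit_logan, fit_ma1
from .reference_models import MIN_POINTS, fit_mrtm2, fit_ref_logan

#: default linearity threshold: max relative residual, percent
DEFAULT_MAX_ERROR = 10.0

_MODELS = ("linear", "logan", "reflogan", "ma1", "mrtm2")


@dataclass
class TstarDiagnostics:
    """Per-candidate t* linearity table with columns
    ``start_index, tstar, n_frames, r2, max_rel_resid``."""

    model: str
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _fit_at(model: str, tstar: float, *, target=None, ref=None, blood=None,
            k2prime=None, weights=None, x=None, y=None):
    if model == "logan":
        return fit_logan(target, blood, weights, tstar=tstar).fit
    if model == "ma1":
        return fit_ma1(target, blood, weights, tstar=tstar).fit
    if model == "reflogan":
        return fit_ref_logan(target, ref, weights, k2prime=k2prime, tstar=tstar).fit
    if model == "mrtm2":
        return fit_mrtm2(target, ref, weights, k2prime=k2prime, tstar=tstar).fit
    raise ConfigurationError(f"unknown t* model '{model}'")


def tstar_scan(model: str, *, target=None, ref=None, blood=None, k2prime=None,
               weights=None, x=None, y=None) -> TstarDiagnostics:
    """Fit ``model`` at every candidate t* and tabulate linearity metrics.

    For ``model="linear"`` pass plain ``x``/``y`` samples (ascending x);
    otherwise pass the TAC/blood inputs of the corresponding fit function.
    Candidate t* values are frame midtimes (or x values) leaving at least
    4 points.
    """
    if model not in _MODELS:
        raise ConfigurationError(f"unknown t* model '{model}'; choose from {_MODELS}")
    if model == "linear":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        times = x
    else:
        if target is None:
            raise ValidationError("tstar_scan: target TAC required")
        times = target.frame_mid
    n = times.size
    n_candidates = n - MIN_POINTS + 1
    if n_candidates < 4:
        raise ValidationError(
            f"tstar_scan: only {max(n_candidates, 0)} usable candidates; need >= 4")
    rows = []
    for i in range(n_candidates):
        try:
            if model == "linear":
                w = None if weights is None else np.asarray(weights, float)[i:]
                reg = wls_regression(x[i:], y[i:], w, intercept=True)
            else:
                reg = _fit_at(model, float(times[i]), target=target, ref=ref,
                              blood=blood, k2prime=k2prime, weights=weights)
            r2, mrr = reg.r2, reg.max_rel_resid
        except (ValidationError, DegenerateInputError):
            # candidate not fittable (e.g. zero activity in early frames):
            # record it as unusable rather than aborting the scan
            r2, mrr = 0.0, float("inf")
        rows.append({
            "start_index": i,
            "tstar": float(times[i]),
            "n_frames": n - i,
            "r2": r2,
            "max_rel_resid": mrr,
        })
    return TstarDiagnostics(model=model, table=pd.DataFrame(rows))


def tstar_auto(diag: TstarDiagnostics,
               max_error: float = DEFAULT_MAX_ERROR) -> float:
    """Earliest candidate t* whose max relative residual is within threshold."""
    tab = diag.table.sort_values("tstar")
    ok = tab[tab["max_rel_resid"] <= max_error]
    if ok.empty:
        raise ValidationError(
            f"no t* candidate reaches max_rel_resid <= {max_error:g}%; "
            "inspect the diagnostics table and choose t* manually")
    return float(ok.iloc[0]["tstar"])


def tstar_fixed(diags: list[TstarDiagnostics],
                max_error: float = DEFAULT_MAX_ERROR) -> float:
    """Smallest candidate time at which every subject passes the threshold.

    Subjects must share a frame schedule (candidate t* values are matched to
    1e-6 min).  Ties break toward more frames automatically because the
    smallest qualifying time is returned.
    """
    if not diags:
        raise ValidationError("tstar_fixed: need at least one subject")
    key = lambda tab: np.round(tab["tstar"].to_numpy(float), 6)
    common = set(key(diags[0].table))
    for d in diags[1:]:
        common &= set(key(d.table))
    if not common:
        raise ValidationError("tstar_fixed: subjects share no candidate t* values")
    for t in sorted(common):
        if all(
            float(d.table.loc[np.isclose(key(d.table), t), "max_rel_resid"].iloc[0])
            <= max_error
            for d in diags
        ):
            return float(t)
    raise ValidationError(
        f"no shared t* reaches max_rel_resid <= {max_error:g}% for every subject")
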