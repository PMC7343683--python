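# Methods

## Conventions

All internal quantities use minutes, kBq/mL and min⁻¹. TAC files may declare
seconds and are converted on read; the BIDS-style blood dialect
(`time, whole_blood_radioactivity, plasma_radioactivity,
metabolite_parent_fraction`) is read with time in seconds per that
convention. Model predictions are evaluated on a uniform fine grid (default
step 1 s, configurable) and sampled at frame midtimes; frame-averaging is
not used — midtime sampling is the dominant convention and the difference is
far below count noise at typical frame durations. Cumulative integrals are
trapezoidal with an implicit (0, 0) anchor (a TAC starts at injection with
zero activity); convolutions use FFT with trapezoid end-point correction,
verified against ODE integration to ~10⁻⁵ relative error at the default grid
step.

## Blood processing

The AIF is plasma × parent fraction. Between samples it is linearly
interpolated with the (0, 0) anchor; beyond the last sample a
mono-exponential fitted to the final third of samples extrapolates the tail
(late-frame integrals need it; a non-decaying tail falls back to holding the
last value). A fitted delay shifts plasma and whole blood together —
physiologically both arrive late — and is estimated by refitting the 2TCM on
a whole-brain TAC over a coarse 5-s grid of candidate delays within ±30 s
(typical cannula transit offsets) followed by bounded scalar refinement.
Delay at the window edge raises a warning.

## Weights

Three framewise schemes: `constant` (all ones — the common commercial-tool
default), `duration`, and `counts`, the package default: inverse-variance
weights under Poisson counting statistics, w_i ∝ dur_i / max(C_i·e^(−λ·mid_i), ε)
with λ = ln 2 / half-life (default 20.4 min, carbon-11) and ε = 5% of the
curve's maximum decay-uncorrected value. The ε floor keeps weights finite on
empty or negative early frames; it is configurable (`WeightScheme.eps_frac`).
Weights are normalised to mean 1 by default so SSR magnitudes stay
comparable across schemes.

## Fitting

Bounded weighted least squares uses a trust-region reflective solver with
Jacobian-based scaling (rate constants span decades). Default starts and
bounds — SRTM: R1 = 1 ∈ [0, 10], k2 = 0.1 ∈ [10⁻⁴, 1] min⁻¹,
BP_ND = 1.5 ∈ [0, 15]; 2TCM: K1 = 0.1 ∈ [10⁻⁴, 2] mL/cm³/min and
k2, k3, k4 ∈ [10⁻⁴, 1] min⁻¹ starting at 0.1/0.05/0.05 — are package
defaults, overridable per study via `ParamSpec`. An estimate within
10⁻⁶·(upper−lower) of a bound raises a `bound_hit` warning: tight enough to
avoid false positives, loose enough to catch genuine clamping. Multistart
draws starting vectors uniformly within the bounds from a seeded generator
(default 100 restarts), always includes the declared default start (so the
multistart SSR can never exceed the single-start SSR), and keeps the lowest
weighted SSR; results are a pure function of (data, specs, n_iter, seed).

## t\* selection

Every linearised model is refit at each candidate start frame (candidates
are frame midtimes leaving ≥ 4 points). The linearity metric is the maximum
relative residual over included frames (default threshold 10%), a simple
statistic from the family used by automatic per-measurement selection in
commercial tools; R² is tabulated alongside. `tstar_auto` takes the earliest
passing candidate (maximising frames subject to linearity); `tstar_fixed`
takes the smallest candidate time at which *every* subject passes, hence is
never earlier than any subject's automatic choice. Candidates that cannot be
fitted at all (zero early-frame activity) are recorded with infinite
residual rather than aborting the scan.

## Reliability statistics

ICC(A,1) — two-way, absolute-agreement, single-measurement — is computed
from the two-way ANOVA mean squares; it is cross-checked in the tests
against an independent first-principles implementation and against
pingouin. CV uses the sample SD (n−1). WSCV = √MS_W / grand mean; AV is
reported per subject and as the mean (the historical convention). The
outlier rule flags a measurement only when it is both > 5 leave-subject-out
SDs from the mean of the *other subjects'* values and a > 500% increase
over the same subject's other measurement (the two printed criteria joined
by AND; OR is available). The same individual's pair is excluded from the
reference sample so that a grossly aberrant pair cannot mask itself.

Note that MRTM1 on a target identical to the reference region is analytically
singular (∫C_T and ∫C_R collinear) and raises a degenerate-input error;
BP_ND = 0 identities are exercised through MRTM2 and the reference Logan
plot, where the design stays full rank.

## Simulator

The simulator emulates a carbon-11 receptor-ligand study. The arterial input
is a linear-rise/tri-exponential form (A1 = 60, A2 = 2.5, A3 = 1 kBq/mL;
L1 = 4, L2 = 0.45, L3 = 0.012 min⁻¹; appearance delay t0 = 0.5 min), sampled
on an autosampler-like schedule (1 s over the first 2 min, sparser later) so
that the sharp peak is represented to < 0.5% of its height. Whole blood is
plasma divided by a constant plasma-to-blood ratio (1.2); the parent
fraction declines as a Hill curve τ^h/(t^h + τ^h) with h = 2, τ = 35 min.
Frame noise is zero-mean Gaussian with SD = noise_scale·√(C·e^(λ·mid)/dur) —
the counts-weighting premise; Gaussian is standard for decay-corrected
concentration data. noise_scale = 0.05 yields ~2–4% relative noise on
mid-to-late frames of a large ROI, which we treat as realistic; 0 returns
the exact forward curve bitwise.

Frame schedules grow from 15-s to 6.4-min frames: 25 frames/63 min for
reference-tissue scans; 120 min for the slowly equilibrating 2TCM truth
(K1 = 0.1, k2 = 0.12, k3 = 0.05, k4 = 0.03; slow eigenvalue ≈ 0.02 min⁻¹),
whose graphical asymptote needs a late t\* — noise-free checks use t\* = 90
min (the last quarter of the scan). Test–retest cohorts draw subject truth
from Normal(1.5, between_sd²) and session truth by adding
Normal(0, within_sd²) (floored at 0.01), giving population
ICC = between²/(between²+within²); the SRTM generator is driven by the
noise-free reference kinetics while the *observed* reference TAC carries its
own noise, as in real data.

What the simulator does not emulate: scanner resolution and partial-volume
effects, motion, time-varying plasma-to-blood ratios, metabolite kinetics,
and model mismatch (data are generated by the same model families that are
fitted). Passing recovery tests therefore demonstrates correctness of the
estimators and pipeline, not robustness to the biological and instrumental
imperfections of real data.

## Problem sizes in the checks

The end-to-end reliability check uses one noise-free n = 200 cohort
(pipeline error only) and the mean over five consecutively-seeded noisy
n = 50 cohorts: at n = 50 the sampling spread of a cohort's realised ICC is
itself ≈ 0.1, so averaging replicates makes the check sensitive to pipeline
bias and noise attenuation rather than to one cohort's luck. Count noise
adds fit error to each session's estimate and attenuates the ICC by roughly
σ_fit²/(σ_b²+σ_w²+σ_fit²) ≈ 0.05 at noise_scale = 0.05 — visible in the
acceptance output as a noisy-cohort ICC slightly below the design value.

## Known limitations

- The graphical methods retain a small negative bias (≈ 1–2% at t\* = 90 on
  the 120-min truth) because the asymptote is approached, never reached —
  inherent to Logan/MA1 on slow kinetics, not a defect of the regression.
- MA1's "weights don't matter when residuals vanish" intuition is only
  approximate noise-free: the linearisation leaves ~0.05% residual
  structure, so switching weight schemes moves V_T by up to ~0.1%.
- MRTM1's k2′ is noise-sensitive (a known property); the macro BP_ND
  outcomes of MRTM2/refLogan are insensitive to moderate k2′ error.
- The delay fit assumes a common delay for plasma and whole blood and no
  dispersion correction.
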