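# petkin

Kinetic modelling of PET time-activity curves: reference-tissue and
arterial-input quantification, t\* selection, and test–retest reliability
statistics, with a built-in synthetic-data simulator.

## The problem

In positron emission tomography, radioligand binding in a region of interest
is estimated by fitting pharmacokinetic models to the time-activity curve
(TAC) — the decay-corrected radioactivity concentration sampled over scan
frames after injection. Which model applies depends on the ligand and on
whether arterial blood sampling is available, and every fit involves further
analytical decisions: statistical weighting of frames, the linearisation
time t\* for graphical methods, parameter bounds and starting points for
iterative fitting, and the delay between tissue and blood curves. `petkin`
implements the six most common quantification models together with those
supporting decisions, plus the agreement and repeatability statistics used
to compare analysis pipelines, all driven by plain tabular text files so
that an analysis is reproducible from code alone.

## Models

**Reference-tissue models** (outcome: non-displaceable binding potential
BP_ND), for ligands with a region devoid of specific binding:

- **SRTM** — C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a·t)](t) with
  k2a = k2/(1+BP_ND), fitted by bounded weighted nonlinear least squares.
- **MRTM1** — multilinear C_T(T) = γ1∫C_R + γ2·C_R(T) + γ3∫C_T over frames
  past t\*; yields the reference efflux constant k2′ = γ1/γ2 and
  BP_ND = −(γ1/γ3 + 1). Fitted on a high-binding region; the k2′ is then
  reused for every region of that subject.
- **MRTM2** — as MRTM1 with k2′ fixed.
- **Non-invasive Logan plot** — ∫C_T/C_T regressed on
  [∫C_R + C_R/k2′]/C_T; slope = DVR, BP_ND = DVR − 1.

**Arterial-input models** (outcome: total volume of distribution V_T), using
the metabolite-corrected arterial plasma curve (AIF):

- **2TCM** — analytic two-tissue compartment model (K1, k2, k3, k4) with
  fractional blood volume v_B (default 0.05);
  V_T = (K1/k2)(1 + k3/k4). The tissue–blood delay is fitted once per
  measurement by the 2TCM on a whole-brain TAC (±30 s window).
- **Invasive Logan plot** — ∫C_T/C_T on ∫C_P/C_T; slope = V_T (v_B = 0).
- **MA1** — C_T(T) = β1∫C_P + β2∫C_T; V_T = −β1/β2 (v_B = 0).

Nonlinear fits support seeded multistart (default 100 random starts drawn
uniformly within the bounds, keeping the lowest weighted SSR) and warn when
an estimate lands on a bound. For the linearised models, `tstar_scan` /
`tstar_auto` / `tstar_fixed` select t\* per measurement or study-wide from a
per-candidate linearity table.

**Reliability statistics**: Pearson r, ICC(A,1)
(= (MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))), bias %, CV, the
within-subject coefficient of variation WSCV = √MS_W/mean·100, absolute
variability AV = 2|X1−X2|/|X1+X2|·100, and an outlier flag (>5 SD from the
rest of the sample **and** >500% within-subject change).

## Worked example

```python
import petkin as pk

# simulate one subject's scan: reference region + target with known binding
blood = pk.make_input()                      # parametric arterial input
ref, _ = pk.simulate_tac("1tc", {"K1": 0.1, "k2": 0.1}, blood=blood,
                         region_name="cerebellum")
target, _ = pk.simulate_tac("srtm", {"r1": 1.2, "k2": 0.15, "bp_nd": 1.5},
                            ref=ref, noise_scale=0.05, seed=42,
                            region_name="striatum")

weights = pk.compute_weights(target, "counts")
srtm = pk.fit_srtm(target, ref, weights)
print(f"SRTM:     R1 = {srtm.r1:.3f}  k2 = {srtm.k2:.4f} /min  "
      f"BP_ND = {srtm.bp_nd:.3f}")

k2p = pk.fit_mrtm1(target, ref, weights, tstar=20.0).k2prime
print(f"MRTM1:    k2' = {k2p:.4f} /min")
mrtm2 = pk.fit_mrtm2(target, ref, weights, k2prime=k2p, tstar=20.0)
logan = pk.fit_ref_logan(target, ref, weights, k2prime=k2p, tstar=20.0)
print(f"MRTM2:    BP_ND = {mrtm2.bp_nd:.3f}")
print(f"refLogan: BP_ND = {logan.bp_nd:.3f}  (DVR = {logan.dvr:.3f})")
```

prints

```
SRTM:     R1 = 1.174  k2 = 0.1571 /min  BP_ND = 1.487
MRTM1:    k2' = 0.1742 /min
MRTM2:    BP_ND = 1.473
refLogan: BP_ND = 1.469  (DVR = 2.469)
```

The generating truth was R1 = 1.2, k2 = 0.15 min⁻¹, BP_ND = 1.5: with
moderate count noise all three BP_ND estimates land within ~2% of truth,
while the MRTM1 k2′ micro-parameter is markedly noisier (0.174 vs the true
0.125 min⁻¹) — binding outcomes are robust where individual rate constants
are not.

A command-line interface mirrors the library (`petkin simulate`, `fit-ref`,
`fit-blood`, `tstar`, `agree`, `trt`); every result table is written with a
paired JSON-lines log holding the resolved configuration, its hash, the
seed, and all fitting warnings, so runs are repeatable bit-for-bit.

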