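# Methods

This note documents the models, the synthetic-data generator, the numeric
choices, and the limits of what the tests can show. Units: time in seconds
internally, kinetic constants in clinical units (K1 in mL/min/g, k2 in
1/min, DV = K1/k2 in mL/g); flows reported in mL/min/g.

## Acquisition model

A dynamic rest acquisition is a contiguous frame grid; the default protocol
is 40 frames (28 × 5 s then 12 × 10 s, 260 s ≈ 4.3 min). All curves are
*frame averages* (re-binned list-mode data are averages, not samples), so
time integration is the rectangle rule over frames and windows must be
frame-aligned — there is deliberately no silent interpolation. Decay,
scatter and attenuation corrections are assumed already applied; every
curve carries a `decay_corrected` flag and the estimators refuse curves
without it. Negative values are legal only on curves flagged as noisy.

## Arterial input

The bolus (50 mL/min) input is a gamma variate
`A·x^α·e^{α(1−x)}`, `x = (t−t₀)/t_p` (peak value `A` at `t₀+t_p`), plus a
delayed, broader recirculation bump (12% of peak) and a slowly declining
tail (15% of peak, rise constant 30 s, decay constant 600 s). The slow
infusion (20 mL/min) is the same curve convolved with a normalized 36-s
boxcar: equal injected dose (areas agree within ~3% over the scan window),
lower and later peak, wider first pass. Defaults: arrival 10 s, peak 30 s,
peak amplitude 150 kBq/mL, shape α = 3. Per-scan physiologic variability is
a 5% log-normal amplitude jitter and a 2-s peak-time jitter, reproducible
from the scan seed.

These parameter values are plausible-shape choices, not fits to published
curves; everything downstream is tested against the generator's own truth,
so only their qualitative features (profile ordering, equal dose, realistic
tail fraction) matter.

## Tissue model and extraction

Tissue curves follow the one-tissue compartment model
`C_t(t) = K1 · (C_a ⊗ e^{−k2 t})` with flow-dependent extraction
`K1 = F·E(F)`, `E(F) = 1 − a·e^{−b/F}` with a = 0.77, b = 0.63 — the
constants conventionally used with the Rb-82 one-tissue model, exposed so a
mismatched set can be supplied deliberately (the retention inversion takes
its own constants, which avoids a hidden inverse crime). At scar flows
(≤ 0.35 mL/min/g) extraction exceeds 0.9, which is exactly why the low-flow
regime is well conditioned for this tracer.

The measured sector value is `RC·C_t + v_b·C_a` with partial-volume
recovery RC = 0.85 (one-dimensional phantom value) and spillover fraction
v_b = 0.10 by default. Tissue washout k2 defaults to 0.15/min for every
sector (resting Rb-82 washout is slow; a flow-linked k2 would make the
retention map non-monotone at high flow for no benefit at rest).

The convolution treats frame-average inputs as piecewise constant, for
which the compartment ODE has an exact per-frame update (both the
end-of-frame state and the frame average are closed-form). Forward model
and fitted model are therefore the *same* operator: no quadrature error,
boxcar inputs solved exactly, smooth inputs (mono-exponential test) agree
with the continuous closed form to well under 1% per frame at 5-s framing.

## Geometry

The left ventricle is a polar grid of 72 angular sectors × 3 rings (basal,
mid, apical) plus one apex cap sector, each sector mapped to exactly one
AHA segment (basal 1–6, mid 7–12, apical 13–16 by 90° spans, apex 17).
Ring area weights follow the equal-area segment convention (6/17, 6/17,
4/17, 1/17), so scar size in %LV is a sector-area sum. The published
17-segment adjacency (ring neighbours, radial neighbours, span-overlap
mid–apical edges, apex adjacent to 13–16) is shipped as an explicit edge
list. A pure 72 × 3 grid would leave segment 17 without sectors, which is
why the apex cap exists.

## Ground-truth flow maps

A scar is a contiguous transmural wedge (random centre; extent 80–130°,
i.e. ~21–34 %LV) with a ±15° border band. Region flow levels are drawn
uniformly from scar 0.15–0.35, border 0.35–0.60, normal 0.55–1.00 mL/min/g,
with 5% per-sector jitter clipped back into each band. Because extraction
compresses flow contrast into uptake contrast, an unconstrained draw can
produce a "scar" whose relative uptake is far above the 50% transmural
threshold; the generator therefore redraws the (scar, normal) pair until
K1(scar)/K1(normal) ∈ [0.33, 0.43], emulating a study population selected
for visually obvious transmural defects (scar relative uptake ~40–47% of
maximum). This is a population model, not a tuning knob: it is applied
identically whatever is being estimated.

Each of the (default 3) rest scans shares the flow map; a per-scan global
flow modulation (5% log-normal) represents the physiologic rest-state
variability that dominates same-day test–retest spread. Frame noise is
zero-mean Gaussian with variance proportional to value/duration
(count statistics of corrected, frame-averaged data), scaled by
`noise_level` (default 1, ≈5% on late tissue frames). Scan profiles follow
the acquisition protocol: the first two scans use bolus and slow infusion
in random order, the third is drawn at random.

Candidate arterial-input locations are modelled as
`scale·C_a + contamination·mean-tissue`: left atrium/aorta is the unbiased
reference (1.0, 0); LV cavity (0.85, 0.05) and mitral-valve plane
(0.80, 0.05) are illustrative bias settings, not estimates of any vendor's
behaviour. An additional `input_scale` knob on the estimator side allows
exactly paired bias experiments on identical scans.

## Estimators

**Retention.** Retention is the late-window tissue mean (140–260 s, the
10-s frame block, duration-weighted, partial-volume corrected) divided by
the first-two-minutes arterial integral. Flow is the root of the predicted
retention map `R(F) = (K1(F)/60) · M / I₁₂₀`, where `M` is the late-window
mean of the blood curve convolved with the assumed washout (0.15/min,
configurable) and `I₁₂₀` the early integral — both computed from the
*observed* (individualized) input, so the map self-calibrates to the
injected dose and curve shape. The map is strictly increasing, so the
inversion is a bracketed 1-D root find (vectorized as a 4001-point
monotone interpolation table, grid 0–12 mL/min/g, error ≪ 0.1%). Zero
uptake maps to zero flow. The model carries no spillover term; blood tail
spill-in is a real (few percent, upward) bias of this estimator family
and is left visible.

**One-tissue fit.** Weighted least squares of
`(1−v_b)·K1·(C_a ⊗ e^{−k2 t}) + v_b·C_a` with frame-duration weights;
bounds K1 ∈ [0,5] mL/min/g, k2 ∈ [0.001,5] /min, v_b ∈ [0,0.8]. Because the
model is linear given k2, fitting profiles the amplitudes out (variable
projection) over a deterministic 30-point geometric k2 grid, then polishes
with bounded trust-region least squares from four deterministic starts
(tolerances 1e-10). The fixed-DV variant substitutes k2 = K1/DV
(default DV 0.77 mL/g, configurable) and profiles only v_b.
Non-convergence is reported on the result (`converged=False`, flagged
unreliable), never raised. Reported MBF inverts the Renkin–Crone map at
the partial-volume-corrected uptake constant `K1·(1−v_b)/RC`; whole-study
estimation uses the same profiled path per sector with a bounded scalar k2
refinement between bracketing grid points, which reaches the same optimum
on noiseless data and keeps a 60-scan benchmark in minutes.

Both estimators are exact on noiseless, model-consistent data by
construction; the parameter-recovery suite therefore checks the pipeline
wiring (windows, units, partial-volume and spillover handling), while the
noise sweeps and bias experiments probe behaviour where the answer is not
built in.

## Quality screen

Eight detectors, each returning a flag plus its numeric evidence; a study
passes iff no flag is raised. Only the spillover bound (0.60) is a
published constant; the rest are conservative defaults, config-exposed,
and validated by round trip against the artifact injector (noiseless
studies of both profiles: each artifact raises exactly its own flag, clean
studies raise none; at default noise the false-positive rate measured over
90 clean scans is zero).

- *Frame durations*: observed schedule must equal the declared protocol
  exactly; evidence is the largest duration difference.
- *Saturation*: ≥ 2 consecutive frames within 1e-9 (relative) of the blood
  maximum. Clipping leaves frames *exactly* equal; smooth curves never tie
  to that precision, whereas a percent-level plateau test misfires whenever
  a symmetric peak straddles a frame boundary.
- *Blood peak time*: outside [10, 90] s (bolus) / [10, 150] s (slow),
  measured from acquisition start. Measuring from a detected arrival frame
  sounds more principled but is self-defeating: a delayed curve delays its
  arrival equally, leaving peak-minus-arrival unchanged.
- *Peak width*: FWHM (linear interpolation around the global peak) outside
  [10, 45] s (bolus) / [20, 90] s (slow).
- *Flat tail*: least-squares slope over the last 60 s below 0.1% of peak
  per second **and** tail mean above 30% of peak (true tails decline, and
  low tails are not suspicious).
- *Motion*: per-frame angular direction of the uptake distribution
  (area-weighted circular mean over myocardial sectors; a defect makes the
  distribution anisotropic, and rigid rotation rotates this direction
  equally), evaluated from 90 s on. Abrupt motion: any jump of the
  median-of-3 filtered series above 1 sector (the filter removes isolated
  noise excursions but preserves steps). Gradual motion: fitted drift
  (LS slope × span) above 1 sector, flagged only when no abrupt jump —
  otherwise a step would always raise both flags.
- *Spillover*: largest fitted v_b across the 17 segment-average curves;
  flag above 0.60.

Default artifact severities (clip at 0.8·peak, 120-s peak delay, 2.8×
width stretch confined to t ≤ 180 s, 35%-of-peak flat tail, 3-sector ramp,
2-sector step at 130 s, spillover 0.7) were chosen jointly with the
thresholds so the confusion matrix is diagonal for any phantom seed; the
width stretch keeps the measured tail untouched because stretching the
whole axis drags the recirculation shoulder into the tail window.

## Scar analysis

Relative uptake (%RU) is the late-window uptake normalized to the maximum
*segment* (the clinical normalization reference is the hottest region of
the polar map, not the noisiest fine sector; the fine map is normalized to
the same reference). ROI-Scar is the largest contiguous fine-grid
component at ≤ 50 %RU (ties broken toward lower mean %RU); disjoint
secondary defects are reported by size only. An all-above-threshold map
returns a flagged empty ROI, not an exception.

Rest scores discretize %RU: ≥ 70 → 0, 50–69 → 1, 35–49 → 2, 10–34 → 3,
< 10 → 4 (standard 5-point scoring; bins config-exposed).

Segment classification applies criteria 2–4 per segment first (defect
coverage > 50% of segment area, score ≥ 2, %RU < 65), then takes the
largest connected candidate set on the AHA graph as Seg-Scar (the
criteria-first order is a documented choice; the alternative order is not
well defined when candidates are scattered). Segments touching the defect
but failing a criterion — or candidates outside the chosen component —
form Seg-Border; the rest are Seg-Norm. Tightening any criterion can only
shrink Seg-Scar. Because Seg-Scar segments admix border tissue wherever
the wedge does not align with segment boundaries, the ROI mean is at or
below the Seg-Scar mean — the mechanism behind the ROI-versus-segment flow
difference, asserted across random phantoms with partially covered scar
segments.

## Gates, repeatability, benchmark

The packaged literature table (13 rows: author, method class, mean ± SD or
published range) yields the gates by `max(mean + 1·SD)` within a method
class (rows published as ranges contribute their range top): 0.39 mL/min/g
(ROI class) and 0.44 (segmental class). The ROI gate is strict
(`value < 0.39` passes); the segmental gate fails only above 0.44.

Test–retest COV is the SD of the signed ordered pairwise differences
(i < j, sample denominator) divided by the mean; with exactly two scans
the single difference is undefined under a sample SD, so the within-pair
SD |d|/√2 is used (documented fallback; a plain per-scan SD/mean
convention is available). Summaries use median and type-7
(linear-interpolation) quartiles so reports are byte-reproducible.

`run_benchmark` wires everything: simulate N phantoms (default 20 × 3
scans — the 60-scan scale of a single-centre study), screen (a scan
failing any QA flag is dropped; a phantom with < 2 surviving scans leaves
the COV pool), estimate per variant, classify, gate, aggregate. Identical
(config, seed) produce byte-identical JSON. At the defaults the unbiased
retention variant lands at ROI-Scar ≈ 0.22 (IQR ~0.20–0.24), scar size
~29 %LV, %RU ~38, COV 4–5%, zero gate failures; fixed-DV misspecification
inflates normal-territory flow ~2×, and scaling the arterial input to 0.7
moves ~20% of scans over the segmental gate.

## Problem sizes

Default experiment sizes (20 phantoms × 3 scans for benchmarks, 40-replicate
noise sweeps, 40-seed ROI-versus-segment checks) are chosen so the complete
analysis chain runs in minutes on a single core while keeping the monotone
comparisons (noise, bias) far from tie-breaking.

## Known limitations

- The simulator and the estimators share the one-tissue model family, so
  absolute accuracy statements are about pipeline consistency, not about
  physiology; model-mismatch experiments (wrong extraction constants,
  wrong washout, wrong DV, input bias) are the scientifically meaningful
  outputs.
- No photon transport, scatter, randoms, reconstruction or voxel imagery;
  partial volume is a single multiplicative constant; motion is rigid
  rotation in the angular coordinate only.
- The QA thresholds other than the 0.60 spillover bound are this package's
  own operationalizations of the named checks.
- The phantom population (wedge scars, uniform band draws, contrast
  selection) is deliberately simple; fractions such as "% scans above the
  segmental gate" depend on it and should be read as mechanism
  demonstrations, not clinical frequencies.
- The per-scan flow modulation means repeat scans share a flow *map* but
  not a flow *state*; fully identical repeats require setting both
  `noise_level` and `flow_jitter_sd` (and the AIF jitters) to zero.
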