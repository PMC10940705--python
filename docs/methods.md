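# Methods

## Assay model

The pipeline analyses kinetic fluorescence recordings of dye-loaded
platelets in plates where an agonist is robot-injected into each well
after a baseline period. Two response phenotypes are modeled: a
sustained rise (GPVI stimulation by collagen-related peptide, recorded
10 min after injection) and a transient peak (PAR1/4 stimulation by
thrombin, recorded 5 min). Each 1536-well plate carries 192
agonist-control (vehicle) wells, 64 buffer-control (resting) wells and up
to 1280 compound wells; compound plates are screened in duplicate (A/B)
for each agonist, with identical compound placement across the four
plates.

Two instrument artifacts are part of the model: a slow pre-injection
baseline drift caused by dye leakage, and a transient fluorescence drop
at injection caused by the added volume and the tip crossing the light
path.

## Curve parameters

Each trace is reduced to seven characteristics, all on the raw
fluorescence scale (arbitrary units, AU) with responses expressed as
F − F₀ rather than F/F₀ ratios:

| parameter | definition | estimator |
|---|---|---|
| P1 (= F₀) | baseline before injection | median of the last 15 pre-injection samples |
| P2 | maximal increase | P4 − F₀ |
| P3 | slope 1 (rise rate), AU/s | least-squares line from the post-injection minimum to the first smoothed crossing of F₀ + 0.9·(P4 − F₀) |
| P4 | peak after injection | raw sample at the argmax of a width-7 median-filtered copy; ties resolve to the earliest sample |
| P5 | slope 2 (post-peak decline), AU/s | least-squares line over ≤ 60 s starting at the first smoothed sample below F₀ + 0.97·(P4 − F₀); exactly 0 when no sample falls below that level (no decline phase); clamped ≤ 0 |
| P6 | slope 3 (late phase), AU/s | least-squares line from t = 650 s (CRP) / 500 s (thrombin), measured from recording start, to trace end |
| P7 | AUC, AU·s | trapezoidal integral of the signed F − F₀ from injection to trace end |

The slope-3 start is clamped to `trace end − 60 s` when it lies beyond
the recording, and then into [peak time, last sample − 5 samples]. The
"decline absent" criterion for P5 is applied to the baseline-subtracted
response so that all of P2–P7 are invariant to adding a constant to the
trace and scale linearly with the trace.

### Why the fit windows are anchored at amplitude crossings

The hit-calling stage standardizes every parameter into a per-plate
Z-score and calls |Z| > 4, i.e. it probes the extreme tails of each
estimator's null distribution. Estimators whose fit window is delimited
by a noisy argmax are not Gaussian in those tails: the argmax of a curve
with a kinked peak jitters by several samples, which (a) mixes
decay-phase samples into a rise fit (multimodal slope distribution) and
(b) modulates the window length (a scale mixture). Both effects were
measured on simulated null plates at several-fold the Gaussian tail mass.
Anchoring the window ends at fixed amplitude fractions of the response
removes both: every fitted sample lies on the phase being fitted, and on
a linear phase a constant-length window sliding with the crossing jitter
leaves the least-squares slope unchanged. The same reasoning selects the
peak estimator (median filter, raw value at the filtered argmax): mean
smoothing displaces the argmax of an asymmetric peak, and taking a raw
maximum in a window around it adds a max-selection skew. On a noise-free
kinked peak the median-filter argmax (earliest tie) recovers the exact
peak sample; on sharp synthetic kinks it may read a sample or two early,
a deterministic offset common to all wells that cancels in normalization
and Z-scoring.

All window parameters are configurable (`ProfilingConfig`); the
measured |Z| > 4 false-call rate on null plates with the defaults is
reported by `scripts/acceptance.py` next to the Gaussian expectation.

## Duplicate-consistency QC

For each compound the duplicate traces A and B are aligned on a common
post-injection grid (linear interpolation onto the coarser grid when
grids differ; the pre-injection segment is excluded because dye-leak
drift differences would dominate). The pointwise relative difference
r_t = |A_t − B_t| / (max(A∪B) − min(A∪B)) uses the combined range of
both signals; the difference index is the 95th percentile of {r_t} with
the linear-interpolation percentile convention (rank = q·(n−1)).
DI ≤ 30 % marks the pair consistent; inconsistent pairs are excluded
before Z-scoring. DI is symmetric, bounded in [0, 1], and invariant to
shifting or positively scaling both traces together.

A consequence worth knowing: a duplicate pair of *flat* traces (failed
injection in both replicates) has DI ≈ noise / (noise range) ≈ 0.4, so
failed injections are rejected by the DI filter itself, before the
dedicated artifact stage. The dedicated detectors still run and their
flags are reported per compound.

## Artifact detectors

Visual curve inspection is replaced by two detectors:

* **Interference** — a compound well whose pre-injection median lies
  above (autofluorescent) or below (quencher) the plate's control
  pre-injection median by more than k·MAD (default k = 6; MAD floored at
  1 % of the control median when zero).
* **Injection failure** — flagged only when *both* no injection-drop
  step ≥ 25 AU exists within ±10 s of the scheduled injection (the step
  scan runs on a 3-sample median-filtered trace so single noise
  excursions neither fake nor mask a drop) *and* the well's P2 is below
  10 % of the control median P2. The conjunction protects genuine strong
  inhibitors, whose drop artifact is intact. The response threshold is
  10 % rather than lower because baseline drift alone gives a failed
  well an apparent P2 of several percent of control on a 10-minute
  recording.

## Normalization, Z-scores and the cascade

Per plate, each parameter is divided by the mean of the agonist-control
wells (× 100 %); a parameter whose control mean is exactly 0 (e.g. P5 on
plates without a decline phase) is carried as missing and excluded from
activity calls. A/B duplicate percent values are averaged per compound,
then Z-scored per parameter over the plate pair's compound wells.

Two Z variants are provided. The classical Z = (x − mean)/SD (ddof = 1)
matches the textbook definition and is exactly calibrated on clean
plates. The robust variant Z = (x − median)/(1.4826·MAD) is the cascade
default, because the reference distribution on a real screening plate
contains the actives and interferers themselves: a handful of strong
interferers inflates the plate SD enough to mask genuine inhibitors
(measured: a magnitude-0.2 inhibitor drops from |Z| ≈ 50 to |Z| ≈ 2–3),
while median/MAD are unaffected at realistic contamination fractions.
On null plates the MAD's larger sampling jitter makes the robust
|Z| > 4 rate run ~1.5× the Gaussian expectation; calibration statements
therefore refer to the classical variant.

A compound is *active* when at least one of P2–P7 exceeds |Z| > 4 (P1 is
excluded: baseline shifts indicate interference, not a response effect).
Direction is read from the direction parameters (default P2 and P7) that
exceed the threshold: all negative → inhibitor, all positive →
potentiator, otherwise mixed. The cascade per agonist:

1. duplicate-consistent (DI ≤ 30 %);
2. active (|Z| > 4);
3. agonist-specific — active with exactly one agonist; compounds
   screened with a single agonist cannot be called specific and are
   dropped here with a warning;
4. inhibitor direction;
5. artifact rejection (injection-failure or interference flags);
6. ADMET — an external in-silico flag consumed from an annotation table;
   unknown compounds are retained.

Stage counts are non-increasing and each stage's retained set is a
subset of the previous one; the report carries ids, counts, a config
snapshot and input checksums.

For orientation, the original campaign this workflow reproduces screened
16,635 compounds per agonist and reported 11,883 / 12,952
duplicate-consistent compounds (CRP / thrombin), 333 / 330 actives,
310 / 209 agonist-specific compounds, 108 / 43 inhibitors and 151 total
selected molecules. Those counts depend on its full compound library and
plate data, which this package does not ship; the synthetic-screen
counts computed here (e.g. 320 → 316 → 24 → 20 → 12 → 8 → 8 for a
default CRP screen) are the package's own and are not comparable
number-for-number. `calscreen.external.read_screen_table` imports such
per-compound result tables defensively when one is available, after
which the same cascade can be run on them.

## Dose–response confirmation

Single-dose confirmation uses inhibition = 100 − percent-of-control with
a strict > 25 % pass. IC₅₀ estimation fits the four-parameter logistic
by least squares with IC₅₀ parameterized on log₁₀ scale, multi-start
initialization (5-point log-spaced IC₅₀ grid × 3 hill starts), and
bounds hill ∈ [0.2, 10], bottom ∈ [−10, 50] %, top ∈ [50, 150] %,
IC₅₀ ∈ [min conc/100, max conc×100]. Fits are unweighted. A fit is
reported non-converged when responses carry no downward trend, the
optimizer fails, or the fitted IC₅₀ leaves the admissible range. The
multi-start solution was checked against a differential-evolution global
optimizer on noisy series and always attained the same minimum. With six
doses measured in duplicate wells (the confirmation-assay layout) and
5 % response noise, the median relative IC₅₀ error is ≈ 10 %; with
single wells the intrinsic error of the 4-parameter fit is ≈ 17 %.

## Synthetic data generator

Traces are piecewise linear plus i.i.d. Gaussian noise: baseline with
dye-leak drift (+0.02 AU/s), a 60 AU injection drop recovering linearly
over 10 s, a linear rise (2.8 AU/s CRP, 3.5 AU/s thrombin) from 100 AU
baseline to 500 AU peak, then either a transient decline (2.0 AU/s,
thrombin, floored at baseline) or — for the sustained phenotype — a
partial decline (1.0 AU/s for 120 s) followed by a slow late-phase rise
(+0.03 AU/s), which is what the slope-3 parameter measures late in
sustained responses. Default sampling 2 s, injection at 60 s, total
660 s (CRP) / 360 s (thrombin), noise SD 8 AU ≈ 2 % of the 400 AU
control response. Every well has its own deterministic noise substream
keyed on (seed, plate id, well id), so generation order is irrelevant
and identical seeds give bit-identical plates.

Planted effects: inhibitors/potentiators multiply the baseline-subtracted
response (default magnitudes 0.2 / 1.5); autofluorescent and quenching
interferers multiply the whole trace (3.0 / 0.2); injection failures
suppress both the drop artifact and the response. Effects are keyed by
compound, shared by both duplicates, and gated by an agonist-selectivity
attribute. Default planted fractions per screen: 2.5 % CRP-specific and
2.5 % thrombin-specific inhibitors, 1.25 % each of dual-agonist
inhibitors, potentiators, autofluorescent, quenching and
injection-failure compounds.

What the generator does *not* emulate: autocorrelated or
heteroscedastic noise, plate-position (edge/evaporation) effects,
compound carry-over, partial injections, donor-to-donor response
variability, and real compound pharmacology. Passing the recovery tests
therefore shows that the statistical machinery is correct under the
stated noise model, not that the thresholds are optimal for any
particular instrument.

## Problem sizes and numerical choices

The test suite and acceptance script use ten 1,280-compound null plates
for Z calibration, twenty 320-compound duplicate screens for cascade
recovery, and twenty seeded dose–response series for IC₅₀ recovery —
sizes chosen so the whole verification runs in about a minute while the
binomial/Poisson resolution of each check remains informative. Percentile
computation uses numpy's linear-interpolation convention; least-squares
slopes use the closed-form centered formulation; the AUC uses the
trapezoidal rule on the recorded grid. Trace CSVs are written at full
float precision and parsed with a correctly-rounded reader, so dataset
round trips are bit-exact.

## Known limitations

* The DI statistic rejects flat duplicate pairs by construction, so
  injection failures never reach the dedicated artifact stage; their
  detector flags are still reported.
* Autofluorescent interferers scale the response upward and are removed
  as potentiation-direction compounds (stage 4) rather than at the
  artifact stage; their interference flag is likewise reported.
* The activity rule (which parameters, how many simultaneously) and the
  duplicate-merging convention are configurable because no single
  convention is canonical; reported stage counts depend on them.
* P4's ties-first median-filter peak location reads a sample or two
  early on perfectly sharp noise-free kinks (a deterministic, sub-percent
  offset that cancels in Z-scoring).
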