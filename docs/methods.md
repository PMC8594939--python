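# Methods

## The system being modelled

A budding-yeast batch culture exhausting glucose passes through four
population growth phases: exponential fermentation (doubling time 84 min),
a diauxic-shift arrest (DS, 5.5–13.9 h after inoculation in the conditions
the defaults encode), slow respiratory growth on ethanol (doubling time
307 min) until ~31.6 h, and stationary phase (SP). At the DS the population
splits: ~88% of cells switch to respiration (R+) and ~12% fail to (R−).
Cytosolic pH, read out ratiometrically with pHluorin, starts near 7.7,
declines during fermentation, and then diverges — R− cells crash to ~5.8
during the DS, R+ cells plateau near 6.9, rebound to ~7.2 while respiring,
and crash to ~5.8 at heterogeneous times in SP. Distinct protein
superassemblies form when pH falls through marker-specific thresholds
(~7 for P-body/Gln1-type foci, ~6 for actin bodies, PSGs, Cdc28 foci), and
near pH 6 the cytoplasm transitions to a gel-like state in which tracer
particles (lipid droplets, LDs) stop moving.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions above and are not tuned per experiment.

**Lineage.** Event-driven divisions with per-phase doubling times
(lognormal jitter, σ = 0.1, on each interval); no divisions during the DS
or SP, and R− cells never divide after the DS begins. Founder fates are
Bernoulli(0.12); daughters born before the DS copy the mother's fate with
probability `inheritance_strength` (default 0.9) and otherwise resample
from the population fraction; daughters born after the DS onset always
share the mother's fate, because respiratory competence is revealed at the
DS — resampling a post-DS bud would create cells whose pH history
contradicts their mother's. Among R− cells, 19% carry a pre-existing
mitochondrial-DNA defect (ρ−) as a ground-truth label.

**pH program.** Piecewise-linear per fate. R−: 7.7 → 6.9 by the DS onset,
then linearly to 5.8 completing 60% of the way through the DS. R+:
7.7 → 6.9 plateau, rise to 7.2 peaking 40% into the respiration phase,
relax to ~7.05 at SP entry, then a 2-h linear crash to 5.8 starting at a
truncated-normal time (mean 12 h after SP onset, σ = 6 h, truncated at SP
onset) — the heterogeneity of SP crash times is documented in the source
data only qualitatively, so the truncated normal is an explicit stand-in.
Each cell gets a constant additive offset ~N(0, 0.05 pH).

**Markers and mobility.** Foci per marker follow the pH threshold with a
0.1-pH hysteresis margin (so trajectories produce discrete waves rather
than flicker at threshold). Mobility is lost the first frame pH ≤ 6.0 and
never recovers. One LD per cell performs a reflected 2-D random walk with
per-axis step variance 2DΔt, D switching from 0.5 to 0.01 px²/frame at the
gel event. The rendered marker focus co-moves with the LD — one mobility
tracer per cell — which suffices because the analysis never compares the
two tracers' positions.

**Rendering.** Cells are static hard disks (radius 5 px; R+ area grows
linearly to 2× over the respiration phase) placed on a founder grid with
daughters on rings around the mother, rejected on overlap. Channels:
phase (bright body, dark LD puncta), ex390/ex475 with in-cell ratio equal
to a 4-parameter-logistic forward model of pH_true
(R_min 0.3, R_max 3.0, midpoint pH 6.6, slope 1.1), and a marker channel
(diffuse level + focus, or a tubular/fragmented/globular mitochondrial
texture when rendering the mitochondrial marker). Gaussian read noise
(σ = 30 counts on signals of 600–3000 counts) is added last; everything is
deterministic given the seed.

What the generator does **not** emulate: point-spread blur, photobleaching,
focus drift, cell motion and deformation, segmentation-hostile crowding,
uneven illumination, autofluorescence, and the real optics of
phase contrast. Passing tests therefore demonstrate correctness of the
quantification logic on geometrically clean data, not robustness to
real-microscopy artefacts.

## Analysis components and numerical choices

**Segmentation.** Gaussian smoothing (σ = 1 px) → Otsu threshold → hole
filling (LDs punch holes) → small-object removal (< 20 px²) → watershed on
the inverted distance transform seeded at distance peaks (min separation ≈
cell radius). Every step commutes with affine intensity rescaling, which a
property test asserts exactly. Constant images yield an empty mask rather
than an error.

**Tracking.** Gated optimal assignment between consecutive frames with
cost = centroid distance + λ·|ΔA|/A (λ = 5 px per unit relative area
change); leaving a region unmatched costs the gate (default half a cell
diameter, estimated from the median region area). The gated problem is
solved exactly via the augmented square assignment matrix, and a test
checks it against exhaustive enumeration. New regions adjacent to an
existing track and below half its area are recorded as that track's bud
(their area is folded into the mother's `area_total`) until they outgrow
the threshold and become daughter tracks.

**Calibration and pH.** The calibration curve is a 4-parameter logistic in
pH → ratio fitted by bounded least squares to ≥ 4 buffer points spanning
≥ 2 pH units; monotonicity is verified on a grid and a Spearman check
rejects scrambled or inverted tables. Inversion is by bisection on the
fitted curve (the analytic inverse serves as a test oracle); ratios
outside the calibrated range clip to the domain ends with a flag. Cell
ratios are background-subtracted in-mask means (per-frame median outside
all masks); in-mask measurement regions are eroded 2 px where individual
pixels matter (foci, LDs) so rim pixels straddling the boundary cannot
pose as structure. Synthetic buffer points carry 1% relative noise —
calibration ratios are population means over many imaged cells, so they
are much less noisy than a single-cell, single-frame ratio.

**Phase detection.** Continuous piecewise-linear least squares on
ln(count) over a hinge basis; breakpoints restricted to sample times with
≥ 3 samples separation, found by exhaustive enumeration up to 10⁵
placements and otherwise by a deterministic coarse grid refined to a
stride-1 local optimum. Doubling time = ln 2/slope (flagged NaN for
non-positive slopes). Fitting on log counts reconciles "piecewise linear"
bookkeeping with piecewise-exponential growth; continuity is enforced
because transitions are defined as intersections of adjacent pieces.

**pH-drop fits.** Three segments (flat — linear decline — flat) with both
interior breakpoints on frame times; for each breakpoint pair the two
levels have a 2×2 closed-form least-squares solution, and all O(n²) pairs
are enumerated (vectorised per left breakpoint). t½ is the midpoint of the
two breakpoints — where the fitted decline crosses the mean of the levels.
A drop is reported only if the amplitude reaches 0.3 pH *and* the
three-segment model beats the flat fit in an F-ratio test at α = 0.01
(4 vs 1 parameters). The fit is shift-equivariant by construction.

**Foci and mobility.** Globularization score = mean of the five brightest
in-cell pixels − mean of the rest (exactly 0 on constant input;
shift-invariant; gain-equivariant). A focus is called when the score
exceeds k = 4 robust SDs (1.4826·MAD) of the in-cell intensities. The
focus/LD position is the unweighted centroid of the five brightest pixels
(phase is inverted first for the dark LDs). Mobility loss is the exact
two-mean changepoint of the displacement series (prefix-sum enumeration),
requiring ≥ 3 points per side for identifiability, and an event is
reported only when the post-mean falls below half the pre-mean.
Displacement samples are timestamped at the *start* of their interval, so
a changepoint dates the first arrested interval. Displacements before
2 h after the DS onset are excluded, matching when the tracked foci
become reliably present.

**Fate calls.** R− ⇔ a fitted drop whose half-time is at or before the DS
end + 2 h grace *and* whose post-drop level is a genuine crash
(≤ 6.3, midway between the R+ plateau and the terminal pH). The crash
condition exists because the universal fermentation decline (7.7 → 6.9)
is itself a well-fitted "drop" that ends high; without it, R+ cells whose
SP crash falls outside the movie would be miscalled. No lower time bound
is imposed: an early crash's fitted decline merges with the fermentation
decline, dragging t½ slightly before the detected DS onset. Cells without
a detected crash are classified by the respiration-phase area fold
(≥ 1.5× → R+; below that with a track covering the full respiration phase
→ R−), and only tracks that reach back to the DS-end normalisation frame
get a fold at all — anything else stays `unclassified` rather than being
guessed.

**Inheritance index.** Mean within-microcolony variance of the 0/1 fate
over the pooled variance, both with the unbiased (n−1) estimator: exactly
0 when every colony is internally homogeneous and expectation 1 at any
colony size under random assignment. A ratio of standard deviations —
the other natural reading of the definition — is biased well below 1
(≈ 0.73 at colony size 15, fate probability 0.12) because E[s] < sd for
small binary samples, so it cannot satisfy the defining endpoint; the
variance ratio is used for that reason. Colonies with fewer than two
cells are skipped; an all-identical population raises (the index is
undefined at zero pooled variance).

**Coupling.** pH at the mobility-loss time is linearly interpolated from
the per-cell trajectory; cells whose loss time falls outside the measured
span are excluded with a notice. Summaries report median and IQR per fate
and pooled, plus Pearson and Spearman correlations between drop half-time
and loss time.

## Problem sizes

The reference experiments use division-free rendered populations (cells
trapped from t = 0, as in a microfluidic observation chamber): 466 cells
at 30-min frames for fate-fraction recovery, 100 cells at 15-min frames
for the gel-threshold recovery, 50 cells for the pH round trip, and
193-point count series for phase recovery; each runs in well under a
minute to a few minutes on one CPU. Full-lineage movies (divisions,
buds, colony growth) are exercised at smaller scale in the pipeline and
tracking tests.

## Known limitations

- Tracking assumes near-static cells (trap geometry); there is no motion
  model, so fast motion relative to cell spacing will gate out matches.
- One focus/LD per cell; multiple simultaneous foci would shift the top-5
  centroid toward their mean (documented behaviour of the definition).
- The three-segment drop model fits a single drop; the R+ trajectory's
  two-decline structure is handled by the crash condition in the fate
  call, not by a multi-drop fit.
- The inheritance index needs microcolony membership, which the pipeline
  takes from generator ground truth; on real data it requires lineage
  reconstruction upstream.
- `fraction_R_minus` is reported over classified cells; with short or
  coarsely sampled movies many late-born cells are honestly
  `unclassified` and the fraction then reflects the classifiable subset.
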