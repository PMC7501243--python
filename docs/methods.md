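# Methods

`fmtkit` analyses flow-magnetic-tweezers (FMT) experiments: DNA molecules
tethered between a coverslip and a magnetic microsphere, stretched by the
combination of a vertical magnetic force and a lateral drag force, and imaged
at low magnification so that tether-length changes appear as lateral bead
displacements. This note records the models implemented, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was open.

## Force and length calibration

Only the projected tether length `l_xy` is observable, so force `F` and
end-to-end extension `l` are solved simultaneously from the variance of bead
motion orthogonal to flow:

- equipartition: `F = k_B T l / <dy^2>`;
- worm-like chain (WLC) interpolation:
  `F P / (k_B T) = 1/4 (1 - l/l0)^-2 - 1/4 + l/l0`.

Defaults describe a 21 kb dsDNA construct: persistence length `P = 46 nm`,
contour length `l0 = 6.8 um`, `T = 296 K`. The WLC interpolation formula is
used as stated, accepting its known 5–7 % error at mid extension. The root of
`F_wlc(l) - k_B T l / var` is bracketed on `(0, l0)` and solved with Brent's
method to machine tolerance; the root is unique because the WLC force is
convex while the equipartition force is linear in `l`. Variances too large to
intersect the WLC curve raise an error naming the offending value.

Finite camera integration time `W` attenuates the measured variance by the
boxcar blur factor

    S(alpha) = 2/alpha - 2/alpha^2 (1 - e^-alpha),   alpha = W / tau,

with trap relaxation time `tau = gamma l / F` and Stokes friction
`gamma = 6 pi eta R` (bead radius `R = 0.5 um`, viscosity `8.9e-4 Pa s`).
Because `alpha` depends on the solution, the corrected solve iterates: solve,
update `alpha` and `S`, divide the measured variance by `S`, re-solve, until
the force changes by less than 1e-9 relative (converges in a handful of
iterations; 200 allowed). For `alpha < 1e-4` the factor is evaluated by
Taylor series to avoid cancellation. Blur correction always increases the
inferred variance and therefore lowers the force estimate.

Bead geometry follows `theta = arccos(l_xy / l)`, `z = l sin(theta)`; drag
from the laminar channel profile `v = 2 v_max (z/h)(1 - z/h)` with
`v_max = 3 Q / (2 w h)` and `F_d = gamma v`. Note this printed profile peaks
at `v_max / 2` at mid-channel; the package implements it as printed, and the
worked value at `z = 2.1 um` (0.07 pN) confirms that convention. Internally
everything is SI; the public accessors convert to um and pN.

## Localization and tracking

Detection follows the standard chain: discoidal averaging filter (disk mean
minus annulus mean, radii 2 / 5 px by default, kernels truncated at image
edges so constants map to zero), intensity threshold plus local-maximum
test with greedy suppression (ties by smaller row, then column), isotropic
2-D Gaussian least-squares refinement (photons `N = 2 pi A s^2`, gain 1),
and per-frame nearest-neighbour linking within a search radius on a KD-tree
(greedy by ascending distance; each detection used once; gaps up to
`max_gap` frames, default 0). Drift is the across-bead mean displacement of
immobile reference beads, smoothed by a centred moving average (default
5 min window) and subtracted from all tracks, which leaves all same-frame
pairwise distances unchanged.

The theoretical localization precision is

    sigma^2 = s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2)

(photon count `N`, pixel size `a`, background s.d. `b`, spot width `s`). At
the reference imaging point (`N = 50,200`, `a = 1.57 um`, `b = 107`,
`s = 0.78 um`) it evaluates to 5.78 nm, i.e. ~6 nm. Two caveats the tests
make explicit: (i) unweighted least squares carries excess variance over this
bound in photon-limited images, so the fitter offers `weights="photon"`
(inverse expected shot-plus-background noise), which the Monte-Carlo tests
show reaches the numerically computed Cramér–Rao bound; (ii) at the reference
point itself — an undersampled spot (`s = 0.50 px`) under heavy background —
the closed form is optimistic by ~1.4x relative to that bound, so Monte-Carlo
agreement with the formula is asserted only in its valid, photon-limited
regime. The formula itself is still the right summary statistic for
instrument comparison and is what the acceptance computation evaluates.

## Change-point segmentation

Traces are piecewise linear to good approximation, so the detector fits two
independent least-squares lines over every admissible split (at least 3
points per side) and keeps the split minimizing total SSE — an exhaustive
scan, computed in O(n) with prefix sums and exactly equal to the brute-force
double regression. Significance is an F-test of the 4-parameter two-line
model against the single line, Bonferroni-corrected for the number of
scanned splits (the statistic is maximized over candidate splits, so the raw
tail probability is anti-conservative; without the correction ~2/3 of pure
noise traces would split at the 0.05 level). Recursive binary splitting at
confidence 0.99 is followed by a bottom-up merge pass across non-significant
boundaries, because the optimal single split of a multi-kink chunk need not
land on a kink. SSE below `1e-12 x sum(y^2)` is treated as numerically zero
(float cancellation floor of the prefix sums). Ties in SSE break toward the
earliest split; the reported change point is the time of the first point of
the right segment.

## Molecule classification

The pipeline replays the experiment protocol, a timeline of phases
(reversal, negative/positive coiling at high flow, a 33 Hz force window at
the reaction flow, a partial uncoil leaving positive supercoils, the enzyme
reaction):

1. **Mobility.** The attachment site is the midpoint of the extreme
   flow-axis positions during flow reversal; mobile requires swing amplitude
   >= 0.5 um and positional variance above a stuck baseline (0.0025 um^2).
2. **Coilability / multiplicity.** At high force, single intact tethers
   compact only when overwound (underwound DNA melts); nicked tethers ignore
   turns; multiply-tethered beads compact for both senses. Coilable requires
   >= 25 % fractional shortening across the positive coiling phase; single
   requires the negative-phase |slope| to be <= 25 % of the positive-phase
   slope (slopes of `l_xy` against cumulative turns).
3. **Force.** Variance of the orthogonal coordinate in the force window,
   through the blur-corrected solver with `W` = one frame interval
   (>= 100 samples required).
4. **Turn-slope calibration** (nm per magnet turn, at the reaction flow):
   the steepest linear piece of the segmented `l_xy`-versus-turns response
   during the partial uncoil. Segmentation, rather than a plain fit, because
   part of the phase can sit at the compaction floor; non-responding
   molecules raise (cannot be calibrated).
5. **Bursts.** Sliding-window slope search in the reaction phase: maximum
   slope in a 12.5 s window before the trace maximum (positive-supercoil
   relaxation), minimum slope in a 25 s window after it (negative-supercoil
   introduction). A window qualifies if its slope exceeds both 3 standard
   errors and a 10 nm/s floor. Burst velocity in enzymatic cycles/s is
   |slope| / turn-slope / 2, two magnet turns per enzymatic cycle. Burst
   intervals are widened to the enclosing change-point segment; for traces
   that end mid-reaction (tether loss) the window shrinks to the available
   run so partial bursts still register.
6. **alpha/chi.** Net length change across the reaction read off the
   segmentation (first-segment level at reaction start vs last-segment level
   at the end): negative -> alpha (negative supercoils introduced after
   relaxation), else chi. Traces ending more than 30 s before the reaction
   end are left untagged.
7. **Breaks.** Irreversible tether loss: the track ends early while >= 90 %
   of concurrent tracks persist, or the projected length jumps beyond the
   contour length. Break rates inside versus outside activity intervals are
   pooled over molecules; activity time is read off the stored reaction
   segment table (rows with |slope| >= 10 nm/s), which also covers ramps cut
   short by the break itself. The rate ratio's s.d. comes from 30 bootstrap
   resamples over molecules; zero background breaks yields a flagged
   infinite ratio, not an exception.
8. **Dose response.** `Y = Bottom + (Top - Bottom) / (1 + X / IC50)` by
   least squares, CI95 from the parameter covariance; treadmilling cycles
   are rotation rate / 2 x active time.

The acceptance funnel is monotone by construction:
accepted ⊆ single ⊆ coilable ⊆ mobile.

## Synthetic data generator

The generator emulates exactly the features the pipeline is sensitive to:

- **Lateral fluctuations**: exact discrete Ornstein–Uhlenbeck updates with
  stationary variance `k_B T l / F` and relaxation time `gamma l / F`;
  camera blur by averaging equispaced substeps across the frame interval
  (substeps refined to at most `tau/10`). Simulated attenuation matches
  `S(alpha)` to a few percent across `alpha` in [0.1, 3].
- **Supercoiling response**: a phenomenological hat curve. Baseline
  projected length is the WLC extension at the molecule's force times a
  fixed projection factor 3.8/4.4 (constant tether angle ~30 deg). The
  buckling onset grows linearly with force, anchored at 150 turns
  (sigma = 0.075 with Lk0 = 2000) for 6.5 pN overwound; underwound DNA uses
  the same onset below the 1 pN melting force and is flat above it. Beyond
  onset the tether compacts at 50 nm/turn (free parameter; the analysis
  asserts only ratios, i.e. cycles/s). Compaction clips at a 0.2 um floor.
- **Protocol traces** per class: stuck (jitter only), nicked (no turn
  response), multi-tethered (compaction for both coiling senses, any
  force), single (hat-curve response; gyrase kinetics). Gyrase: exponential
  arrival (mean 10 s), relaxation of the remaining +40 turns at
  `2 v_pos` turns/s (default v_pos = 1.26 cycles/s), a 10 s pause, then —
  below 0.5 pN (alpha mode) — introduction of 60 negative turns at
  `2 v_neg` turns/s (default v_neg = 0.65 cycles/s). The 60-turn default
  keeps the negative ramp above the compaction floor for the default force
  distribution, so the alpha/chi sign and break-time attribution stay well
  defined; the remaining-positive-turn default is 40 for the same
  geometric reason (40 x 50 nm = 2 um of head-room under a ~3.8 um
  projected extension).
- **Forces**: lognormal across molecules, median 0.2 pN, log-sd 0.25 —
  single-bead magnetic-content variation; bead clusters, which broaden the
  experimental force spread, are represented by the multi-tether class
  instead.
- **Breaks**: inhomogeneous Poisson with hazard 3e-4 /s during activity
  bursts and 1e-4 /s otherwise in the reaction phase (3x contrast); after a
  break the bead position jumps beyond the contour length for one frame and
  the track ends.
- **Images**: integrated 2-D Gaussian spots (error-function pixel
  integrals), Poisson shot noise, Gaussian background; deterministic per
  seed, byte-identical TIFFs.

Measurement noise is 50 nm (1 s.d.) on positions at 4 Hz; the force window
carries the physical OU fluctuations instead. One child random stream per
molecule is derived from the cohort seed, so cohorts are reproducible and
order-independent. Class assignment is stratified (largest remainder), so
fraction x n is exact.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mechanistic plectoneme/torque physics (the hat
curve is phenomenological), 3-D Brownian motion (x carries white noise, z is
implicit in the projection factor), stage drift and illumination decay
during protocol traces, bead-size dispersion in the optics, enzyme-kinetic
heterogeneity beyond the fixed (v_pos, v_neg, pause) triple, and transient
protein-stabilized break intermediates that hold the tether (only
irreversible tether loss is simulated).

## Problem sizes and determinism

Default study conditions used by the test suite: cohorts of 200 (module
tests) and 1,000 molecules (end-to-end label/velocity recovery), 10,000
molecules in ten seeded batches for the break-rate contrast, 1e5-sample OU
segments for calibration recovery, and 400–500 Monte-Carlo repeats for
localization. All randomness flows through numpy Generators seeded
explicitly; archives written twice from the same seed are byte-identical.

## Known limitations

- The archive reader assumes the file was written by this package (header
  and index layout); arbitrary JSON with the same schema string but
  different layout is rejected rather than parsed leniently.
- The burst detector reports at most one positive and one negative burst
  per reaction (the paper-style maximum-slope summary); repeated bursts
  within one trace fold into the segment table instead.
- The F-test split gate with Bonferroni correction is conservative for
  heavy-tailed noise; confidence is configurable per call.
- Dose–response fitting uses the one-site equation without a Hill slope,
  as printed; strongly cooperative inhibition would be mis-fit.
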