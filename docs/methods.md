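# Methods

`centrotrace` reimplements, as a tested pipeline on synthetic data, a
fluorescent-birthdating analysis of centrosome inheritance in cortical
organoid units: NPCs lining a ventricle-like lumen divide asymmetrically, and
the question is whether the self-renewing daughter preferentially retains the
older centrosome. Tag colour encodes organelle age: before Cre recombination
all Centriolin is tdTomato-tagged (red); after recombination all newly made
Centriolin is NeonGreen-tagged (green), so the only red-containing centrosome
of a recombined lineage is the founder's, and its residual red fades only as
slowly as Centriolin turns over.

## Generative model

State per centrosome: a tagged Centriolin pool `(T, N)` on the mother
centriole and a maturation index (the division at which its mother centriole
matured; founders carry 0).

Per division of a VZ cell, in order:

1. **Turnover.** A fraction `tau` of the resident pool is exchanged for fresh
   protein (green if recombined, red otherwise), so `T + N = L0` always.
2. **Semi-conservative duplication.** The resident (older) centrosome keeps
   its pool and index; the new centrosome receives a fresh load — pure green
   in a recombined cell — stamped with the current division index. A
   centrosome born after recombination therefore has green ratio exactly 1
   for the rest of the simulation.
3. **Asymmetric segregation.** With probability `p_asym` the VZ-remaining
   daughter keeps the older centrosome; the other daughter exports its
   centrosome, leaves the VZ and never divides again. `p_asym = 0.9` is the
   wild-type-like default; `0.5` models Ninein-knockdown-like randomisation.

Optional fate coupling (`q_diff`, default 0): a VZ daughter that inherited
the younger centrosome converts to a differentiating CTIP2 fate with
probability `q_diff` and the lineage stops. This emulates the observation
that randomised inheritance depletes SOX2-positive progenitors; it is off by
default because the coupling strength is not quantified.

Default study conditions (one "study" mirrors one experiment): 22 cortical
units, 12 founder lineages per unit, recombination fraction 0.4, `n_div = 6`
divisions after induction (a discrete stand-in for ~22 days; division count
is a free parameter, not asserted), `tau = 0.05` per division (chosen so the
founder centrosome shows visibly mixed red/green after ~6 divisions, matching
the qualitative observation of slow turnover), `L0 = 1`.

## Geometry and rendering

Each unit is a ring: apical (VZ) centrosomes on the lumen wall
(radius 40 px ± 2 px) at jittered, uniformly-phased home angles — consecutive
slots at least half a slot apart so the ring is dense but collision-free, with
an exactly uniform pooled angle distribution — and progeny placed in the same
angular sector at radii uniform in (lumen + VZ thickness, tissue radius] =
(100, 150] px. Scenes are 512×512, two channels (1 = tdTomato,
2 = NeonGreen), each punctum an isotropic Gaussian (sigma 2 px, evaluated at
pixel centres within a 6-sigma window; truncation error < 1e-7 relative),
amplitude `gain × load` over a constant background, optional Poisson shot
noise then Gaussian read noise, written as 16-bit TIFF with clipped-pixel
counts logged. Imaging settings are arbitrary defaults (no pixel size or
objective is being emulated). The standard fixture enforces a 12 px minimum
separation between progeny so detection can be benchmarked on isolated
puncta.

## Image analysis

- **ROI geometry.** Analysis circle centred on the ventricle midpoint with
  radius `min(3 × VZ thickness, tissue radius)`. The wedge over a recombined
  cluster is bounded by the chord between the cluster ends, two rays leaving
  the chord ends at 45° opening outward (the radial line through the chord
  midpoint only orients "outward"), and the circle arc. The VENT band is
  `|r − lumen_radius| ≤ wall_tolerance` with `wall_tolerance` defaulting to
  half the VZ thickness — the original criterion is visual, so the band is a
  configuration knob. The default pipeline analyses the whole circle (the
  simulated ring has no single privileged cluster); the wedge is available
  for user-driven analyses of annotated scenes.
- **Detection.** Scale-matched Laplacian-of-Gaussian on the channel-sum
  image, median-centred (the truncated kernel does not sum exactly to zero),
  thresholded at `k × MAD` of the response (`k = 5`); on noise-free images a
  relative floor (0.5% of the peak response) suppresses quantisation ripple.
  Raw maxima closer than `min_sep = 3 sigma` collapse into one detection
  flagged as a merge. Sub-pixel positions by iterative windowed centroid.
  Detections whose aperture total falls below 25% of the scene maximum are
  discarded: total Centriolin load is conserved in the model, so genuine
  centrosomes share a narrow total-intensity band and sub-threshold specks
  are noise.
- **Photometry.** Per channel, mean of a 3-sigma aperture minus the median of
  a 1.5–2.5 aperture-radius annulus (median resists neighbouring puncta).
  Negative means are clamped to zero and flagged so ratios stay in [0, 1].
- **Recombination call.** NeonGreen above 3 × the channel-2 background MAD.
  TABLE mode (ground-truth intensities) uses the simulator's flag.

## Classification

The age statistic is the green ratio `r = N / (T + N)`. Two schemes, both
per image (per unit): the **tertile** split sorts recombined centrosomes by
`r` descending (stable tie-break on input order) and assigns the first
`ceil(n/3)` GREEN, the next `ceil((n − n_green)/2)` YELLOW, the rest ORANGE,
so group sizes never differ by more than one; the **manual** scheme calls
ORANGE when tdTomato is within `c1 = 2` MADs of the unrecombined reference
location, GREEN when tdTomato is below its detection floor, YELLOW between,
and refuses to run on fewer than three unrecombined reference centrosomes.

The pipeline processes each unit's puncta in angular order around the
ventricle centre. This pins the tertile tie-break (exact ties at ratio 1 are
common, because every post-recombination centrosome is pure green) to a
quantity that is identical between TABLE and IMAGE modes and carries no
region information, which is what makes the two modes agree exactly on
noise-free scenes.

## Statistics and inference

Counts are tallied per (unit, region, colour); the unit of replication is
the cortical unit. Per-colour comparisons of per-unit proportions use the
unpaired two-sample Student t-test (pooled variance, as in the original
analysis; Welch behind a flag; no multiple-testing correction, matching the
per-comparison reporting). Zero pooled variance with equal means returns
t = 0, p = 1.

`estimate_asymmetry` recovers `p_asym`. For `n_div = 1` the
method-of-moments estimate is the fraction of oldest-class (ORANGE)
centrosomes on the ventricular wall — exact at p ∈ {0, 1}. For deeper
lineages, a grid search over p (step 0.02) minimises the L2 distance between
the observed and model-simulated region-by-colour composition at matched
`tau` and `n_div`. The reference compositions are simulated once per call
with common random numbers across the grid (600 reference units), so the
curve is smooth in p and reference Monte-Carlo error is shared rather than
independent per grid point; reference size is chosen so that reference noise
is small against sampling noise at 50 observed units. Confidence intervals
are percentile bootstrap over cortical units (300 resamples). Identifiability
is asymmetric: the observable footprint of p is dominated by the founder
retention probability `p^n_div`, which is flat for small p, so intervals at
p ≈ 0.5 are wide (≈ ±0.2 at 50 units) while p ≈ 0.9 is pinned to ±0.02.

## Known limitations

- **Discrete tag model.** Because new centrosomes are born pure green, the
  recombined ratio distribution is a point mass at 1 plus one founder per
  lineage. The yellow tertile class is therefore an artefact of forced
  thirds rather than a genuine intermediate-age population, unlike real
  centrosomes whose ratios form a continuum.
- **Export accumulation.** Progeny never divide and their pools freeze, so
  old centrosomes accumulate outside the VZ even under randomised
  inheritance: the founder stays in the VZ with probability `p^n_div`
  (1.6% at p = 0.5, n_div = 6), far below the 1-in-7 share a fully
  exchangeable null would give. Consequently the vent-vs-nonvent comparisons
  are *not* exchangeable at p = 0.5 under this model — ORANGE remains
  significantly nonvent-enriched at the randomised setting, and YELLOW
  differs significantly at p = 0.9 because founders crowd out the vent
  yellow share. The package reports these directions faithfully; a model
  with continuing turnover or dividing progeny would be required to obtain a
  non-significant randomisation null.
- Passing tests on this generator show the pipeline's bookkeeping and
  statistics are correct under the stated model; they do not certify
  performance on real microscopy (no autofluorescence gradients, z-stacks,
  chromatic shift, bleaching, or segmentation of the ventricle itself, which
  is taken from the annotation as in the original manual workflow).
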