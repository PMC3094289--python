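# Methods

`pscarbor` is a synthetic twin of a quantitative single-neuron morphometry
study. The biological object is the posterior scutellar (pSc)
mechanosensory neuron of *Drosophila*, whose axon enters the thoracic
ganglion through a stereotyped mesothoracic nerve and elaborates a
branched terminal arbor. The study quantified, per animal and genotype:
the number of axonal branches (only branches longer than 4 μm count),
the total arbor length normalized to the width of the ganglion, the
number of axonal varicosities (putative synaptic boutons), the frequency
of axon guidance errors (entry through the posterior, metathoracic
pathway), and a "core skeleton" of branches present in more than 80% of
wildtype animals. Because no raw images were deposited, every pipeline
stage here runs on synthetic data whose cohort statistics are calibrated
to the published mean ± SEM values, and the package's claim is that the
*computations* — not the biology — are reproduced end to end.

## The skeleton template

The wildtype template (`data/wildtype_template.tsv`) has 16 branches.
Each row fixes a branch's parent, attachment fraction along the parent's
arc length, unit initial heading, mean length, length SD and per-animal
presence probability. Mean lengths span 13–151 μm (the published range);
per-branch SDs default to 20% CV because the source figure marks
variability without printing numbers, and they are user-overridable
through the template file. Presence probabilities are set to 0.98 for
all non-root branches (the trunk is always present): each branch must
individually clear the >80% consensus rule with margin in a 21-animal
cohort, and values much below ~0.95 make the 16-branch consensus
unstable against matching noise. The 2-D layout was chosen so that no
two non-adjacent branches approach within ~8 μm in projection; child
headings depart at least ~30° from their parents. Both properties are
what make rendered arbors traceable: closer passes bridge in the
thresholded mask, and shallower departures defeat the collinearity rule
used to follow a branch through junctions.

## Generative model and calibration

A `GenotypeConfig` carries the published targets (mean ± SEM of branch
count, total length, varicosity count at the published cohort size) plus
three packaged phenotype rates: the guidance-error probability (the
published frequency), a routing-error probability, and a skeletal
presence scale. For the PlexB-knockdown genotypes the presence scale is
0.843, the value at which the expected number of missing skeletal
branches against the wildtype template exceeds the control's by 3.3 (the
published skeletal loss); the PlexA-knockdown routing rate 0.1375 makes
the expected 8.6-variable-branch excess decompose into the branch-count
difference (6.6) plus two misrouted skeletal branches per arbor.

`calibrate_config` moment-matches the free parameters deterministically:

* variable-branch count: `max(0, round(Normal(μ, σ)))` with μ solved so
  the expected branch count equals the target exactly (the skeletal
  expectation is computed exactly over the presence tree, including
  parent–child inclusion dependence), and σ solved so the per-arbor
  branch-count variance equals `n·SEM²`. A counting family was needed
  whose variance can be far *below* Poisson: several genotypes print
  SEMs implying count SDs of ~1.4 where a Poisson mean of ~7 would give
  ~2.7. A fractional mean imposes a variance floor of `frac·(1−frac)`.
* global length scale on skeletal branches, solved so the expected total
  length (skeletal plus variable, variable mean length fixed at 25 μm)
  equals the target; a per-animal lognormal size factor (mean 1) absorbs
  the remaining length variance up to `n·SEM²`.
* varicosities: a hard-core point process along each branch (minimum gap
  4 μm, keeping swellings optically separable at the default optics;
  4.5 μm margins from branch ends and junctions, where detection is
  blind) with per-branch Poisson counts at density ρ·h, where h is a
  per-animal gamma multiplier (mean 1) whose variance is solved from the
  heavily overdispersed printed varicosity SEMs. Because the hard-core
  rule drops a density-dependent fraction of draws on crowded branches,
  ρ is calibrated against the *placed* expectation with a short internal
  Monte-Carlo (fixed seed derived from the genotype name, so calibration
  stays deterministic); the retention fraction is stored on the config.
  In the extreme upper tail of h the placement saturates at the packing
  capacity, so realized dispersion is slightly below the printed SEM for
  the highest-dispersion genotypes — means are unaffected.

Calibration raises a named infeasibility error when targets cannot be
reached (branch target below the skeletal floor, or a length scale
outside (0.2, 3)). `sample_arbor` refuses configs whose stored
expectations drift more than 5% from their targets.

Geometry at sampling time: attachment fractions jitter by SD 0.02,
headings by SD 6°, branches curve by a linear heading drift of SD 5°
over their length. Variable branches attach to skeletal branches with
probability proportional to length, at uniform arc positions, departing
35–110° from the local parent heading; placements are
rejection-sampled (up to 25 candidates) to keep ≥7 μm projected
clearance from existing geometry, falling back to the best-clearance
candidate in crowded arbors. Misrouted skeletal branches rotate their
heading by 60–120° (sign random), likewise choosing among candidate
rotations for clearance. Guidance errors relocate the entry annotation
130 μm posteriorly into the metathoracic band; the arbor geometry itself
is left in place — entry-pathway classification needs only the entry
point, and the within-ganglion morphometry of misguided axons is not a
quantity the study reports. The whole arbor is finally scaled by the
animal's ganglion width (Normal(180, 9) μm) over the 180 μm reference,
which downstream normalization inverts.

## Rendering

Branches are drawn on a 0.5 μm/px grid as tubes with Gaussian
cross-section (FWHM = 1.5 μm) via a distance transform of the rasterized
centerline; varicosities add Gaussian blobs of their diameter (3.3–4.5
μm) and intensity gain (2–3×). Each branch receives a Gaussian focal
profile across the 16 z-slices, slices are blurred with a σ = 0.6 μm
PSF, and Gaussian noise (SD 8) is added over a background of 10.
Intensity per pixel scales with pixel area (photon integration), which
keeps tracing stable when the pixel size changes at fixed optics. The
two-channel IHC renderer draws a random fiber field (structural,
MAP1B-like channel) and punctate signal along the same fibers whose
amplitude scales linearly with the expression level; all random
structure is drawn before the expression scaling, so the structural
channel is bit-identical across expression levels at a fixed seed.

## Tracing

The traced quantities come from maximum-intensity projections, mirroring
the projection-based manual analysis the study describes. Operators, in
order: three-class Otsu threshold (lowest cut) with a robust sanity band
of background + 2–6 noise σ (the histogram cut can land in the noise
floor or above the axon when bright varicosities dominate); largest
connected component; morphological skeletonization; an 8-connected
pixel graph whose cycles (crossings) are broken at the lowest-intensity
edge via a maximum spanning tree, flagged in the result; spur pruning
below 3.8 μm; rooting at the skeleton endpoint nearest the recorded
entry point. Paths between topological nodes become branches, and at
each junction the straightest continuation (turn below 55°) extends the
incoming branch so that branches run *through* junctions, matching the
generator's granularity; internal branches shorter than 6 μm between two
junctions are collapsed as bridge artifacts. Polylines are smoothed with
a 5-sample moving average before arc length is measured, removing the
~8% staircase inflation of 8-connected chains.

Varicosity detection implements the two-factor rule — wider than the
axon and brighter than the axon — with explicit operators: every 0.5 μm
along each branch (outside a 2.5 μm junction radius and a 3.5 μm radius
around any *other* branch's centerline, where a neighbour's halo mimics
a swelling) the perpendicular intensity profile is sampled; the width is
the symmetric bright span about the centerline at a fixed reference
level (half the typical on-axon amplitude), so one-sided widening at
junction arms does not trigger; the references are lower-quartile
statistics, robust to arbors so dense with varicosities that a median
would track the swellings themselves. Local intensity maxima at least
2 μm apart that exceed 1.5× the reference width *and* 1.5× the reference
amplitude are detections.

## Morphometry, consensus, statistics

Normalization multiplies coordinates by `reference / ganglion_width`
(default reference: the cohort mean width) before the strictly-greater
4 μm branch filter; filtering is idempotent because the scaled tree
records the reference as its own width. Normalize-then-filter order is
fixed by config only in the sense that the filter always sees scaled
lengths; the study does not state its order, and this reading is
documented rather than guessed.

Branch correspondence uses a four-term descriptor distance (attachment
fraction /0.1, topological depth, heading angle /60°, |log length
ratio| /0.45, weights 1, 1, 1, 0.5) and optimal one-to-one assignment.
Assignability is gated on the non-direction terms (≤ 0.8): a branch that
matches in position, depth and length but points the wrong way is
assigned and flagged as a routing error — excluded from the skeletal
count, counted as variable, its template slot counted missing, which is
the counting convention the study's skeletal-loss and variable-branch
numbers imply. Consensus building iterates match/re-estimate rounds from
a first-arbor initialization, absorbs near-duplicate working entries
(cost < 1.1) that would otherwise split one branch's frequency across
clones, prunes at strictly >80% presence, and then iterates a final
re-match on the pruned template to a fixed point, which removes the
initialization dependence except when a frequency sits exactly at the
16-vs-17-of-21 boundary.

The statistical battery is deliberately plain: two-sided Mann–Whitney U
(exact by full enumeration for n₁+n₂ ≤ 12, handling ties; tie-corrected
normal approximation otherwise), two-sample Kolmogorov–Smirnov on raw
per-arbor totals (the histogram is display only), 2×2 χ² without
continuity correction (flagged when expected counts are small — several
guidance-error comparisons have tiny counts), one-way ANOVA with
Bonferroni-adjusted pairwise t comparisons (`p_adj = min(1, m·p)`), and
summary rows as mean ± SEM (SD/√n). ROI quantification integrates
background-subtracted (projection median) intensities of four 20×20 μm
ROIs sampled inside the structural channel's foreground, reporting the
signal/structural ratio mean ± SD across ROIs.

## Problem sizes and determinism

The fast (ground-truth) path samples full published-size cohorts
(n = 10–42) in milliseconds per arbor; replicated recovery checks use
40–100 cohort replicates per genotype and the imaging-path check renders
the wildtype and PlexA-knockdown cohorts once. All randomness flows
through explicit `numpy` generators; a run manifest plus seed reproduces
byte-identical SWC files and summary CSVs.

## What passing tests do and do not show

The generator emulates cohort-level statistics and the geometric
stereotypy of the arbor; it does not emulate real image pathology —
uneven staining, out-of-focus haze, dissection damage, overlapping
fascicles — and its varicosities are ideal Gaussian blobs with a
resolvability floor built in. Recovery of the published cohort means
through rendering and tracing therefore validates the internal
consistency of the pipeline (generator, renderer, tracer and
morphometry agree about what a branch and a varicosity are), not the
tracer's performance on real micrographs. Two further limitations are
known and deliberate: per-arbor branch-count recovery is exact to ±1 in
only ~two-thirds of arbors (short-trunk draws crowd junctions until
projected masks bridge; cohort means stay within 10%), and for the
highest-dispersion genotypes the realized varicosity variance sits
slightly below the printed SEMs because counts saturate at the packing
capacity of the arbor.
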