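# Methods

`hdmorph` reimplements, as a tested pipeline, the histomorphometric
comparison of paired aganglionic and ganglionic bowel segments in
Hirschsprung's disease: layer-thickness measurement from manually
delineated boundary contours, two derived ratios, a two-criterion paired
diagnostic algorithm, and the paired cohort statistics. Because the
original histology slides are not publicly available, the pipeline is
exercised end to end on a synthetic tissue phantom whose statistical
structure follows the published cohort summaries.

## Contour measurement model

A specimen cross-section is a set of boundary polylines in planar µm
coordinates, closed rings for a full circumference or open arcs where only
part of the specimen could be delineated. Each histoanatomic layer —
mucosa, submucosa, muscularis propria interna (circular muscle), myenteric
tissue layer, muscularis propria externa (longitudinal muscle), and the
full wall — is a pair of inner (luminal-side) and outer boundaries.

**Sampling.** The inner boundary is resampled at fixed arc-length
intervals, 14 µm by default (exposed as `spacing`). On a closed ring the
nominal interval is adjusted to the nearest value that divides the
perimeter evenly (`floor(L/s)` samples), so samples are strictly uniform;
on an open arc samples sit at 0, s, 2s, … with the final sample on the end
point. Tangents come from central finite differences of the resampled
polyline.

**Thickness.** The original measurement software's point-wise definition is
not published; we define the thickness at each sample as the length of the
ray cast along the local inward-to-outward normal from the inner boundary
to its first intersection with the outer boundary. This matches the visual
of radial measurement lines on delineated sections and remains well defined
on folds. On closed delineations, a ray that misses the outer ring (possible
at high curvature) falls back to the nearest-point distance and is flagged
(`n_fallback`); on open arcs such rays exit through the end caps and are
discarded instead. Whether the original software anchored measurements on
the inner boundary, the outer boundary, or a midline is unknowable from the
published figures; the luminal side was chosen and fixed.

**Summaries.** Per layer: mean and sample SD of the per-sample thicknesses,
the polygon area between the boundaries (ring difference when closed;
inner path + end caps + reversed outer path when open), the two boundary
arc lengths, the valid sample count, and an estimated coverage fraction
(angular span of an open arc about its least-squares fitted circle center).
Inputs are in µm; all reported lengths are mm, areas mm²; rounding to three
decimals happens only when tables are written.

Two derived features per specimen:

* **muscularis interna / externa ratio** — ratio of the two muscle-coat
  mean thicknesses, the cohort's key discriminative feature;
* **submucosal folding ratio** — inner / outer submucosal boundary length.
  The pleated luminal-side boundary is the numerator, so published cohort
  values near 1.1 mean the folding more than compensates the geometric
  deficit of the inner radius (a smooth annular submucosa would score
  r_in/r_out < 1).

The full wall is measured from its own innermost/outermost boundary pair,
never by summing layer means; on nested boundaries sampled along shared
rays the two agree (enforced by a test).

## Diagnostic algorithm

Within one patient, the aganglionic segment is predicted by two relative
criteria: (I) thinner muscularis interna; (II) lower interna/externa
ratio. No absolute cut-offs are used — reliable cut-off values have not
been validated, so the comparison is strictly pairwise. Exact feature
equality yields a tie on that criterion. Cohort evaluation reports
per-criterion correct counts and the *either-criterion* count (a pair is
correct when at least one criterion points at the truly aganglionic
segment), which is the retrospective counting used when the criteria are
validated against known labels. For prospective use, where labels are
unknown and the criteria may disagree, `classify_pair` requires an explicit
resolution policy: `ratio_priority` (default — the ratio criterion was the
more reliable of the two in the source cohort), `mi_priority`, or
`abstain`.

## Paired statistics

Patients serve as their own controls; each feature is compared by a paired
t-test on within-patient differences, with the sign convention *difference
= aganglionic − ganglionic* (so a thicker ganglionic interna gives a
negative difference). Confidence intervals are d̄ ± t_{n−1,(1+level)/2}·s/√n
and can be recomputed from printed summary statistics
(`ci_from_summary`, `paired_t_from_summary`). Pearson correlations (with
t-based two-sided p) relate full-wall thickness to weight and age at
surgery. Features missing in either segment of a patient drop that patient
from that feature's row only; rows with fewer than two complete pairs are
marked not computable, and zero-variance differences are flagged degenerate
rather than tested. An informational Shapiro–Wilk p-value of the
differences is attached to each row; no multiple-testing correction is
applied across rows, matching the source analysis.

The inclusion flow filters a patient registry on: age at surgery ≤ 1 year,
no prior stoma, primary surgery, aganglionic segment ≤ 25 cm, adequate
image quality — applied in that order, with a record failing several
criteria tallied once under its first failure (the attribution rule for
multi-criterion failures is not published; first-failing was fixed here).

## Synthetic cohort generator

The generator defines the study conditions for every simulation in the
package; its defaults are the published cohort summaries and are not tuned
per experiment.

**Feature level.** For each patient and layer, the aganglionic thickness is
drawn Normal(μ_A, σ_A) truncated below, the within-patient difference
Normal(μ_d, σ_d), and the ganglionic value is their difference (same
floor). The truncation floor is 0.05 mm, except the myenteric tissue layer
(cohort mean 0.018 mm, an order of magnitude thinner than every other
layer) which uses 0.002 mm. Truncation slightly raises the realised
myenteric mean (≈0.024 vs 0.018 mm); other layers are essentially
unaffected.

The two muscle coats need a joint model: the diagnostic ratio's variance
depends on their within-specimen correlation, which per-layer summary
statistics do not identify. Under the default `mi_me_model="ratio"`, the
muscularis interna *and the interna/externa ratio* — the two diagnostic
features — are drawn as independent paired features at their published
means/SDs (interna 0.461 (0.130), difference −0.205 (0.138); ratio
1.287 (0.356), difference −0.760 (0.521)), and the externa is derived as
interna/ratio. This reproduces both diagnostic feature distributions
exactly and makes the two criteria fail independently, matching the
disjoint criterion failures reported for the source cohort; the cost is
that the externa's induced marginals are approximate (mean ≈ 0.39 vs 0.40
mm; difference SD ≈ 0.23 vs 0.20). The alternative
`mi_me_model="independent"` draws both coats at their published marginals
and derives the ratio — but nothing then ties a thick interna to a thick
externa, the derived ratio becomes far more dispersed than the cohort's
(SD ≈ 1.2 vs 0.356), and the two criteria fail together; it is kept as an
explicit sensitivity mode, not the default. The folding ratio is drawn with
the same paired structure (1.101 (0.203), difference 0.021 (0.222)). An
optional shared per-patient scale factor (`patient_scale_sd`, default 0)
can induce between-layer correlation.

**Geometry level.** A specimen is built outward from a lumen
r(θ) = R₀(1 + ε·g(θ)), with R₀ drawn per patient (default 1500 ± 200 µm —
an infant rectosigmoid calibre), g a smooth low-order-harmonic perturbation
of unit peak amplitude, and ε = 0.03 by default. Each successive boundary
offsets the previous one outward along its local normals by the drawn layer
thickness. The submucosal inner boundary is additionally pleated radially by
A·sin(kθ), k = 40 folds per circumference and A a fixed fraction of the
boundary radius — 0.0344 (aganglionic) and 0.0311 (ganglionic), calibrated
once so the *measured* folding ratio of a mean-parameter specimen lands on
the cohort values (1.101 / 1.080). This is a calibration of the phantom,
not an inference about tissue. Emitted contours are checked simple and
strictly nested; offsets that would self-intersect raise an error advising
a smaller amplitude, and the cohort generator retries such specimens with
progressively reduced pleat amplitude (a thin submucosa cannot fold
deeply).

Pleating tilts the local normals of the pleated boundary, so
boundary-anchored normal rays cross the submucosa obliquely and measure
systematically more than its radial extent (≈ +30 % at the calibrated
amplitude) — exactly as they would on a real pleated specimen. The
generating submucosal thickness is therefore defined as the *measured*
mean: the radial gap is calibrated downward per specimen by a three-step
secant iteration against the package's own ray measurement at the same
14 µm spacing. One consequence is that the measured full-wall thickness of
a folded phantom sits below the sum of the generating layer thicknesses by
the same offset; parameter-recovery checks accordingly target the five
generated layers, with the full wall validated separately on unfolded
co-sampled geometry where additivity is exact.

**What the phantom is not.** It is geometric: no staining or texture, no
transition-zone gradients along the bowel, concentric layers by
construction, one cross-section per specimen, and (by default) no angular
thickness variation within a layer (an optional `thickness_wobble` exists).
Passing tests on the phantom therefore validate the measurement, inference
and classification machinery — not the biological claims, which would
require real delineations.

**Registry.** The registry generator emits records that each fail exactly
one named inclusion criterion, plus passing records with covariates drawn
around the cohort descriptives (age log-normal with median 34.5 d and
log-SD 0.73, chosen to match the published median/mean pair 34.5/45.2;
weight Normal 4.3 ± 0.7 kg; aganglionic length Normal 11.6 ± 5.5 cm clipped
to 25 cm).

## Numerical choices

* Contours must have ≥ 3 distinct vertices, finite coordinates, no
  consecutive duplicates; closed contours must be simple, and a closed
  inner boundary must lie strictly inside its outer boundary.
* Ray/segment intersection is fully vectorised (all samples × all
  segments); hits within 10⁻⁶ µm of the origin are ignored; the first
  (smallest-t) crossing wins.
* Sample SD uses ddof = 1; a single-sample layer reports SD 0.
* Default test-problem sizes: 2048 boundary vertices per contour, cohorts
  of n = 30 patients, 10⁴ replicates for coverage checks, 10³ cohorts for
  classifier simulations.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the parameter objects; identical seeds give bit-identical outputs, and
  run logs record parameters, versions and seed without timestamps so
  reruns are byte-identical.

## Known limitations

* The thickness definition (inner-boundary-anchored normal rays) is one of
  several defensible readings of the original semi-automated measurement;
  alternatives (outer-anchored, midline) would differ on curved or folded
  layers.
* Open-arc coverage estimation assumes a roughly circular specimen; deeply
  non-circular arcs get a rough estimate (the value is informational).
* The generator draws layers independently across patients and layers;
  real bowel walls correlate between layers and along the bowel axis, so
  cohort-level SDs of derived quantities (e.g. full wall) run below the
  published ones.
* The externa's marginals under the default muscle-coat model are
  approximate, as described above.
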