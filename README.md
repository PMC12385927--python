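# hdmorph

Histomorphometry of paired bowel-wall specimens in Hirschsprung's disease
(HD). In HD the distal bowel lacks enteric ganglion cells and must be
resected; distinguishing aganglionic from ganglionic bowel quickly during
surgery is the clinical problem behind this analysis. `hdmorph` provides a
tested reimplementation of the histomorphometric pipeline that compares the
two segment types within each patient:

* **contour morphometry** — layer thickness sampled every 14 µm along
  manually delineated boundaries by normal-ray casting, plus per-layer
  mean/SD, area, boundary lengths, the muscularis interna/externa
  mean-thickness ratio and the submucosal folding ratio
  (inner/outer submucosal boundary length);
* **a paired diagnostic algorithm** — within a patient, the segment with
  (I) the thinner muscularis interna and (II) the lower interna/externa
  ratio is predicted aganglionic, evaluated with per-criterion and
  either-criterion counting;
* **paired statistics** — per-layer paired t-tests with confidence
  intervals (difference = aganglionic − ganglionic), Pearson correlations
  of full-wall thickness with weight/age at surgery, and the cohort
  inclusion/exclusion flow;
* **a synthetic phantom generator** — paired cross-section geometry and
  feature tables whose distributions follow the published cohort summaries
  (muscularis interna 0.461 (0.130) mm aganglionic vs 0.666 (0.177) mm
  ganglionic; difference −0.205 (0.138) mm), so the whole pipeline runs and
  is tested without access to histology slides.

The core statistic per feature is the paired t-test on within-patient
differences d_i: t = d̄/(s_d/√n) with n−1 degrees of freedom and
CI = d̄ ± t_{n−1,0.975}·s_d/√n.

## Worked example

The numbered scripts under `analysis/` run the study workflow on a
simulated cohort (each step writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py    # 30 paired specimens + registry
python analysis/02_measure_layers.py     # contour measurement at 14 µm
python analysis/03_cohort_statistics.py  # paired tests, correlations
python analysis/04_diagnostic_algorithm.py
python analysis/05_patient_flow.py       # 49-record inclusion flow
```

Output of one run (seed fixed in the scripts):

```
measured 60 specimens at 14 µm intervals
muscularis interna mean: aganglionic 0.403 mm, ganglionic 0.581 mm
muscularis interna: diff -0.178 mm (CI -0.228 to -0.127), p = 7.02e-08, ganglionic greater in 26/30
full wall vs weight (aganglionic): r = -0.172, p = 0.363
criterion I (thinner interna) correct: 26/30
criterion II (lower ratio)    correct: 29/30
either-criterion accuracy: 29/30 = 97%
registry: 49 patients ... included: 30
```

Read: in this simulated cohort the ganglionic segment's circular muscle
coat is systematically thicker (paired difference −0.178 mm, CI excluding
zero, p ≪ 0.001), full-wall thickness shows no weight correlation, and the
two-criterion algorithm identifies the aganglionic segment in 29 of 30
patients because the criteria fail on different patients. Single-cohort
counts fluctuate: across 1000 simulated cohorts at these effect sizes,
≥29/30 either-criterion accuracy is reached in ≈99 % of cohorts.

The same steps are available as a CLI (`hdmorph simulate | measure |
classify | cohort-stats | patient-flow`) for GeoJSON/CSV contour files and
feature tables; every subcommand writes a machine-readable run log.

A minimal library session:

```python
from hdmorph import ci_from_summary, paired_t_from_summary

ci_from_summary(-0.205, 0.138, 30)   # -> (-0.2565, -0.1535)
paired_t_from_summary(-0.205, 0.138, 30).p   # -> 5.7e-09
```

## Layout

```
src/hdmorph/      geometry.py  contour measurement and derived ratios
                  classify.py  paired two-criterion diagnostic algorithm
                  paired_stats.py  paired tests, correlations, cohort flow
                  simulate.py  synthetic phantom and registry generator
                  io.py, cli.py  GeoJSON/CSV interchange, configuration, CLI
analysis/         numbered narrative drivers (see worked example)
docs/methods.md   measurement model, generator assumptions, limitations
tests/            unit, property and end-to-end suites
```
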