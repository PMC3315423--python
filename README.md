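# morphrel

Reliability analysis of multi-site, test–retest brain morphometry.

When the same subjects are scanned repeatedly on several MR scanners,
the morphometric measures derived from those scans — grey-matter (GM),
white-matter (WM) and CSF volumes, cerebral hemisphere volume, the
global sulcal index (GSI), and sulcus-wise surface area and geodesic
depth — vary not only between subjects but also between centres
(scanners) and between visits to the same scanner. In cross-sectional
and multicentre studies this scanner-related variability can swamp the
biological differences of interest. `morphrel` quantifies it, for
anyone running or evaluating a multicentre structural-MRI study.

## What it computes

For each measure on a fully crossed design (every subject scanned at
every centre and visit, hemispheres as within-cell replicates), the
crossed random-effects ANOVA

    y_scvh = μ + A_s + B_c + C_v + AB_sc + AC_sv + BC_cv + ABC_scv + ε_scvh

is decomposed into variance components σ²_T by the method of moments
(expected-mean-squares equations; REML via statsmodels is available for
unbalanced data). The reliability of factor F ∈ {centre, visit} is

    reliability(F) = (V_total − V_F) / V_total,

where V_total is the sum of all components and V_F sums the components
of F and every interaction containing F. A value of 1 means the factor
contributes nothing to the total variance; 0 means it is the only
source. Values are graded poor (< 0.50), moderate (0.50–0.70), good
(0.70–0.90) and excellent (≥ 0.90).

Alongside the decomposition:

* **ANCOVA scanner-effect tests** — fixed-effects F tests of centre,
  visit and centre×visit with a subject factor and brain-volume (and,
  for sulcal measures, GSI) covariates;
* **derived measures** — hemisphere volume as GM+WM+CSF, and the
  buried-cortex fraction GSI/(1+GSI);
* **bias-correction quality metrics** — within-mask coefficient of
  variation and WM/GM histogram-peak contrast on NIfTI volumes, with
  mask intersection to compare segmentation programs fairly;
* **synthetic generators** — morphometry tables with known variance
  components and 3-D tissue phantoms with noise and a multiplicative
  bias field, so the whole pipeline is testable without scan data.

## Worked example

Simulate the 13 subjects × 3 centres × 2 visits × 2 hemispheres design
with variance components (subject 9, centre 1, visit 0.25,
subject×centre 0.5, residual 1) plus fixed centre offsets of 0, +4 and
−4 cm³, and analyse GM volume:

```python
import morphrel as m

params = m.TableSimParams(seed=42, fixed_centre_shifts=[0.0, 4.0, -4.0])
table, truth = m.simulate_morphometry(params)
frame = table.analysis_frame("gm_volume")

print(m.f_test_effects(frame, m.ModelSpec()).round(4))
vc = m.estimate_variance_components(frame)
for factor in ("centre", "visit"):
    r = m.reliability(vc, factor)
    print(f"between-{factor} reliability: {r.value:.2f} ({r.grade})")
```

prints

```
                      F  df_num  df_den  p_value  significant
effect
centre        1085.7695       2     138   0.0000         True
visit            0.5485       1     138   0.4602        False
centre:visit     0.2716       2     138   0.7625        False
between-centre reliability: 0.29 (poor)
between-visit reliability: 1.00 (excellent)
```

The injected centre offsets are picked up twice: the ANCOVA flags a
highly significant centre effect (visit and the interaction stay null),
and the between-centre reliability collapses to 0.29 because the fixed
offsets inflate the centre variance component (33.99 here against a
subject component of 12.60), while the between-visit reliability stays
excellent. Without the offsets the analytic reliabilities implied by
the generating components are 0.87 (centre) and 0.98 (visit), returned
in `truth["analytic_reliability"]`.

The same analysis runs from the shell on CSV tables
(`morphrel analyze --config config.yaml`), and `morphrel simulate
table|phantom` / `morphrel image-metrics` cover the generators and the
image metrics; see `morphrel --help`.

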