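# rkt — robotic knee-testing analysis

`rkt` analyses torque–rotation recordings from instrumented knee-laxity
testing, in which a servomotor rotates the tibia between −6 and +6 N·m of
axial torque while an electromagnetic tracker records motion in all six
degrees of freedom. It is written for biomechanics and sports-medicine
researchers who need to turn such recordings into interpretable joint-laxity
measures and to quantify how repeatable those measures are across test days.

The package provides, end to end:

* a **synthetic cohort generator** that emulates the device protocol
  (±6 N·m torque-limited sweeps, three cycles with four external and three
  internal rotations, sensor noise at the tracker's static accuracy) with
  known ground-truth curve features and a known nested variance structure;
* **curve feature extraction** from the load-deformation curve;
* **test–retest reliability**: ICC(2,1), SEM, MDC90, and pointwise
  ("simple functional") reliability curves along the torque grid;
* **nested variance decomposition** of each feature into subject,
  knee-within-subject, day and residual components;
* **group comparisons** (left vs right knee, female vs male) with a
  Shapiro–Wilk normality gate and post-hoc power.

## The model

A test cycle yields a load-deformation curve: torque τ (N·m) against tibial
axial rotation θ (degrees), monotone increasing under the sign convention
that external rotation is negative. Its features are the maximal rotations
at the torque limits, the rotation at zero torque, and two *turning points*
that separate a compliant play region from the stiff end regions. Each half
of the curve (split at the zero-torque rotation) is fitted with a cubic
τ(θ), and the turning point is where the fitted slope dτ/dθ crosses
1 N·m/degree. From the turning points:

* **slack** = θ_tp,IR − θ_tp,ER  (rotation across the play region),
* **ER laxity** = θ_tp,ER − θ_max,ER,
* **IR laxity** = θ_max,IR − θ_tp,IR,

so that ER laxity + slack + IR laxity equals the total rotation range.

Reliability of a units × days matrix *y* uses the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation

    ICC(2,1) = (BMS − EMS) / (BMS + (k−1)·EMS + k·(TMS − EMS)/n),

and each feature is decomposed with the nested mixed model

    y_skd = μ + β·I(knee = R) + a_s + b_sk + c_sd + ε_skd,

with SEM = √var(ε) and MDC90 = 1.65·√2·SEM. The generator draws realized
features from exactly this model and maps them onto a piecewise
linear-plus-exponential torque curve, so every estimator can be validated
against known truth.

## Worked example

Simulate a 25-subject × 2-knee × 5-day reliability cohort at the package's
default nested variance scales and summarise each curve feature:

```python
import numpy as np
from rkt.config import GeneratorConfig
from rkt.simulate import sample_feature_table
from rkt.varcomp import feature_reliability_summary

cfg = GeneratorConfig(mu_features={"slack": 16.6, "er_laxity": 5.0,
                                   "ir_laxity": 5.6, "rot_at_zero": 0.0})
tab = sample_feature_table(cfg, np.random.default_rng(0))
print(feature_reliability_summary(tab).round(2).to_string(index=False))
```

```
  feature  var_subject  pct_subject  var_knee  pct_knee  var_day  pct_day  var_residual  pct_residual  sem_deg  mdc90_deg  total_variance  icc_2_1
er_laxity         0.98         69.0      0.11       7.9     0.23     16.3          0.09           6.7     0.31       0.72            1.41     0.77
    slack         6.95         72.2      0.90       9.3     1.49     15.5          0.29           3.0     0.54       1.25            9.63     0.81
ir_laxity         0.75         57.3      0.23      17.7     0.28     21.1          0.05           3.8     0.22       0.52            1.31     0.75
```

Read each row as: most of the observed variance (57–72 %) is genuine
subject-to-subject difference, day-to-day setup contributes 15–21 %, and the
residual (unexplained) share is a few percent, giving SEMs of a few tenths
of a degree and moderate-to-good ICC(2,1) reliability for every feature.

The same analyses are available from the shell:

```
rkt simulate --out run/ --seed 1
rkt features --trials run/trials.csv --out run/features.csv
rkt varcomp  --features run/features.csv --out run/table2.csv
rkt reliability --trials run/trials.csv --channel rot_z_deg --out run/curve.csv
rkt run --out run/ --seed 1          # all stages plus a manifest
```

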