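# valsampsize

Sample size calculations for **external validation studies of clinical
prediction models**, for biostatisticians and applied researchers planning
such studies. Instead of events-based rules of thumb, each key performance
measure gets its own precision criterion — the study is sized so that every
95% confidence interval (width `2 × 1.96 × SE`) is as narrow as prespecified,
and the largest requirement across criteria is the study's minimum n.

**Continuous outcomes** (four criteria): overall fit R², calibration-in-the-
large (mean observed − mean predicted), calibration slope, and the residual
variance (a 10% multiplicative margin of error on the residual SD by
default). **Binary outcomes** (four criteria): the O/E statistic (CI formed
on the log scale, `SE(ln O/E) = sqrt((1−φ)/(nφ))`), the calibration slope
(SE from the expected Fisher information of the logistic calibration model
`logit P(Y=1) = α + β·LP`, with expectations over the anticipated
linear-predictor distribution), the c statistic (Newcombe's SE), and
standardised net benefit at clinical decision thresholds (delta-method
variance of Marsh et al.). The LP distribution can be a beta distribution of
predicted probabilities, a normal linear predictor, or — as a last resort —
a binormal construction implied by the anticipated c statistic. See
`docs/methods.md` for every formula, convention and limitation.

Also included: an inverse mode (anticipated precision for a *fixed*,
already-available dataset size), missing-data inflation of the recruitment
target, report generation for transparent study-size justification, and a
simulation module that overlays replicated calibration curves to check
curve-level stability at a candidate n.

## Worked example (binary outcome)

A deterioration model for hospitalised covid-19 patients is to be validated:
anticipated event proportion 0.43, c statistic 0.77, predicted probabilities
approximately beta(1.33, 1.75), and a well calibrated model assumed. Target
CI widths: 0.22 (O/E), 0.3 (slope), 0.1 (c statistic), 0.2 (standardised net
benefit at thresholds 0.1 and 0.3).

```python
from valsampsize import BinaryValidationDesign, LPDistribution

design = BinaryValidationDesign(
    prevalence=0.43, cstat=0.77,
    lp=LPDistribution.from_beta(1.33, 1.75),
    ciw_oe=0.22, ciw_slope=0.3, ciw_cstat=0.1, ciw_snb=0.2,
    thresholds=(0.1, 0.3),
)
print(design.solve().summary())
```

```
Sample size for external validation
============================================================
Binary outcome: prevalence=0.43, c=0.77, assumed O/E=1, slope=1; LP: beta(1.33, 1.75) on the probability scale; thresholds: 0.1, 0.3; targets: CI width 0.22 (O/E), 0.3 (slope), 0.1 (c), 0.2 (sNB)
------------------------------------------------------------
                                n performance       SE CI width target width  events
criterion
oe_ratio                      423           1  0.05598   0.2199         0.22     182
calibration_slope             949           1  0.07652      0.3          0.3     408
c_statistic                   347        0.77  0.02549  0.09993          0.1     149
standardised_net_benefit@0.1   37      0.8628  0.05088   0.1994          0.2      16
standardised_net_benefit@0.3  280       0.588  0.05098   0.1998          0.2     120
------------------------------------------------------------
Minimum required sample size: 949 (408 events) (binding criterion: calibration_slope)
```

The calibration slope binds: 949 participants (408 events) are needed so all
four measures reach their target precision — far above the 100- or
200-events rules of thumb (233 or 466 participants at this prevalence,
via `rule_of_thumb_n`). With 5% anticipated missing data,
`inflate_for_missing(949, 0.05)` → recruit 999.

The same study from the shell, with flags transliterating the established
Stata-style syntax:

```bash
valsampsize --type b --prevalence .43 --cstatistic .77 --lpbeta 1.33 1.75 \
    --oeciwidth .22 --csciwidth .3 --cstatciwidth .1 --threshold .1 .3 --nbciwidth .2
valsampsize --type c --rsquared .4 --varobs 497.29 --citlciwidth 5 --csciwidth .3
```

The second command is the continuous worked example (pain-intensity model,
R² 0.40, outcome SD 22.30): it prints 886 (R²), 184 (CITL), 258 (slope) and
235 (residual variance), so 886 participants are required, with R² binding.

Curve-level stability at the chosen n (overlay of 100 simulated calibration
curves, spread summarised in regions holding decision thresholds):

```bash
valsampsize stability --type b --prevalence .43 --cstatistic .77 \
    --lpbeta 1.33 1.75 --n 949 --replicates 100 --seed 1 \
    --plot curves.png --regions 0.05:0.1,0.25:0.35
```

For an already-available dataset, `--fixed-n 500` (or
`design.precision(500)`) reports the anticipated CI of every measure at that
size instead of solving for n.

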