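"""Sample size criteria for validating a binary-outcome prediction model.

Four precision criteria, each giving a minimum n (and implied events); the
study requirement is their maximum:

1. **O/E statistic** — observed/expected events, overall calibration.  The
   CI is formed on the log scale with ``SE(ln O/E) = sqrt((1 - phi)/(n phi))``
   (phi the outcome proportion) and back-transformed, so the width target
   applies to the asymmetric interval on the O/E scale.
2. **Calibration slope** — from the logistic calibration model
   ``logit P(Y=1) = alpha + beta * LP``.  The SE is derived from the expected
   unit Fisher information under the assumed truth, with expectations taken
   over the anticipated linear-predictor distribution:

   ``I_00 = E[q(1-q)]``, ``I_01 = E[LP q(1-q)]``, ``I_11 = E[LP^2 q(1-q)]``,
   ``SE(beta-hat) = sqrt(I_00 / (n (I_00 I_11 - I_01^2)))``

   where ``q = expit(alpha + beta LP)`` is the true event probability.
3. **c statistic** — Newcombe's SE approximation, a function of the assumed
   c, the event fraction and n; solved by integer search.
4. **Standardised net benefit** — ``sNB = sens - w (1 - spec)`` with
   ``w = ((1-phi)/phi) (t/(1-t))`` at probability threshold t; the variance
   follows the delta method of Marsh et al. with sensitivity and specificity
   computed as expectations over the LP distribution under the assumed truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from ._search import smallest_n
from .lp_dist import LPDistribution
from .results import CriterionResult, SampleSizeResult

__all__ = [
    "BinaryValidationDesign",
    "n_for_oe",
    "n_for_slope_bin",
    "n_for_cstat",
    "n_for_net_benefit",
    "events_from_n",
    "rule_of_thumb_n",
    "run_binary",
    "se_ln_oe",
    "se_cstat_newcombe",
    "slope_unit_information",
    "sens_spec_at_threshold",
    "snb_unit_variance",
    "oe_ci",
]

Z95 = 1.96
MIN_N_BINARY = 20

CRITERION_OE = "oe_ratio"
CRITERION_SLOPE = "calibration_slope"
CRITERION_CSTAT = "c_statistic"
CRITERION_SNB = "standardised_net_benefit"


def _check_prevalence(prevalence: float):
    if not (0 < prevalence < 1):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence!r}")


def _check_width(name: str, value: float):
    if not (value > 0):
        raise ValueError(f"{name} must be > 0, got {value!r}")


# ----------------------------------------------------------------------
# events helpers
# ----------------------------------------------------------------------
def events_from_n(n: int, prevalence: float) -> int:
    """Expected number of events at sample size n (nearest integer)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    _check_prevalence(prevalence)
    return int(math.floor(n * prevalence + 0.5))


def rule_of_thumb_n(events: int, prevalence: float) -> int:
    """Participants implied by an events-based rule of thumb (ceiling)."""
    if events < 1:
        raise ValueError(f"events must be >= 1, got {events!r}")
    _check_prevalence(prevalence)
    return int(math.ceil(events / prevalence))


# ----------------------------------------------------------------------
# criterion 1: O/E
# ----------------------------------------------------------------------
def se_ln_oe(prevalence: float, n: int) -> float:
    """SE of ln(O/E) as a function of the outcome proportion and n."""
    _check_prevalence(prevalence)
    return math.sqrt((1 - prevalence) / (n * prevalence))


def oe_ci(oe: float, prevalence: float, n: int) -> tuple[float, float]:
    """95% CI for O/E, formed on the log scale and exponentiated."""
    se = se_ln_oe(prevalence, n)
    return (oe * math.exp(-Z95 * se), oe * math.exp(Z95 * se))


def n_for_oe(prevalence: float, oe_true: float, ciw_oe: float) -> int:
    """Minimum n for a target 95% CI width for O/E (on the O/E scale)."""
    _check_prevalence(prevalence)
    if not (oe_true > 0):
        raise ValueError(f"oe_true must be > 0, got {oe_true!r}")
    _check_width("ciw_oe", ciw_oe)

    def width(n):
        lo, hi = oe_ci(oe_true, prevalence, n)
        return hi - lo

    return smallest_n(lambda n: width(n) <= ciw_oe, MIN_N_BINARY)


# ----------------------------------------------------------------------
# criterion 2: calibration slope
# ----------------------------------------------------------------------
def _solve_intercept(lp: LPDistribution, slope_true: float, prevalence: float) -> float:
    """Intercept of the true calibration model preserving the prevalence.

    For ``slope_true = 1`` the well calibrated model has intercept 0 by
    definition of the linear predictor; otherwise solve
    ``E[expit(a + slope * LP)] = prevalence``.
    """
    if slope_true == 1.0:
        return 0.0

    def mean_risk(a):
        return lp.expect(lambda p, x: expit(a + slope_true * x)) - prevalence

    return optimize.brentq(mean_risk, -20.0, 20.0, xtol=1e-10)


def slope_unit_information(
    lp: LPDistribution, intercept_true: float = 0.0, slope_true: float = 1.0
) -> float:
    """Per-observation variance of the fitted calibration slope.

    ``n * var(beta-hat)`` from the expected Fisher information of the
    logistic calibration model evaluated at the assumed truth.
    """

    def q(p, x):
        return expit(intercept_true + slope_true * x)

    i00 = lp.expect(lambda p, x: q(p, x) * (1 - q(p, x)))
    i01 = lp.expect(lambda p, x: x * q(p, x) * (1 - q(p, x)))
    i11 = lp.expect(lambda p, x: x * x * q(p, x) * (1 - q(p, x)))
    det = i00 * i11 - i01 * i01
    if det <= 0 or i00 <= 0:
        raise ValueError(
            "calibration slope is inestimable: the linear-predictor "
            "distribution carries (numerically) zero variance"
        )
    return i00 / det


def n_for_slope_bin(
    lp: LPDistribution,
    intercept_true: float = 0.0,
    slope_true: float = 1.0,
    ciw_slope: float = 0.2,
) -> int:
    """Minimum n for a target 95% CI width for the calibration slope."""
    _check_width("ciw_slope", ciw_slope)
    unit = slope_unit_information(lp, intercept_true, slope_true)
    target = ciw_slope / (2 * Z95)
    return smallest_n(lambda n: math.sqrt(unit / n) <= target, MIN_N_BINARY)


# ----------------------------------------------------------------------
# criterion 3: c statistic (Newcombe SE)
# ----------------------------------------------------------------------
def se_cstat_newcombe(cstat: float, prevalence: float, n: int) -> float:
    """Newcombe's approximate SE of the estimated c statistic."""
    if not (0.5 < cstat < 1):
        raise ValueError(f"cstat must be in (0.5, 1), got {cstat!r}")
    _check_prevalence(prevalence)
    c = cstat
    var = (
        c
        * (1 - c)
        * (1 + (n / 2 - 1) * ((1 - c) / (2 - c)) + (n / 2 - 1) * c / (1 + c))
        / (n * n * prevalence * (1 - prevalence))
    )
    return math.sqrt(var)


def n_for_cstat(cstat: float, prevalence: float, ciw_cstat: float) -> int:
    """Minimum n for a target 95% CI width for the c statistic."""
    _check_width("ciw_cstat", ciw_cstat)
    return smallest_n(
        lambda n: 2 * Z95 * se_cstat_newcombe(cstat, prevalence, n) <= ciw_cstat,
        MIN_N_BINARY,
    )


# ----------------------------------------------------------------------
# criterion 4: standardised net benefit
# ----------------------------------------------------------------------
def sens_spec_at_threshold(
    lp: LPDistribution,
    threshold: float,
    intercept_true: float = 0.0,
    slope_true: float = 1.0,
) -> tuple[float, float]:
    """Anticipated sensitivity and specificity at a probability threshold.

    Classification is by the model's predicted probability (``expit(LP)``);
    event status follows the assumed true risks ``expit(a + b LP)``.
    Computed as expectations over the LP distribution.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold!r}")

    def q(x):
        return expit(intercept_true + slope_true * x)

    phi = lp.expect(lambda p, x: q(x))
    num_sens = lp.expect(lambda p, x: q(x) * (p > threshold), breakpoints=(threshold,))
    num_spec = lp.expect(
        lambda p, x: (1 - q(x)) * (p <= threshold), breakpoints=(threshold,)
    )
    sens = num_sens / phi
    spec = num_spec / (1 - phi)
    eps = 1e-6
    if not (eps < sens < 1 - eps) or not (eps < spec < 1 - eps):
        raise ValueError(
            f"threshold {threshold} lies outside the effective support of the "
            f"predicted values (sensitivity {sens:.4g}, specificity {spec:.4g} "
            "are degenerate)"
        )
    return sens, spec


def snb_unit_variance(
    sens: float, spec: float, prevalence: float, threshold: float
) -> float:
    """Per-observation variance of the standardised net benefit estimate.

    Delta-method variance (Marsh et al.) for ``sNB = sens - w (1 - spec)``
    with sensitivity, specificity and prevalence all estimated from the
    validation sample:

    ``n var(sNB) = sens(1-sens)/phi + w^2 spec(1-spec)/(1-phi)
                   + w^2 (1-spec)^2 / (phi (1-phi))``.
    """
    _check_prevalence(prevalence)
    w = ((1 - prevalence) / prevalence) * (threshold / (1 - threshold))
    return (
        sens * (1 - sens) / prevalence
        + w * w * spec * (1 - spec) / (1 - prevalence)
        + w * w * (1 - spec) ** 2 / (prevalence * (1 - prevalence))
    )


def standardised_net_benefit(
    sens: float, spec: float, prevalence: float, threshold: float
) -> float:
    """sNB = net benefit divided by the outcome proportion."""
    w = ((1 - prevalence) / prevalence) * (threshold / (1 - threshold))
    return sens - w * (1 - spec)


def n_for_net_benefit(
    lp: LPDistribution,
    prevalence: float,
    threshold: float,
    ciw_snb: float,
    intercept_true: float = 0.0,
    slope_true: float = 1.0,
) -> int:
    """Minimum n for a target 95% CI width for standardised net benefit."""
    _check_width("ciw_snb", ciw_snb)
    sens, spec = sens_spec_at_threshold(lp, threshold, intercept_true, slope_true)
    unit = snb_unit_variance(sens, spec, prevalence, threshold)
    target = ciw_snb / (2 * Z95)
    return smallest_n(lambda n: math.sqrt(unit / n) <= target, MIN_N_BINARY)


# ----------------------------------------------------------------------
# design object
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BinaryValidationDesign:
    """Anticipated performance and precision targets, binary outcome.

    Parameters
    ----------
    prevalence : float
        Anticipated outcome event proportion in the validation population.
    cstat : float
        Anticipated c statistic (optimism-adjusted where possible).
    lp : LPDistribution, optional
        Anticipated distribution of the model's predicted values.  If
        omitted, it is inferred from ``cstat`` and ``prevalence`` (the
        last-resort binormal construction).
    oe_true, slope_true : float
        Anticipated calibration (defaults assume a well calibrated model).
    thresholds : tuple of float
        Probability thresholds for the net-benefit criterion (may be empty).
    ciw_oe, ciw_slope, ciw_cstat, ciw_snb : float
        Target 95% CI widths for O/E, calibration slope, c statistic and
        standardised net benefit.
    prevalence_tol : float
        Maximum tolerated discrepancy between ``prevalence`` and the LP
        distribution's implied event proportion.
    """

    prevalence: float
    cstat: float
    lp: LPDistribution | None = None
    oe_true: float = 1.0
    slope_true: float = 1.0
    thresholds: tuple[float, ...] = ()
    ciw_oe: float = 0.2
    ciw_slope: float = 0.2
    ciw_cstat: float = 0.1
    ciw_snb: float = 0.2
    prevalence_tol: float = 0.02

    def __post_init__(self):
        _check_prevalence(self.prevalence)
        if not (0.5 < self.cstat < 1):
            raise ValueError(f"cstat must be in (0.5, 1), got {self.cstat!r}")
        if not (self.oe_true > 0):
            raise ValueError(f"oe_true must be > 0, got {self.oe_true!r}")
        for name in ("ciw_oe", "ciw_slope", "ciw_cstat", "ciw_snb"):
            _check_width(name, getattr(self, name))
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        for t in self.thresholds:
            if not (0 < t < 1):
                raise ValueError(f"thresholds must lie in (0, 1), got {t!r}")
        if self.lp is None:
            object.__setattr__(
                self, "lp", LPDistribution.from_cstat(self.prevalence, self.cstat)
            )
        diff = abs(self.lp.implied_prevalence - self.prevalence)
        if diff > self.prevalence_tol:
            raise ValueError(
                f"the LP distribution implies an event proportion of "
                f"{self.lp.implied_prevalence:.4f}, which differs from the design "
                f"prevalence {self.prevalence} by {diff:.4f} "
                f"(> tolerance {self.prevalence_tol}); the distribution of "
                "predicted values must reproduce the assumed outcome proportion"
            )

    @property
    def intercept_true(self) -> float:
        """Intercept of the assumed true calibration model."""
        return _solve_intercept(self.lp, self.slope_true, self.prevalence)

    def replace(self, **kwargs) -> "BinaryValidationDesign":
        return replace(self, **kwargs)

    def solve(self) -> SampleSizeResult:
        return run_binary(self)

    def precision(self, n: int, **overrides):
        from .precision import precision_for_n_binary

        return precision_for_n_binary(self, n, **overrides)

    def describe(self) -> str:
        th = ", ".join(f"{t:g}" for t in self.thresholds) or "none"
        return (
            f"Binary outcome: prevalence={self.prevalence:g}, c={self.cstat:g}, "
            f"assumed O/E={self.oe_true:g}, slope={self.slope_true:g}; "
            f"LP: {self.lp.describe()}; thresholds: {th}; targets: CI width "
            f"{self.ciw_oe:g} (O/E), {self.ciw_slope:g} (slope), "
            f"{self.ciw_cstat:g} (c), {self.ciw_snb:g} (sNB)"
        )

    def to_dict(self) -> dict:
        return {
            "outcome_type": "binary",
            "prevalence": self.prevalence,
            "cstat": self.cstat,
            "oe_true": self.oe_true,
            "slope_true": self.slope_true,
            "lp": self.lp.to_dict(),
            "thresholds": list(self.thresholds),
            "ciw_oe": self.ciw_oe,
            "ciw_slope": self.ciw_slope,
            "ciw_cstat": self.ciw_cstat,
            "ciw_snb": self.ciw_snb,
        }


def run_binary(design: BinaryValidationDesign) -> SampleSizeResult:
    """Per-criterion minimum sample sizes for a binary-outcome design.

    The net-benefit criterion is evaluated at every threshold in the design;
    the required sample size is the maximum across all criteria (and all
    thresholds).
    """
    rows = []
    errors = []
    phi = design.prevalence
    try:
        n = n_for_oe(phi, design.oe_true, design.ciw_oe)
        lo, hi = oe_ci(design.oe_true, phi, n)
        rows.append(
            CriterionResult(
                criterion=CRITERION_OE,
                n=n,
                se=se_ln_oe(phi, n),
                ci_width=hi - lo,
                target_width=design.ciw_oe,
                performance=design.oe_true,
                events=events_from_n(n, phi),
            )
        )
    except ValueError as exc:
        errors.append(f"{CRITERION_OE}: {exc}")
    try:
        a = design.intercept_true
        unit = slope_unit_information(design.lp, a, design.slope_true)
        n = n_for_slope_bin(design.lp, a, design.slope_true, design.ciw_slope)
        se = math.sqrt(unit / n)
        rows.append(
            CriterionResult(
                criterion=CRITERION_SLOPE,
                n=n,
                se=se,
                ci_width=2 * Z95 * se,
                target_width=design.ciw_slope,
                performance=design.slope_true,
                events=events_from_n(n, phi),
            )
        )
    except ValueError as exc:
        errors.append(f"{CRITERION_SLOPE}: {exc}")
    try:
        n = n_for_cstat(design.cstat, phi, design.ciw_cstat)
        se = se_cstat_newcombe(design.cstat, phi, n)
        rows.append(
            CriterionResult(
                criterion=CRITERION_CSTAT,
                n=n,
                se=se,
                ci_width=2 * Z95 * se,
                target_width=design.ciw_cstat,
                performance=design.cstat,
                events=events_from_n(n, phi),
            )
        )
    except ValueError as exc:
        errors.append(f"{CRITERION_CSTAT}: {exc}")
    for t in design.thresholds:
        try:
            a = design.intercept_true
            sens, spec = sens_spec_at_threshold(design.lp, t, a, design.slope_true)
            unit = snb_unit_variance(sens, spec, phi, t)
            n = n_for_net_benefit(design.lp, phi, t, design.ciw_snb, a, design.slope_true)
            se = math.sqrt(unit / n)
            rows.append(
                CriterionResult(
                    criterion=f"{CRITERION_SNB}@{t:g}",
                    n=n,
                    se=se,
                    ci_width=2 * Z95 * se,
                    target_width=design.ciw_snb,
                    performance=standardised_net_benefit(sens, spec, phi, t),
                    events=events_from_n(n, phi),
                )
            )
        except ValueError as exc:
            errors.append(f"{CRITERION_SNB}@{t:g}: {exc}")
    if errors:
        raise ValueError("criterion failure: " + "; ".join(errors))
    return SampleSizeResult(per_criterion=tuple(rows), design=design)
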