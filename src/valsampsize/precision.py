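"""Fixed-n mode: anticipated precision conditional on an available dataset.

Many validation studies obtain an existing dataset rather than recruiting new
participants.  The forward criteria are then inverted: given the dataset's
size (and any known characteristics such as its observed outcome proportion
or outcome variance, supplied as overrides), report the expected 95%
confidence interval for every performance measure.  Uses the same SE engines
as the forward calculations, so the two modes are round-trip consistent.
"""

from __future__ import annotations

import math

from . import binary as _bin
from . import continuous as _cont
from .results import PrecisionProfile

__all__ = ["precision_for_n_continuous", "precision_for_n_binary"]

Z95 = 1.96


def precision_for_n_continuous(design, n: int, **overrides) -> PrecisionProfile:
    """Anticipated CI widths for R², CITL, slope and residual SD at fixed n.

    Overrides (e.g. ``var_y=...`` for the dataset's observed outcome
    variance, or ``r_squared=...``) condition the calculation on known
    characteristics of the dataset.
    """
    if n < _cont.MIN_N_CONTINUOUS:
        raise ValueError(f"n must be >= {_cont.MIN_N_CONTINUOUS}, got {n!r}")
    if overrides:
        design = design.replace(**overrides)
    rows = []
    se = _cont.se_r2(design.r_squared, n)
    lo, hi = _cont.ciw_r2_for_n(design.r_squared, n)
    rows.append(
        {
            "measure": _cont.CRITERION_R2,
            "performance": design.r_squared,
            "se": se,
            "ci_lower": lo,
            "ci_upper": hi,
            "ci_width": 2 * Z95 * se,
        }
    )
    se = _cont.se_citl(design.var_y, design.r_squared, n)
    rows.append(
        {
            "measure": _cont.CRITERION_CITL,
            "performance": design.citl_true,
            "se": se,
            "ci_lower": design.citl_true - Z95 * se,
            "ci_upper": design.citl_true + Z95 * se,
            "ci_width": 2 * Z95 * se,
        }
    )
    se = _cont.se_slope_cont(design.r_squared, design.slope_true, n)
    rows.append(
        {
            "measure": _cont.CRITERION_SLOPE,
            "performance": design.slope_true,
            "se": se,
            "ci_lower": design.slope_true - Z95 * se,
            "ci_upper": design.slope_true + Z95 * se,
            "ci_width": 2 * Z95 * se,
        }
    )
    mmoe = _cont.resvar_mmoe(n)
    rv = design.residual_variance
    rows.append(
        {
            "measure": _cont.CRITERION_RESVAR,
            "performance": rv,
            "se": float("nan"),
            # chi-square interval for the residual variance implied by the MMOE
            "ci_lower": rv / mmoe**2,
            "ci_upper": rv * mmoe**2,
            "ci_width": rv * (mmoe**2 - 1 / mmoe**2),
        }
    )
    return PrecisionProfile(n=n, per_measure=tuple(rows), assumptions=design.to_dict())


def precision_for_n_binary(design, n: int, **overrides) -> PrecisionProfile:
    """Anticipated CI widths for O/E, slope, c statistic and sNB at fixed n."""
    if n < _bin.MIN_N_BINARY:
        raise ValueError(f"n must be >= {_bin.MIN_N_BINARY}, got {n!r}")
    if overrides:
        design = design.replace(**overrides)
    phi = design.prevalence
    rows = []
    lo, hi = _bin.oe_ci(design.oe_true, phi, n)
    rows.append(
        {
            "measure": _bin.CRITERION_OE,
            "performance": design.oe_true,
            "se": _bin.se_ln_oe(phi, n),  # SE on the log(O/E) scale
            "ci_lower": lo,
            "ci_upper": hi,
            "ci_width": hi - lo,
        }
    )
    a = design.intercept_true
    unit = _bin.slope_unit_information(design.lp, a, design.slope_true)
    se = math.sqrt(unit / n)
    rows.append(
        {
            "measure": _bin.CRITERION_SLOPE,
            "performance": design.slope_true,
            "se": se,
            "ci_lower": design.slope_true - Z95 * se,
            "ci_upper": design.slope_true + Z95 * se,
            "ci_width": 2 * Z95 * se,
        }
    )
    se = _bin.se_cstat_newcombe(design.cstat, phi, n)
    rows.append(
        {
            "measure": _bin.CRITERION_CSTAT,
            "performance": design.cstat,
            "se": se,
            "ci_lower": max(0.0, design.cstat - Z95 * se),
            "ci_upper": min(1.0, design.cstat + Z95 * se),
            "ci_width": 2 * Z95 * se,
        }
    )
    for t in design.thresholds:
        sens, spec = _bin.sens_spec_at_threshold(design.lp, t, a, design.slope_true)
        unit = _bin.snb_unit_variance(sens, spec, phi, t)
        snb = _bin.standardised_net_benefit(sens, spec, phi, t)
        se = math.sqrt(unit / n)
        rows.append(
            {
                "measure": f"{_bin.CRITERION_SNB}@{t:g}",
                "performance": snb,
                "se": se,
                "ci_lower": snb - Z95 * se,
                "ci_upper": snb + Z95 * se,
                "ci_width": 2 * Z95 * se,
            }
        )
    return PrecisionProfile(n=n, per_measure=tuple(rows), assumptions=design.to_dict())
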