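"""Planning utilities: missing-data inflation and study-size reporting.

Covers the practicalities around the core calculations: inflating the
required sample size for anticipated missing outcomes or predictor values,
and rendering a report that states every assumed input alongside the
per-criterion results (transparent reporting of how the study size was
arrived at, per the TRIPOD study-size item).
"""

from __future__ import annotations

import json
import math

from .results import SampleSizeResult

__all__ = ["inflate_for_missing", "render_report"]


def inflate_for_missing(n: int, missing_proportion: float) -> int:
    """Participants to recruit so that n remain after missingness.

    Smallest integer m with ``m * (1 - missing_proportion) >= n``; e.g. with
    5% anticipated missingness, a requirement of 949 complete observations
    means recruiting 999 (999 x 0.95 = 949.05).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if not (0 <= missing_proportion < 1):
        raise ValueError(
            f"missing_proportion must be in [0, 1), got {missing_proportion!r}"
        )
    if missing_proportion == 0:
        return int(n)
    m = math.ceil(n / (1 - missing_proportion))
    # guard against floating-point overshoot at exact multiples, keep minimal
    while (m - 1) * (1 - missing_proportion) >= n:
        m -= 1
    while m * (1 - missing_proportion) < n:
        m += 1
    return int(m)


def _methods_paragraph(result: SampleSizeResult, design, inflated: int | None) -> str:
    """A sentence suitable for a study protocol or methods section."""
    d = design.to_dict()
    if d["outcome_type"] == "binary":
        lp = design.lp.describe()
        assumed = (
            f"an outcome event proportion of {d['prevalence']:g}, a c statistic of "
            f"{d['cstat']:g}, an observed/expected ratio of {d['oe_true']:g}, a "
            f"calibration slope of {d['slope_true']:g}, and predicted values "
            f"distributed as {lp}"
        )
        targets = (
            f"target 95% confidence interval widths of {d['ciw_oe']:g} for O/E, "
            f"{d['ciw_slope']:g} for the calibration slope, {d['ciw_cstat']:g} for "
            f"the c statistic"
        )
        if d["thresholds"]:
            th = ", ".join(f"{t:g}" for t in d["thresholds"])
            targets += (
                f", and {d['ciw_snb']:g} for standardised net benefit at "
                f"probability threshold(s) {th}"
            )
    else:
        assumed = (
            f"an R-squared of {d['r_squared']:g}, an outcome variance of "
            f"{d['var_y']:g}, a calibration-in-the-large of {d['citl_true']:g} and "
            f"a calibration slope of {d['slope_true']:g}"
        )
        targets = (
            f"target 95% confidence interval widths of {d['ciw_r2']:g} for "
            f"R-squared, {d['ciw_citl']:g} for calibration-in-the-large, "
            f"{d['ciw_slope']:g} for the calibration slope, and a {d['resvar_mmoe']:g} "
            "multiplicative margin of error for the residual standard deviation"
        )
    ev = result.events_required
    ev_txt = f" ({ev} events)" if ev is not None else ""
    text = (
        f"The minimum sample size for the external validation study was calculated "
        f"to target precise estimates of each performance measure, assuming {assumed}, "
        f"with {targets}. The largest requirement across criteria was "
        f"{result.n_required} participants{ev_txt}, driven by the "
        f"{result.binding_criterion.replace('_', ' ')} criterion."
    )
    if inflated is not None and inflated != result.n_required:
        text += (
            f" Allowing for anticipated missing data, {inflated} participants "
            "should be recruited."
        )
    return text


def render_report(
    result: SampleSizeResult,
    design=None,
    format: str = "text",
    missing_proportion: float | None = None,
) -> str:
    """Render a study-size report in ``text``, ``markdown`` or ``json``.

    The report echoes every assumed input (for a binary outcome: event
    proportion, O/E, slope, c statistic, LP distribution family and
    parameters, width targets and thresholds), lists each criterion's
    required n with its achieved precision, names the binding criterion,
    and, if ``missing_proportion`` is given, the inflated recruitment target.
    """
    if design is None:
        design = result.design
    if design is None:
        raise ValueError("a design is required to render a report")
    inflated = (
        inflate_for_missing(result.n_required, missing_proportion)
        if missing_proportion
        else None
    )
    if format == "json":
        payload = {
            "assumptions": design.to_dict(),
            **result.to_dict(),
            "missing_proportion": missing_proportion,
            "n_to_recruit": inflated if inflated is not None else result.n_required,
            "methods_paragraph": _methods_paragraph(result, design, inflated),
        }
        return json.dumps(payload, indent=2)
    if format not in ("text", "markdown"):
        raise ValueError(f"unknown report format {format!r}")
    md = format == "markdown"
    lines = []
    title = "Sample size report for external validation"
    lines.append(f"# {title}" if md else title)
    lines.append("")
    lines.append("## Assumptions" if md else "Assumptions:")
    lines.append(design.describe())
    lines.append("")
    lines.append("## Criteria" if md else "Per-criterion requirements:")
    tbl = result.table()
    if md:
        lines.append(tbl.to_markdown())
    else:
        lines.append(tbl.to_string())
    lines.append("")
    ev = result.events_required
    ev_txt = f" ({ev} events)" if ev is not None else ""
    lines.append(
        f"Minimum required sample size: {result.n_required}{ev_txt} "
        f"(binding criterion: {result.binding_criterion})"
    )
    if inflated is not None:
        lines.append(
            f"Recruitment target allowing for {missing_proportion:.0%} missing "
            f"data: {inflated}"
        )
    lines.append("")
    lines.append("## Suggested methods text" if md else "Suggested methods text:")
    lines.append(_methods_paragraph(result, design, inflated))
    return "\n".join(lines)
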