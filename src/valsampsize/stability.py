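"""Simulation-based assessment of calibration-curve instability.

Analytic criteria target the calibration slope and intercept, but a study
sized for those summaries can still yield unstable calibration *curves*.
The check implemented here:

1. simulate many validation datasets (default 100) of the candidate size,
   under the same assumptions as the sample size calculation (predicted
   values drawn from the design's assumed distribution, outcomes generated
   from the assumed truth — by default a well calibrated model);
2. fit a smooth calibration curve to each dataset (logistic regression on a
   restricted cubic spline of the linear predictor for binary outcomes;
   loess for continuous outcomes);
3. overlay the curves on a common grid of predicted values;
4. summarise the pointwise spread (envelope between replicate quantiles),
   overall and within regions of predicted values that matter for clinical
   decision making.

If the envelope is judged too wide where it matters, a larger sample size is
needed; if it is very tight, a smaller one may suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .binary import BinaryValidationDesign
from .continuous import ContinuousValidationDesign

__all__ = ["CurveEnsemble", "simulate_ensemble", "summarise_spread", "plot_ensemble", "rcs_basis"]

GRID_SIZE = 101
GRID_COVERAGE = 0.98  # central mass of the predicted-value distribution
MAX_FAILURE_FRACTION = 0.05


def rcs_basis(x, knots):
    """Restricted cubic spline basis (Harrell), linear in the tails.

    Returns ``len(x) x (len(knots) - 1)`` columns: x itself plus
    ``len(knots) - 2`` nonlinear terms.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if k.size < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    kd = (k[-1] - k[0]) ** 2
    cols = [x]
    for j in range(k.size - 2):
        term = (
            np.clip(x - k[j], 0, None) ** 3
            - np.clip(x - k[-2], 0, None) ** 3 * (k[-1] - k[j]) / (k[-1] - k[-2])
            + np.clip(x - k[-1], 0, None) ** 3 * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(term / kd)
    return np.column_stack(cols)


@dataclass(frozen=True)
class CurveEnsemble:
    """Replicated calibration curves on a common grid.

    ``grid`` holds predicted values (probability scale for binary designs,
    outcome scale for continuous); ``curves`` is a replicate-by-grid matrix
    of fitted observed-value estimates.
    """

    grid: np.ndarray
    curves: np.ndarray
    outcome_type: str
    n: int
    envelope_quantiles: tuple[float, float] = (0.025, 0.975)
    n_failed: int = 0
    design: object = field(repr=False, default=None)

    @property
    def replicates(self) -> int:
        return self.curves.shape[0]

    @property
    def lower(self) -> np.ndarray:
        return np.quantile(self.curves, self.envelope_quantiles[0], axis=0)

    @property
    def median(self) -> np.ndarray:
        return np.quantile(self.curves, 0.5, axis=0)

    @property
    def upper(self) -> np.ndarray:
        return np.quantile(self.curves, self.envelope_quantiles[1], axis=0)

    @property
    def spread(self) -> np.ndarray:
        """Pointwise envelope width (upper minus lower quantile curve)."""
        return self.upper - self.lower

    def summarise_spread(self, regions, max_width: float | None = None):
        return summarise_spread(self, regions, max_width=max_width)

    def plot(self, path=None, ax=None):
        return plot_ensemble(self, path, ax=ax)


def _simulate_binary(design: BinaryValidationDesign, n, replicates, rng, grid):
    a = design.intercept_true
    b = design.slope_true
    # knots fixed from the assumed LP distribution, common across replicates
    knots = logit(design.lp.ppf_probability([0.05, 0.35, 0.65, 0.95]))
    grid_lp = logit(grid)
    grid_basis = sm.add_constant(rcs_basis(grid_lp, knots), has_constant="add")
    curves = []
    failed = 0
    for _ in range(replicates):
        lp = design.lp.sample(n, rng=rng)
        q = expit(a + b * lp)
        y = (rng.random(n) < q).astype(float)
        X = sm.add_constant(rcs_basis(lp, knots), has_constant="add")
        try:
            with np.errstate(all="ignore"):
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            pred = np.asarray(fit.predict(grid_basis))
            if not np.all(np.isfinite(pred)):
                raise ValueError("non-finite curve")
        except Exception:
            failed += 1
            continue
        curves.append(np.clip(pred, 0.0, 1.0))
    return curves, failed


def _simulate_continuous(design: ContinuousValidationDesign, n, replicates, rng, grid):
    sd_pred = np.sqrt(design.r_squared * design.var_y) / design.slope_true
    sd_resid = np.sqrt(design.residual_variance)
    curves = []
    failed = 0
    for _ in range(replicates):
        pred = rng.normal(design.mean_y, sd_pred, size=n)
        y = design.citl_true + design.slope_true * pred + rng.normal(0.0, sd_resid, n)
        try:
            fitted = sm.nonparametric.lowess(y, pred, xvals=grid)
            if not np.all(np.isfinite(fitted)):
                raise ValueError("non-finite curve")
        except Exception:
            failed += 1
            continue
        curves.append(np.asarray(fitted, dtype=float))
    return curves, failed


def simulate_ensemble(
    design,
    n: int,
    replicates: int = 100,
    seed: int | None = None,
    grid_size: int = GRID_SIZE,
    envelope_quantiles: tuple[float, float] = (0.025, 0.975),
) -> CurveEnsemble:
    """Simulate replicated calibration curves at candidate sample size n.

    Deterministic for a fixed ``seed``.  Replicates whose curve fit fails
    (e.g. perfect separation at small n) are dropped and counted; more than
    5% failures raises an error.
    """
    if replicates < 2:
        raise ValueError(f"replicates must be >= 2, got {replicates!r}")
    if n < 20:
        raise ValueError(f"n must be >= 20, got {n!r}")
    lo_q, hi_q = envelope_quantiles
    if not (0 <= lo_q < hi_q <= 1):
        raise ValueError(f"invalid envelope quantiles {envelope_quantiles!r}")
    rng = np.random.default_rng(seed)
    tail = (1 - GRID_COVERAGE) / 2
    qs = np.linspace(tail, 1 - tail, grid_size)
    if isinstance(design, BinaryValidationDesign):
        grid = np.asarray(design.lp.ppf_probability(qs), dtype=float)
        curves, failed = _simulate_binary(design, n, replicates, rng, grid)
        outcome_type = "binary"
    elif isinstance(design, ContinuousValidationDesign):
        sd_pred = np.sqrt(design.r_squared * design.var_y) / design.slope_true
        grid = design.mean_y + sd_pred * stats.norm.ppf(qs)
        curves, failed = _simulate_continuous(design, n, replicates, rng, grid)
        outcome_type = "continuous"
    else:
        raise TypeError(f"unsupported design type {type(design).__name__}")
    if failed > MAX_FAILURE_FRACTION * replicates:
        raise RuntimeError(
            f"{failed}/{replicates} replicate curve fits failed; the candidate "
            "sample size is too small for stable curve estimation"
        )
    return CurveEnsemble(
        grid=grid,
        curves=np.asarray(curves),
        outcome_type=outcome_type,
        n=int(n),
        envelope_quantiles=(lo_q, hi_q),
        n_failed=failed,
        design=design,
    )


def summarise_spread(ensemble: CurveEnsemble, regions, max_width: float | None = None):
    """Maximum envelope width within regions of predicted values.

    ``regions`` is a sequence of ``(lower, upper)`` predicted-value
    intervals (e.g. ranges containing decision thresholds).  If
    ``max_width`` is given, each region is flagged as acceptable or not.
    """
    spread = ensemble.spread
    out = []
    for lo, hi in regions:
        if not (lo < hi):
            raise ValueError(f"region bounds must satisfy lower < upper, got ({lo}, {hi})")
        mask = (ensemble.grid >= lo) & (ensemble.grid <= hi)
        if not mask.any():
            raise ValueError(
                f"region ({lo}, {hi}) contains no grid points; the grid spans "
                f"[{ensemble.grid[0]:.4g}, {ensemble.grid[-1]:.4g}]"
            )
        width = float(spread[mask].max())
        row = {"lower": float(lo), "upper": float(hi), "max_spread": width}
        if max_width is not None:
            row["acceptable"] = bool(width <= max_width)
        out.append(row)
    return out


def plot_ensemble(ensemble: CurveEnsemble, path=None, ax=None):
    """Overlay all replicate curves with the identity (perfect calibration) line."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    for row in ensemble.curves:
        ax.plot(ensemble.grid, row, color="steelblue", alpha=0.25, lw=0.8)
    ax.plot(
        ensemble.grid, ensemble.grid, color="black", lw=1.5, ls="--", label="perfect calibration"
    )
    ax.plot(ensemble.grid, ensemble.median, color="firebrick", lw=1.2, label="median curve")
    if ensemble.outcome_type == "binary":
        ax.set_xlabel("estimated event probability")
        ax.set_ylabel("observed event probability")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    else:
        ax.set_xlabel("predicted outcome value")
        ax.set_ylabel("observed outcome value")
    ax.set_title(
        f"{ensemble.replicates} simulated validation studies, n = {ensemble.n}"
    )
    ax.legend(loc="upper left", frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
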