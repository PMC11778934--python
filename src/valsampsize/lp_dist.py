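"""Distributions of a prediction model's estimated risks in the validation population.

Sample size criteria for the calibration slope and for net benefit depend on
the anticipated distribution of the model's predicted values, specified either
on the probability scale (a beta distribution fitted to a published histogram
of predicted risks) or on the log-odds scale (the "linear predictor", LP).
When no direct information is available, the distribution can be inferred from
the anticipated c statistic under a binormal model: LP values normal with a
common variance and different means in the event and non-event groups.

:class:`LPDistribution` exposes every supported family through one interface:
sampling, probability-scale density/CDF/quantiles, and an expectation engine
(adaptive quadrature with a Monte Carlo fallback) used by the binary criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit, logit

__all__ = ["LPDistribution", "fit_beta_to_histogram"]

# draws on the probability scale are clipped here before the logit transform,
# so sampled log-odds are always finite
_P_CLIP = 1e-10

_FAMILIES = ("beta_probability", "normal_logit", "cstat_implied", "mixture_logit")


def _as_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LPDistribution:
    """Assumed distribution of predicted values, on both scales.

    Use the ``from_*`` constructors rather than instantiating directly.

    Attributes
    ----------
    family : str
        One of ``beta_probability``, ``normal_logit``, ``cstat_implied`` or
        ``mixture_logit`` (the last is the advanced two-component option for
        histograms stratified by outcome status).
    params : dict
        Family-specific parameters.
    """

    family: str
    params: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_beta(cls, shape1: float, shape2: float) -> "LPDistribution":
        """Beta distribution of predicted probabilities.

        The implied outcome proportion is the beta mean ``shape1/(shape1+shape2)``.
        """
        for name, v in (("shape1", shape1), ("shape2", shape2)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"beta parameter {name} must be > 0, got {v!r}")
        return cls("beta_probability", {"shape1": float(shape1), "shape2": float(shape2)})

    @classmethod
    def from_normal_logit(cls, mean: float, sd: float) -> "LPDistribution":
        """Normal distribution of the linear predictor (log-odds scale)."""
        mean = _as_finite("mean", mean)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"normal_logit parameter sd must be > 0, got {sd!r}")
        return cls("normal_logit", {"mean": mean, "sd": float(sd)})

    @classmethod
    def from_cstat(cls, prevalence: float, cstat: float) -> "LPDistribution":
        """Infer the LP distribution from an anticipated c statistic.

        Assumes log-odds values are normal with a common variance and
        different means for events and non-events.  Requiring (i) the implied
        c statistic to equal ``cstat``, (ii) the overall event proportion to
        equal ``prevalence`` and (iii) self-consistency of the risks (a true
        calibration slope of 1) fixes the construction in closed form:
        with ``delta = 2 * Phi^-1(cstat)**2``,

        * common variance ``delta``,
        * non-event mean ``logit(prevalence) - delta/2``,
        * event mean ``logit(prevalence) + delta/2``.

        This is the analytic fixed point of the iterative prevalence-matching
        procedure used in common implementations, so no simulation is needed.
        """
        if not (0 < prevalence < 1):
            raise ValueError(f"prevalence must be in (0, 1), got {prevalence!r}")
        if not (0.5 < cstat < 1):
            raise ValueError(
                f"cstat must be in (0.5, 1), got {cstat!r}; the construction is "
                "undefined for a non-discriminating model"
            )
        z = stats.norm.ppf(cstat)
        delta = 2.0 * z * z
        mu0 = logit(prevalence) - delta / 2.0
        return cls(
            "cstat_implied",
            {
                "prevalence": float(prevalence),
                "cstat": float(cstat),
                "mean_nonevent": float(mu0),
                "mean_event": float(mu0 + delta),
                "sd": float(np.sqrt(delta)),
            },
        )

    @classmethod
    def from_mixture_logit(
        cls,
        prevalence: float,
        mean_nonevent: float,
        mean_event: float,
        sd_nonevent: float,
        sd_event: float | None = None,
    ) -> "LPDistribution":
        """Two-component normal mixture on the log-odds scale (advanced).

        For use when the development study reports histograms of predicted
        values stratified by outcome status.  Component weights are
        ``1 - prevalence`` (non-events) and ``prevalence`` (events).  Note the
        implied overall event proportion is the expectation of the
        probability-scale mixture, which matches ``prevalence`` exactly only
        when the components are consistent with the assumed risks; check
        :attr:`implied_prevalence` against the design value.
        """
        if not (0 < prevalence < 1):
            raise ValueError(f"prevalence must be in (0, 1), got {prevalence!r}")
        mean_nonevent = _as_finite("mean_nonevent", mean_nonevent)
        mean_event = _as_finite("mean_event", mean_event)
        if sd_event is None:
            sd_event = sd_nonevent
        for name, v in (("sd_nonevent", sd_nonevent), ("sd_event", sd_event)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"mixture parameter {name} must be > 0, got {v!r}")
        return cls(
            "mixture_logit",
            {
                "prevalence": float(prevalence),
                "mean_nonevent": mean_nonevent,
                "mean_event": mean_event,
                "sd_nonevent": float(sd_nonevent),
                "sd_event": float(sd_event),
            },
        )

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown LP distribution family {self.family!r}")

    # ------------------------------------------------------------------
    # densities and quantiles
    # ------------------------------------------------------------------
    def _logit_components(self):
        """(weights, means, sds) of the log-odds normal mixture, if any."""
        p = self.params
        if self.family == "normal_logit":
            return np.array([1.0]), np.array([p["mean"]]), np.array([p["sd"]])
        if self.family == "cstat_implied":
            phi = p["prevalence"]
            return (
                np.array([1.0 - phi, phi]),
                np.array([p["mean_nonevent"], p["mean_event"]]),
                np.array([p["sd"], p["sd"]]),
            )
        if self.family == "mixture_logit":
            phi = p["prevalence"]
            return (
                np.array([1.0 - phi, phi]),
                np.array([p["mean_nonevent"], p["mean_event"]]),
                np.array([p["sd_nonevent"], p["sd_event"]]),
            )
        raise AttributeError("beta_probability has no log-odds mixture form")

    def pdf_logit(self, x):
        """Density of the linear predictor (log-odds scale)."""
        x = np.asarray(x, dtype=float)
        if self.family == "beta_probability":
            p = expit(x)
            return stats.beta.pdf(p, self.params["shape1"], self.params["shape2"]) * p * (1 - p)
        w, m, s = self._logit_components()
        xv = np.atleast_1d(x)
        out = np.sum(w[:, None] * stats.norm.pdf(xv[None, :], m[:, None], s[:, None]), axis=0)
        return out[0] if x.ndim == 0 else out.reshape(x.shape)

    def pdf_probability(self, p):
        """Density of the predicted probability on (0, 1)."""
        p = np.asarray(p, dtype=float)
        if self.family == "beta_probability":
            return stats.beta.pdf(p, self.params["shape1"], self.params["shape2"])
        with np.errstate(divide="ignore"):
            return self.pdf_logit(logit(p)) / (p * (1 - p))

    def cdf_probability(self, p):
        """CDF of the predicted probability."""
        p = np.asarray(p, dtype=float)
        if self.family == "beta_probability":
            return stats.beta.cdf(p, self.params["shape1"], self.params["shape2"])
        w, m, s = self._logit_components()
        x = logit(np.clip(p, _P_CLIP, 1 - _P_CLIP))
        xv = np.atleast_1d(x)
        out = np.sum(w[:, None] * stats.norm.cdf(xv[None, :], m[:, None], s[:, None]), axis=0)
        return out[0] if p.ndim == 0 else out.reshape(p.shape)

    def ppf_probability(self, q):
        """Quantile of the predicted-probability distribution."""
        q = np.asarray(q, dtype=float)
        if self.family == "beta_probability":
            return stats.beta.ppf(q, self.params["shape1"], self.params["shape2"])
        w, m, s = self._logit_components()
        lo = float(np.min(m - 10 * s))
        hi = float(np.max(m + 10 * s))

        def _one(qq):
            f = lambda x: float(np.sum(w * stats.norm.cdf(x, m, s))) - qq
            return expit(optimize.brentq(f, lo, hi))

        return np.vectorize(_one)(q)

    # ------------------------------------------------------------------
    # prevalence
    # ------------------------------------------------------------------
    @property
    def implied_prevalence(self) -> float:
        """Expectation of the probability-scale distribution, E[p].

        Closed form for the beta family (the beta mean) and for the
        c-statistic construction (self-consistency makes E[expit(LP)] equal
        the input prevalence exactly); quadrature otherwise.
        """
        p = self.params
        if self.family == "beta_probability":
            return p["shape1"] / (p["shape1"] + p["shape2"])
        if self.family == "cstat_implied":
            return p["prevalence"]
        return self.expect(lambda prob, lp: prob)

    # ------------------------------------------------------------------
    # sampling
    # ------------------------------------------------------------------
    def sample(self, n_draws: int, seed: int | None = None, rng: np.random.Generator | None = None):
        """Draw ``n_draws`` linear-predictor (log-odds) values.

        Reproducible for a fixed ``seed``.  Probability-scale draws are
        clipped to ``[1e-10, 1 - 1e-10]`` before the logit transform so all
        returned values are finite.
        """
        if int(n_draws) < 1:
            raise ValueError(f"n_draws must be >= 1, got {n_draws!r}")
        n_draws = int(n_draws)
        if rng is None:
            rng = np.random.default_rng(seed)
        if self.family == "beta_probability":
            p = rng.beta(self.params["shape1"], self.params["shape2"], size=n_draws)
            return logit(np.clip(p, _P_CLIP, 1 - _P_CLIP))
        w, m, s = self._logit_components()
        comp = rng.choice(len(w), size=n_draws, p=w) if len(w) > 1 else np.zeros(n_draws, int)
        return rng.normal(m[comp], s[comp])

    def sample_probability(self, n_draws, seed=None, rng=None):
        """Draw predicted probabilities (inverse-logit of :meth:`sample`)."""
        return expit(self.sample(n_draws, seed=seed, rng=rng))

    # ------------------------------------------------------------------
    # expectations
    # ------------------------------------------------------------------
    def expect(
        self,
        integrand: Callable,
        breakpoints: Sequence[float] = (),
        method: str = "auto",
        rel_tol: float = 1e-6,
        mc_draws: int = 1_000_000,
        mc_seed: int = 76428531,
    ) -> float:
        """Expectation of ``integrand(p, lp)`` over the distribution.

        Parameters
        ----------
        integrand : callable
            Vectorised function of the predicted probability ``p`` and the
            linear predictor ``lp = logit(p)``.
        breakpoints : sequence of float
            Probability-scale discontinuity locations (e.g. a risk
            threshold); quadrature panels are split there.
        method : {"auto", "quadrature", "mc"}
            ``auto`` tries adaptive quadrature and falls back to Monte Carlo
            (``mc_draws`` draws, fixed ``mc_seed``) if the quadrature error
            estimate exceeds the tolerance.  The method actually used is
            recorded in :attr:`last_expect_method`.
        """
        if method not in ("auto", "quadrature", "mc"):
            raise ValueError(f"unknown expectation method {method!r}")
        if method in ("auto", "quadrature"):
            try:
                value, err = self._expect_quad(integrand, breakpoints)
                if np.isfinite(value) and err <= max(rel_tol * abs(value), 1e-10):
                    object.__setattr__(self, "last_expect_method", "quadrature")
                    return value
                if method == "quadrature":
                    raise RuntimeError(
                        f"quadrature did not converge (estimate {value!r}, error {err!r})"
                    )
            except RuntimeError:
                raise
            except Exception:
                if method == "quadrature":
                    raise
        # Monte Carlo fallback (or explicit request)
        lp = self.sample(mc_draws, seed=mc_seed)
        value = float(np.mean(integrand(expit(lp), lp)))
        object.__setattr__(self, "last_expect_method", "monte_carlo")
        return value

    def _expect_quad(self, integrand, breakpoints):
        if self.family == "beta_probability":
            a, b = self.params["shape1"], self.params["shape2"]

            def f(p):
                with np.errstate(divide="ignore"):
                    lp = logit(p)
                return integrand(p, lp) * stats.beta.pdf(p, a, b)

            pts = sorted(float(t) for t in breakpoints if 0 < t < 1)
            edges = [0.0, *pts, 1.0]
            total, err = 0.0, 0.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", integrate.IntegrationWarning)
                for lo, hi in zip(edges[:-1], edges[1:]):
                    v, e = integrate.quad(f, lo, hi, limit=200)
                    total += v
                    err += e
            return total, err
        # log-odds-scale families: integrate over the real line
        w, m, s = self._logit_components()

        def f(x):
            x = np.asarray(x, dtype=float)
            dens = float(np.sum(w * stats.norm.pdf(x, m, s)))
            return integrand(expit(x), x) * dens

        pts = sorted(logit(float(t)) for t in breakpoints if 0 < t < 1)
        edges = [-np.inf, *pts, np.inf]
        total, err = 0.0, 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            for lo, hi in zip(edges[:-1], edges[1:]):
                v, e = integrate.quad(f, lo, hi, limit=200)
                total += v
                err += e
        return total, err

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, **self.params}

    def describe(self) -> str:
        p = self.params
        if self.family == "beta_probability":
            return f"beta({p['shape1']:g}, {p['shape2']:g}) on the probability scale"
        if self.family == "normal_logit":
            return f"normal(mean={p['mean']:g}, sd={p['sd']:g}) on the log-odds scale"
        if self.family == "cstat_implied":
            return (
                f"binormal log-odds implied by c={p['cstat']:g}, "
                f"prevalence={p['prevalence']:g}"
            )
        return (
            f"two-component normal log-odds mixture (non-event mean {p['mean_nonevent']:g}, "
            f"event mean {p['mean_event']:g})"
        )


def fit_beta_to_histogram(bin_edges, counts) -> LPDistribution:
    """Fit a beta distribution to binned counts of predicted probabilities.

    Convenience helper for approximating a published histogram of predicted
    risks (the usual source of the probability-scale distribution).  Least
    squares on the binned probability masses; not part of the core
    calculation path, which takes the beta parameters directly.
    """
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if edges.ndim != 1 or edges.size != counts.size + 1:
        raise ValueError("bin_edges must have len(counts) + 1 entries")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    target = counts / counts.sum()

    def loss(log_ab):
        a, b = np.exp(log_ab)
        mass = np.diff(stats.beta.cdf(edges, a, b))
        return float(np.sum((mass - target) ** 2))

    res = optimize.minimize(loss, x0=np.log([2.0, 2.0]), method="Nelder-Mead")
    a, b = np.exp(res.x)
    return LPDistribution.from_beta(a, b)
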