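"""Size-threshold optimization of liver-graft allocation for HCC waiting lists.

Deterministic compartment-style model of a hepatocellular-carcinoma (HCC)
transplantation waiting list observed "at presentation": ``N`` patients enter
over a short interval, ``F < N`` donor livers are available, and each patient
carries a single tumor of size ``s`` (cm) drawn from an exponential
distribution with rate ``lam`` (per cm).  Mortality is a constant-in-time
hazard that depends on tumor size and on transplant status:

    non-transplanted:  alpha_nt(s) = alpha0 * (alpha1 - exp(-delta1 * s))
    transplanted:      alpha_t(s)  = alpha0 + delta2 * s

so the probability of surviving a horizon ``T`` years is ``exp(-rate * T)``.
With ``alpha1 = 2`` the two hazards coincide at ``s = 0`` (transplanting a
vanishingly small tumor confers no benefit); because the non-transplanted
hazard is concave increasing and saturates while the transplanted one grows
linearly, the two curves cross at a single positive size beyond which
transplantation hurts.

An allocation policy transplants a fraction ``g(s) * F / N`` of patients with
tumor size up to a cutoff ``s0``.  The model integrates size-resolved
survival over the population to obtain the expected 5-year death count
``M(s0)`` and locates the cutoff minimizing it, plus the "equivalent"
cutoff beyond the optimum at which mortality returns to its value at the
Milan-criteria size limit (5 cm) — the largest expansion of the eligibility
rule that does not worsen list-level mortality.

An individual-based Monte-Carlo simulator (exponential death clocks,
Bernoulli-thinned transplant assignment) provides an independent stochastic
counterpart of the integrals, and a small exponential-distribution fitter
recovers ``lam`` from observed tumor sizes.

Sections below follow the order the method runs: parameters and scenario
configuration; hazards, survival and the size distribution; allocation
policies and graft utilization; outcome integrals and threshold
optimization; Monte-Carlo cohort simulation and distribution fitting;
scenario runner used by the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "CohortParams",
    "Policy",
    "MilanSummary",
    "MortalityCurve",
    "SimCohort",
    "SizeDistFit",
    "ScenarioConfig",
    "constant_bias",
    "step_bias",
    "table_bias",
    "milan_policy",
    "hazard_nontransplanted",
    "hazard_transplanted",
    "survival_nontransplanted",
    "survival_transplanted",
    "size_pdf",
    "size_cdf",
    "size_moments",
    "crossing_size",
    "calibrate_delta1",
    "allocation_densities",
    "full_utilization_threshold",
    "milan_summary",
    "grafts_used",
    "transplanted_survivors",
    "transplanted_survivors_closed_form",
    "nontransplanted_survivors",
    "total_survivors",
    "total_mortality",
    "mortality_slope",
    "mortality_curve",
    "optimal_threshold",
    "equivalent_threshold",
    "sample_cohort",
    "simulate_deaths",
    "mc_mortality",
    "fit_size_distribution",
    "load_config",
    "run_scenario",
]

logger = logging.getLogger("hcc_alloc")

# Quadrature tolerances on proportions (integrals are scaled by N or F after).
_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-10, limit=200)

# Tail quantile used when bracketing roots in s: sizes beyond the
# 1 - 1e-10 quantile of the exponential size distribution carry no mass.
_TAIL_QUANTILE = 1e-10


# ---------------------------------------------------------------------------
# Parameters and scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Hazard and tumor-size-distribution parameters plus the horizon.

    Parameters
    ----------
    alpha0 : float
        Baseline mortality rate (per year); hazard of a transplanted patient
        with a zero-size tumor.
    alpha1 : float
        Dimensionless multiplier in the non-transplanted hazard.  ``alpha1=2``
        makes the two hazards coincide at ``s=0`` and is the standing
        assumption of the model.
    delta1 : float
        Shape rate (per cm) of the non-transplanted hazard; controls how fast
        that hazard saturates at ``alpha0*alpha1``.
    delta2 : float
        Slope (per year per cm) of the transplanted hazard.
    lam : float
        Rate (per cm) of the exponential tumor-size distribution; mean size
        is ``1/lam``.
    T : float
        Survival horizon in years.
    """

    alpha0: float = 0.048
    alpha1: float = 2.0
    delta1: float = 0.3
    delta2: float = 0.006
    lam: float = 0.3
    T: float = 5.0

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "delta1", "delta2", "lam"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"ModelParams.{name} must be strictly positive, got {v!r}")
        # T = 0 is a meaningful degenerate horizon (everyone survives).
        if not (np.isfinite(self.T) and self.T >= 0):
            raise ValueError(f"ModelParams.T must be non-negative, got {self.T!r}")
        if not self.delta1 > self.delta2:
            raise ValueError(
                f"ModelParams requires delta1 > delta2, got delta1={self.delta1}, delta2={self.delta2}"
            )


@dataclass(frozen=True)
class CohortParams:
    """Waiting-list size ``N``, graft supply ``F`` and Milan size cutoff ``S_M`` (cm)."""

    N: int = 1500
    F: int = 500
    S_M: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.F < self.N:
            raise ValueError(f"CohortParams requires 0 < F < N, got F={self.F}, N={self.N}")
        if not self.S_M > 0:
            raise ValueError(f"CohortParams.S_M must be positive, got {self.S_M!r}")


BiasFn = Callable[[np.ndarray], np.ndarray]


def constant_bias(value: float = 1.0) -> BiasFn:
    """Size-independent bias ``g(s) = value`` (default: no bias)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"bias value must lie in [0, 1], got {value!r}")

    def g(s: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(s, dtype=float), value)

    return g


def step_bias(threshold: float) -> BiasFn:
    """Indicator bias ``g(s) = 1 if s <= threshold else 0`` (Milan-style rule)."""

    def g(s: np.ndarray) -> np.ndarray:
        return (np.asarray(s, dtype=float) <= threshold).astype(float)

    return g


def table_bias(breakpoints: Sequence[float], values: Sequence[float]) -> BiasFn:
    """Piecewise-linear bias interpolating ``values`` at ``breakpoints``."""
    bp = np.asarray(breakpoints, dtype=float)
    val = np.asarray(values, dtype=float)
    if bp.ndim != 1 or bp.shape != val.shape or bp.size < 2:
        raise ValueError("table bias needs matching 1-d breakpoints and values (>= 2 points)")
    if np.any(np.diff(bp) <= 0):
        raise ValueError("table bias breakpoints must be strictly increasing")
    if np.any((val < 0) | (val > 1)):
        raise ValueError("table bias values must lie in [0, 1]")

    def g(s: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), bp, val)

    return g


@dataclass(frozen=True)
class Policy:
    """Allocation rule: transplant below cutoff ``s0`` with size bias ``g``.

    A patient of size ``s <= s0`` is transplanted with probability
    ``g(s) * F / N`` (density ``x(s) = g(s) (F/N) p(s)``); larger tumors are
    never transplanted.  ``s0`` may be infinite.  The default ``g`` is the
    unbiased constant 1.
    """

    s0: float = math.inf
    g: BiasFn = field(default_factory=constant_bias)

    def __post_init__(self) -> None:
        if not (self.s0 >= 0):
            raise ValueError(f"Policy.s0 must be non-negative, got {self.s0!r}")

    def bias_at(self, s) -> np.ndarray:
        """Evaluate ``g`` and validate its range."""
        out = np.asarray(self.g(np.asarray(s, dtype=float)), dtype=float)
        if np.any((out < 0) | (out > 1)):
            raise ValueError("policy bias g(s) must take values in [0, 1]")
        return out


def milan_policy(c: CohortParams) -> Policy:
    """The Milan rule as a policy: transplant only tumors up to ``S_M``."""
    return Policy(s0=c.S_M)


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated bundle of model, cohort, policy and run settings."""

    model: ModelParams = ModelParams()
    cohort: CohortParams = CohortParams()
    policy: Policy = field(default_factory=Policy)
    grid: tuple[float, float, float] = (0.0, 15.0, 0.01)
    reps: int = 300
    seed: int = 0

    @staticmethod
    def from_mapping(raw: Mapping) -> "ScenarioConfig":
        """Build a config from a flat key-value mapping, naming any bad key."""
        known_model = {"alpha0", "alpha1", "delta1", "delta2", "lambda", "T"}
        known_other = {"N", "F", "S_M", "policy", "run"}
        for key in raw:
            if key not in known_model | known_other:
                raise ValueError(f"unknown config key: {key!r}")

        def grab(key: str, cast, default):
            if key not in raw:
                return default
            try:
                return cast(raw[key])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"config key {key!r} is invalid: {exc}") from exc

        mkw = {}
        for key, attr in [("alpha0", "alpha0"), ("alpha1", "alpha1"), ("delta1", "delta1"),
                          ("delta2", "delta2"), ("lambda", "lam"), ("T", "T")]:
            if key in raw:
                mkw[attr] = grab(key, float, None)
        try:
            model = ModelParams(**mkw)
        except ValueError as exc:
            raise ValueError(f"invalid model parameters: {exc}") from exc

        ckw = {}
        for key in ("N", "F"):
            if key in raw:
                ckw[key] = grab(key, int, None)
        if "S_M" in raw:
            ckw["S_M"] = grab("S_M", float, None)
        try:
            cohort = CohortParams(**ckw)
        except ValueError as exc:
            raise ValueError(f"invalid cohort parameters: {exc}") from exc

        pol_raw = raw.get("policy", {}) or {}
        s0 = float(pol_raw.get("s0", math.inf))
        bias_raw = pol_raw.get("bias", None)
        if bias_raw is None:
            g = constant_bias()
        else:
            kind = bias_raw.get("type")
            if kind == "constant":
                g = constant_bias(float(bias_raw.get("value", 1.0)))
            elif kind == "step":
                g = step_bias(float(bias_raw["threshold"]))
            elif kind == "table":
                g = table_bias(bias_raw["s"], bias_raw["g"])
            else:
                raise ValueError(f"config key 'policy.bias.type' is invalid: {kind!r}")
        policy = Policy(s0=s0, g=g)

        run_raw = raw.get("run", {}) or {}
        grid_raw = run_raw.get("grid", {}) or {}
        grid = (
            float(grid_raw.get("start", 0.0)),
            float(grid_raw.get("stop", 15.0)),
            float(grid_raw.get("step", 0.01)),
        )
        if not (grid[0] >= 0 and grid[1] > grid[0] and grid[2] > 0):
            raise ValueError(f"config key 'run.grid' is invalid: {grid!r}")
        reps = int(run_raw.get("reps", 300))
        if reps < 2:
            raise ValueError(f"config key 'run.reps' must be >= 2, got {reps}")
        seed = int(run_raw.get("seed", 0))
        return ScenarioConfig(model=model, cohort=cohort, policy=policy,
                              grid=grid, reps=reps, seed=seed)

    def params_echo(self) -> dict:
        """Flat record of every parameter, echoed into all output headers."""
        from . import __version__

        return {
            "alpha0": self.model.alpha0,
            "alpha1": self.model.alpha1,
            "delta1": self.model.delta1,
            "delta2": self.model.delta2,
            "lambda": self.model.lam,
            "T": self.model.T,
            "N": self.cohort.N,
            "F": self.cohort.F,
            "S_M": self.cohort.S_M,
            "policy_s0": self.policy.s0,
            "grid_start": self.grid[0],
            "grid_stop": self.grid[1],
            "grid_step": self.grid[2],
            "reps": self.reps,
            "seed": self.seed,
            "version": __version__,
        }


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a YAML or JSON scenario config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError(f"config file {path} does not contain a key-value mapping")
    return ScenarioConfig.from_mapping(raw)


def _check_size(s) -> np.ndarray:
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0):
        raise ValueError("tumor size s must be non-negative")
    return arr


# ---------------------------------------------------------------------------
# Hazards, survival probabilities, and the tumor-size distribution
# ---------------------------------------------------------------------------

def hazard_nontransplanted(s, p: ModelParams):
    """Mortality rate (per year) of a non-transplanted patient with tumor size ``s``.

    ``alpha0 * (alpha1 - exp(-delta1 * s))``: concave increasing in ``s``,
    saturating at ``alpha0 * alpha1`` for large tumors.
    """
    arr = _check_size(s)
    out = p.alpha0 * (p.alpha1 - np.exp(-p.delta1 * arr))
    return out if out.ndim else float(out)


def hazard_transplanted(s, p: ModelParams):
    """Mortality rate (per year) of a transplanted patient: ``alpha0 + delta2 * s``."""
    arr = _check_size(s)
    out = p.alpha0 + p.delta2 * arr
    return out if out.ndim else float(out)


def survival_nontransplanted(s, p: ModelParams):
    """Probability a non-transplanted patient of size ``s`` survives ``T`` years."""
    arr = _check_size(s)
    out = np.exp(-hazard_nontransplanted(arr, p) * p.T)
    return out if out.ndim else float(out)


def survival_transplanted(s, p: ModelParams):
    """Probability a transplanted patient of size ``s`` survives ``T`` years."""
    arr = _check_size(s)
    out = np.exp(-hazard_transplanted(arr, p) * p.T)
    return out if out.ndim else float(out)


def size_pdf(s, lam: float):
    """Exponential tumor-size density ``lam * exp(-lam * s)`` (per cm).

    Negative sizes raise rather than returning 0: a negative size here is a
    caller bug, not a tail evaluation.
    """
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam!r}")
    arr = _check_size(s)
    out = lam * np.exp(-lam * arr)
    return out if out.ndim else float(out)


def size_cdf(s, lam: float):
    """Probability of tumor size <= ``s``: ``1 - exp(-lam * s)``."""
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam!r}")
    arr = _check_size(s)
    out = 1.0 - np.exp(-lam * arr)
    return out if out.ndim else float(out)


def size_moments(lam: float) -> tuple[float, float]:
    """Mean (cm) and variance (cm^2) of the size distribution: ``(1/lam, 1/lam^2)``."""
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam!r}")
    return 1.0 / lam, 1.0 / lam**2


def crossing_size(p: ModelParams) -> float | None:
    """Smallest positive size at which the two hazards are equal, or ``None``.

    Root of ``alpha0*(alpha1 - exp(-delta1 s)) = alpha0 + delta2 s``.  The
    difference is strictly concave in ``s``, so it has at most two roots;
    with ``alpha1 = 2`` the difference vanishes at ``s = 0`` and a positive
    root exists iff its initial slope ``alpha0*delta1 - delta2`` is positive.
    Below the crossing transplantation lowers the hazard; above it raises it,
    which is why the optimal cutoff of the mortality curve sits exactly here.
    """
    def f(s: float) -> float:
        return (p.alpha0 * (p.alpha1 - math.exp(-p.delta1 * s))
                - (p.alpha0 + p.delta2 * s))

    slope0 = p.alpha0 * p.delta1 - p.delta2
    f0 = f(0.0)
    # Concave f: increasing up to s_pk (if slope0 > 0), decreasing after.
    s_pk = math.log(p.alpha0 * p.delta1 / p.delta2) / p.delta1 if slope0 > 0 else 0.0

    if abs(f0) < 1e-15:  # hazards coincide at zero (alpha1 = 2)
        if slope0 <= 0:
            return None
        lo = s_pk
    elif f0 > 0:
        lo = 0.0
    else:  # f0 < 0: only crosses if it climbs above zero before the peak
        if slope0 <= 0 or f(s_pk) <= 0:
            return None
        return float(brentq(f, 1e-12, s_pk, xtol=1e-12))

    hi = max(2.0 * lo, 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for valid params
            return None
    return float(brentq(f, lo, hi, xtol=1e-12))


def calibrate_delta1(s_star: float, p: ModelParams) -> float:
    """The ``delta1`` that places the hazard crossing exactly at ``s_star``.

    Inverts the crossing condition:
    ``delta1 = -ln(1 - delta2*s_star / (alpha0*(alpha1-1))) / s_star``.
    Raises if no such crossing is feasible (the linear transplanted hazard
    already exceeds the saturation level of the non-transplanted one).
    """
    if not s_star > 0:
        raise ValueError(f"s_star must be positive, got {s_star!r}")
    arg = 1.0 - p.delta2 * s_star / (p.alpha0 * (p.alpha1 - 1.0))
    if arg <= 0:
        raise ValueError(
            f"no feasible delta1: crossing at s_star={s_star} requires "
            f"alpha0*(alpha1-1) > delta2*s_star"
        )
    return -math.log(arg) / s_star


# ---------------------------------------------------------------------------
# Allocation policies, full-utilization threshold, Milan proportions
# ---------------------------------------------------------------------------

def allocation_densities(s, pol: Policy, c: CohortParams, lam: float):
    """Transplanted and non-transplanted densities ``(x(s), y(s))`` per cm.

    Below the cutoff a fraction ``g(s) * F/N`` of the size density goes to
    the transplanted compartment; above it nothing does.  Always
    ``x(s) + y(s) = p(s)``.
    """
    arr = _check_size(s)
    p_s = size_pdf(arr, lam)
    gvals = pol.bias_at(arr)
    x = np.where(arr <= pol.s0, gvals * (c.F / c.N) * p_s, 0.0)
    y = p_s - x
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def full_utilization_threshold(c: CohortParams, lam: float) -> float:
    """Size cutoff ``s_F`` at which transplanting everyone below it uses all ``F`` grafts.

    Solves ``N * P(size <= s_F) = F``: ``s_F = -ln(1 - F/N) / lam``.
    """
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam!r}")
    if c.F >= c.N:
        raise ValueError("full utilization threshold undefined for F >= N")
    return -math.log(1.0 - c.F / c.N) / lam


@dataclass(frozen=True)
class MilanSummary:
    """Population split under the Milan rule, as proportions of ``N``.

    ``branch`` records which regime applied: ``"scarce"`` when grafts cannot
    cover every tumor below ``S_M`` (``F < N*(1 - exp(-lam*S_M))``), else
    ``"rich"`` — the surplus then reaches tumors above ``S_M``.
    """

    p_nt_below: float
    p_t_below: float
    p_nt_above: float
    p_t_above: float
    branch: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def milan_summary(c: CohortParams, lam: float) -> MilanSummary:
    """Proportions of (non-)transplanted patients below/above the Milan cutoff."""
    frac_below = size_cdf(c.S_M, lam)  # 1 - exp(-lam*S_M)
    tail = 1.0 - frac_below
    fN = c.F / c.N
    if c.F < c.N * frac_below:
        # Liver-scarce: every graft goes below S_M, demand there still unmet.
        return MilanSummary(
            p_nt_below=frac_below - fN,
            p_t_below=fN,
            p_nt_above=tail,
            p_t_above=0.0,
            branch="scarce",
        )
    # Liver-rich: everyone below S_M transplanted; surplus grafts reach the tail.
    return MilanSummary(
        p_nt_below=0.0,
        p_t_below=fN * frac_below,
        p_nt_above=1.0 - fN,
        p_t_above=fN * tail,
        branch="rich",
    )


def grafts_used(s0: float, c: CohortParams, lam: float) -> float:
    """Expected number of grafts consumed by the proportional policy with cutoff ``s0``.

    ``F * (1 - exp(-lam*s0))``: transplanting a fraction ``F/N`` of each size
    class below ``s0`` never uses all ``F`` grafts at a finite cutoff, so a
    policy that expands the cutoff beyond the full-utilization size still
    leaves livers unused.  Reported as a real number (continuum model).
    """
    if not s0 >= 0:
        raise ValueError(f"s0 must be non-negative, got {s0!r}")
    return c.F * size_cdf(s0, lam)


# ---------------------------------------------------------------------------
# Outcome integrals: survivors, total mortality, threshold optimization
# ---------------------------------------------------------------------------

def transplanted_survivors(s0: float, p: ModelParams, c: CohortParams) -> float:
    """Expected transplanted patients (cutoff ``s0``) alive at ``T``.

    ``F * int_0^{s0} lam e^{-lam s} e^{-alpha_t(s) T} ds`` by adaptive
    quadrature.
    """
    if not s0 >= 0:
        raise ValueError(f"s0 must be non-negative, got {s0!r}")
    if s0 == 0:
        return 0.0
    upper = min(s0, -math.log(_TAIL_QUANTILE) / p.lam)

    def integrand(s: float) -> float:
        return p.lam * math.exp(-p.lam * s) * math.exp(-(p.alpha0 + p.delta2 * s) * p.T)

    val, _ = quad(integrand, 0.0, upper, **_QUAD_KW)
    return c.F * val


def transplanted_survivors_closed_form(s0: float, p: ModelParams, c: CohortParams) -> float:
    """Analytic form of :func:`transplanted_survivors`, used as a cross-check.

    ``F e^{-alpha0 T} lam/(lam + delta2 T) (1 - e^{-(lam + delta2 T) s0})``.
    """
    k = p.lam + p.delta2 * p.T
    tail = 0.0 if math.isinf(s0) else math.exp(-k * s0)
    return c.F * math.exp(-p.alpha0 * p.T) * (p.lam / k) * (1.0 - tail)


def nontransplanted_survivors(s0: float, p: ModelParams, c: CohortParams) -> float:
    """Expected non-transplanted patients alive at ``T`` under cutoff ``s0``.

    Sum of the below-cutoff remainder ``N (1 - F/N) int_0^{s0} ...`` and the
    untouched tail ``N int_{s0}^inf ...``.  The tail is integrated exactly on
    the transformed variable ``u = exp(-lam s)`` (finite interval
    ``[0, e^{-lam s0}]``), avoiding arbitrary truncation: under the change of
    variable ``lam e^{-lam s} ds = -du`` and ``e^{-delta1 s} = u^{delta1/lam}``.
    """
    if not s0 >= 0:
        raise ValueError(f"s0 must be non-negative, got {s0!r}")

    ratio = p.delta1 / p.lam

    def tail_integrand(u: float) -> float:
        return math.exp(-p.alpha0 * p.T * (p.alpha1 - u**ratio))

    def body_integrand(s: float) -> float:
        rate = p.alpha0 * (p.alpha1 - math.exp(-p.delta1 * s))
        return p.lam * math.exp(-p.lam * s) * math.exp(-rate * p.T)

    u0 = 0.0 if math.isinf(s0) else math.exp(-p.lam * s0)
    tail, _ = quad(tail_integrand, 0.0, u0, **_QUAD_KW)
    if s0 == 0 or math.isinf(s0):
        body = 0.0 if s0 == 0 else quad(
            tail_integrand, 0.0, 1.0, **_QUAD_KW)[0]  # whole mass via u-variable
    else:
        body, _ = quad(body_integrand, 0.0, s0, **_QUAD_KW)
    return c.N * (1.0 - c.F / c.N) * body + c.N * tail


def total_survivors(s0: float, p: ModelParams, c: CohortParams) -> float:
    """Expected survivors at ``T`` over both compartments."""
    return transplanted_survivors(s0, p, c) + nontransplanted_survivors(s0, p, c)


def total_mortality(s0: float, p: ModelParams, c: CohortParams) -> float:
    """Expected deaths ``M(s0) = N - survivors`` at horizon ``T``."""
    return c.N - total_survivors(s0, p, c)


def mortality_slope(s0: float, p: ModelParams, c: CohortParams) -> float:
    """Derivative ``dM/ds0 = -F lam e^{-lam s0} [pi_t(s0) - pi_nt(s0)]``.

    Negative exactly while transplantation still helps at the margin, so the
    interior minimum of ``M`` sits at the hazard crossing.
    """
    if not s0 >= 0:
        raise ValueError(f"s0 must be non-negative, got {s0!r}")
    diff = survival_transplanted(s0, p) - survival_nontransplanted(s0, p)
    return -c.F * p.lam * math.exp(-p.lam * s0) * diff


@dataclass(frozen=True)
class MortalityCurve:
    """Total deaths, survivors and grafts used on a grid of cutoffs."""

    thresholds: np.ndarray
    deaths: np.ndarray
    survivors: np.ndarray
    grafts: np.ndarray
    params_echo: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s0_cm": self.thresholds,
            "deaths": self.deaths,
            "survivors": self.survivors,
            "grafts_used": self.grafts,
        })

    def argmin(self) -> tuple[float, float]:
        """Grid point with fewest deaths (first one on ties)."""
        i = int(np.argmin(self.deaths))
        return float(self.thresholds[i]), float(self.deaths[i])


def mortality_curve(grid, p: ModelParams, c: CohortParams,
                    params_echo: dict | None = None) -> MortalityCurve:
    """Evaluate ``M(s0)`` and graft usage on an ordered grid of cutoffs.

    ``grid`` is either an explicit ordered array of cutoffs or a
    ``(start, stop, step)`` triple.
    """
    if isinstance(grid, tuple) and len(grid) == 3:
        start, stop, step = grid
        thresholds = np.arange(start, stop + 0.5 * step, step)
    else:
        thresholds = np.asarray(grid, dtype=float)
    if thresholds.size == 0:
        raise ValueError("mortality_curve requires a non-empty grid")
    if np.any(thresholds < 0) or np.any(np.diff(thresholds) <= 0):
        raise ValueError("grid must be ordered, strictly increasing and non-negative")

    surv = np.array([total_survivors(s0, p, c) for s0 in thresholds])
    deaths = c.N - surv
    grafts = np.array([grafts_used(s0, c, p.lam) for s0 in thresholds])
    return MortalityCurve(
        thresholds=thresholds,
        deaths=deaths,
        survivors=surv,
        grafts=grafts,
        params_echo=dict(params_echo or {}),
    )


def optimal_threshold(p: ModelParams, c: CohortParams,
                      grid: tuple[float, float, float] = (0.0, 15.0, 0.05),
                      ) -> tuple[float, float]:
    """Cutoff minimizing total mortality, and the minimum itself.

    Coarse grid search followed by a root solve of ``dM/ds0`` when the
    minimum is interior; ties break to the smallest cutoff; a boundary
    minimum (e.g. ``s* = 0`` when transplantation never helps) is reported
    as-is rather than raising.
    """
    start, stop, step = grid
    thresholds = np.arange(start, stop + 0.5 * step, step)
    deaths = np.array([total_mortality(s0, p, c) for s0 in thresholds])
    i = int(np.argmin(deaths))
    s_star, m_star = float(thresholds[i]), float(deaths[i])

    if 0 < i < thresholds.size - 1:
        lo, hi = float(thresholds[i - 1]), float(thresholds[i + 1])
        f_lo, f_hi = mortality_slope(lo, p, c), mortality_slope(hi, p, c)
        if f_lo < 0 < f_hi:
            s_star = float(brentq(lambda s: mortality_slope(s, p, c), lo, hi, xtol=1e-10))
            m_star = total_mortality(s_star, p, c)
    return s_star, m_star


def equivalent_threshold(p: ModelParams, c: CohortParams,
                         grid: tuple[float, float, float] = (0.0, 15.0, 0.05),
                         ) -> float | None:
    """Cutoff beyond the optimum where mortality returns to its Milan value.

    Root ``s_eq > s*`` of ``M(s) = M(S_M)`` — the largest cutoff expansion
    that does not worsen list-level mortality.  Returns ``None`` (with a
    logged diagnostic) when no such root exists in the populated size range,
    e.g. when the minimum is at the boundary or ``M`` never climbs back.
    """
    s_star, m_star = optimal_threshold(p, c, grid)
    m_ref = total_mortality(c.S_M, p, c)
    if m_star >= m_ref or s_star <= c.S_M:
        logger.info(
            "equivalent threshold undefined: s*=%.4f, M(s*)=%.6f, M(S_M)=%.6f",
            s_star, m_star, m_ref,
        )
        return None

    s_cap = -math.log(_TAIL_QUANTILE) / p.lam  # 1 - 1e-10 size quantile
    hi = max(2.0 * s_star, s_star + 1.0)
    while total_mortality(hi, p, c) < m_ref:
        if hi >= s_cap:
            logger.info(
                "equivalent threshold not bracketed below the %.1f cm size "
                "quantile: M stays below M(S_M)=%.6f", s_cap, m_ref,
            )
            return None
        hi = min(2.0 * hi, s_cap)
    return float(brentq(lambda s: total_mortality(s, p, c) - m_ref,
                        s_star, hi, xtol=1e-8))


# ---------------------------------------------------------------------------
# Monte-Carlo cohort simulation and size-distribution fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimCohort:
    """One simulated waiting-list cohort (the individual-based oracle).

    ``death_time`` is the latent exponential death clock of each patient
    (years); deaths by a horizon ``T`` are simply ``death_time <= T``.
    """

    sizes: np.ndarray
    transplanted: np.ndarray
    death_time: np.ndarray
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size_cm": self.sizes,
            "transplanted": self.transplanted.astype(int),
            "death_time_years": self.death_time,
        })


def sample_cohort(p: ModelParams, c: CohortParams, pol: Policy,
                  seed: int | np.random.SeedSequence | None = None) -> SimCohort:
    """Draw one cohort: exponential sizes, thinned transplant assignment, death clocks.

    Each patient with ``s <= s0`` is transplanted independently with
    probability ``g(s) * F / N``, mirroring the continuum density
    ``x(s) = g(s)(F/N)p(s)``; if the realized count exceeds the integer graft
    supply ``F``, the excess transplants are revoked uniformly at random (and
    logged).  Death times are exponential with the size- and
    status-dependent hazard, the constant-in-time reading of the survival
    model.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.exponential(1.0 / p.lam, size=c.N)
    prob = np.where(sizes <= pol.s0, pol.bias_at(sizes) * (c.F / c.N), 0.0)
    transplanted = rng.random(c.N) < prob

    excess = int(transplanted.sum()) - c.F
    if excess > 0:
        idx = np.flatnonzero(transplanted)
        revoke = rng.choice(idx, size=excess, replace=False)
        transplanted[revoke] = False
        logger.info("revoked %d transplants exceeding graft supply F=%d", excess, c.F)

    rates = np.where(
        transplanted,
        hazard_transplanted(sizes, p),
        hazard_nontransplanted(sizes, p),
    )
    death_time = rng.exponential(1.0 / rates)
    seed_record = seed if isinstance(seed, (int, type(None))) else None
    return SimCohort(sizes=sizes, transplanted=transplanted,
                     death_time=death_time, seed=seed_record)


def simulate_deaths(cohort: SimCohort, T: float) -> int:
    """Number of cohort members dead by the horizon ``T`` (years)."""
    if not T >= 0:
        raise ValueError(f"T must be non-negative, got {T!r}")
    return int(np.count_nonzero(cohort.death_time <= T))


def mc_mortality(s0: float, p: ModelParams, c: CohortParams, reps: int,
                 seed: int | np.random.SeedSequence | None = None,
                 g: BiasFn | None = None) -> tuple[float, float]:
    """Monte-Carlo estimate of ``M(s0)``: mean death count and its standard error.

    Replicate cohorts get child seeds spawned deterministically from one
    master seed, so runs are reproducible bit-for-bit.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    pol = Policy(s0=s0) if g is None else Policy(s0=s0, g=g)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(reps)
    deaths = np.array([
        simulate_deaths(sample_cohort(p, c, pol, child), p.T) for child in children
    ], dtype=float)
    return float(deaths.mean()), float(deaths.std(ddof=1) / math.sqrt(reps))


@dataclass(frozen=True)
class SizeDistFit:
    """Exponential fit of observed tumor sizes.

    ``lambda_hat`` is the maximum-likelihood rate (reciprocal sample mean);
    ``ci95`` a Wald interval on the mean (sd = mean for an exponential);
    ``r_squared`` the goodness of fit between binned relative frequencies
    and the fitted density at bin midpoints.
    """

    lambda_hat: float
    mean_hat: float
    ci95: tuple[float, float]
    n: int
    r_squared: float

    def as_dict(self) -> dict:
        return {
            "lambda_hat": self.lambda_hat,
            "mean_hat": self.mean_hat,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n": self.n,
            "r_squared": self.r_squared,
        }


def fit_size_distribution(sizes, bin_width: float = 1.0,
                          bin_max: float = 12.0) -> SizeDistFit:
    """Fit an exponential to tumor sizes: MLE rate, 95% CI on the mean, binned R^2."""
    arr = np.asarray(sizes, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 tumor sizes to fit")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("tumor sizes must be positive and finite")
    if not bin_width > 0:
        raise ValueError(f"bin_width must be positive, got {bin_width!r}")

    n = int(arr.size)
    mean_hat = float(arr.mean())
    lambda_hat = 1.0 / mean_hat
    half = 1.96 * mean_hat / math.sqrt(n)
    ci95 = (mean_hat - half, mean_hat + half)

    edges = np.arange(0.0, bin_max + bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    dens = counts / (n * bin_width)  # empirical density per cm
    mids = 0.5 * (edges[:-1] + edges[1:])
    pred = lambda_hat * np.exp(-lambda_hat * mids)
    ss_res = float(np.sum((dens - pred) ** 2))
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return SizeDistFit(lambda_hat=lambda_hat, mean_hat=mean_hat, ci95=ci95,
                       n=n, r_squared=r_squared)


# ---------------------------------------------------------------------------
# Scenario runner (library surface behind the CLI)
# ---------------------------------------------------------------------------

def _write_csv(path: Path, frame: pd.DataFrame, echo: dict) -> None:
    """CSV with '#'-prefixed header lines echoing every parameter."""
    with open(path, "w", newline="") as fh:
        for key, val in echo.items():
            fh.write(f"# {key} = {val}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def _write_json(path: Path, payload: dict, echo: dict) -> None:
    payload = dict(payload)
    payload["params"] = echo
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_scenario(cfg: ScenarioConfig, command: str, outdir: str | Path,
                 plot: bool = False) -> dict:
    """Execute one subcommand (curve/optimize/milan/simulate) and write outputs.

    Returns the machine-readable result record.  ``fit`` takes file input and
    is handled by the CLI directly via :func:`fit_size_distribution`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    echo = cfg.params_echo()
    p, c = cfg.model, cfg.cohort

    if command == "curve":
        curve = mortality_curve(cfg.grid, p, c, params_echo=echo)
        frame = curve.to_frame()
        if not np.all(np.isfinite(frame.to_numpy())):
            raise RuntimeError("non-finite value in mortality curve output")
        _write_csv(outdir / "curve.csv", frame, echo)
        if plot:
            _plot_curve(curve, c, p, outdir / "curve.png")
        s_min, m_min = curve.argmin()
        logger.info("curve: grid minimum M(%.3f) = %.4f", s_min, m_min)
        return {"path": str(outdir / "curve.csv"), "s_min": s_min, "m_min": m_min}

    if command == "optimize":
        s_star, m_star = optimal_threshold(p, c, cfg.grid)
        s_eq = equivalent_threshold(p, c, cfg.grid)
        m_ref = total_mortality(c.S_M, p, c)
        result = {
            "s_star_cm": s_star,
            "s_star_rounded_0p1cm": round(s_star, 1),
            "M_star": m_star,
            "s_eq_cm": s_eq,
            "s_eq_rounded_0p1cm": round(s_eq, 1) if s_eq is not None else None,
            "M_at_S_M": m_ref,
        }
        _write_json(outdir / "optimize.json", result, echo)
        return result

    if command == "milan":
        summary = milan_summary(c, p.lam)
        result = summary.as_dict()
        result["s_F_cm"] = full_utilization_threshold(c, p.lam)
        result["grafts_used_at_S_M"] = grafts_used(c.S_M, c, p.lam)
        _write_json(outdir / "milan.json", result, echo)
        return result

    if command == "simulate":
        master = np.random.SeedSequence(cfg.seed)
        children = master.spawn(cfg.reps)
        cohort = sample_cohort(p, c, cfg.policy, children[0])
        _write_csv(outdir / "cohort.csv", cohort.to_frame(), echo)
        deaths = np.array([
            simulate_deaths(sample_cohort(p, c, cfg.policy, child), p.T)
            for child in children
        ], dtype=float)
        summary = pd.DataFrame({
            "replicate": np.arange(cfg.reps),
            "deaths": deaths.astype(int),
            "survivors": (c.N - deaths).astype(int),
        })
        _write_csv(outdir / "replicates.csv", summary, echo)
        mean, se = float(deaths.mean()), float(deaths.std(ddof=1) / math.sqrt(cfg.reps))
        result = {"mean_deaths": mean, "se_deaths": se, "reps": cfg.reps}
        _write_json(outdir / "simulate.json", result, echo)
        return result

    raise ValueError(f"unknown command: {command!r}")


def _plot_curve(curve: MortalityCurve, c: CohortParams, p: ModelParams,
                path: Path) -> None:  # pragma: no cover - optional artifact
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.thresholds, curve.deaths, "k-", lw=1.5)
    m_ref = total_mortality(c.S_M, p, c)
    ax.axhline(m_ref, ls=":", color="gray",
               label=f"M(S_M={c.S_M:g} cm) = {m_ref:.1f}")
    ax.set_xlabel("transplant size cutoff $s_0$ (cm)")
    ax.set_ylabel(f"total deaths at T = {p.T:g} y")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
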