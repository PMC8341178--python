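"""One-way and probabilistic sensitivity analysis.

One-way analysis re-runs the base-case comparison with each parameter set
to the lower and then the upper bound of its published range (95% CI where
one exists, otherwise the 2.5/97.5 band implied by a 20%-of-mean standard
error) and ranks parameters by the spread in net monetary benefit at the
willingness-to-pay threshold — the tornado ordering.

The probabilistic analysis draws every uncertain parameter from its
assigned family — lognormal for odds ratios (parameterised from the Wald
CI on the log scale), beta for probabilities and utilities (method of
moments), zero-truncated normal for costs and transfusion units — and
re-evaluates both strategies per draw. Probabilities derived from odds
ratios (the lusutrombopag arm's transfusion and bleeding risks) are
re-derived per draw from the sampled OR and the sampled reference rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import run_comparison
from .params import ModelParameters, get_param, set_param

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054

__all__ = [
    "OwsaEntry",
    "PsaSummary",
    "fit_psa_distribution",
    "one_way_sa",
    "run_psa",
    "ceac_table",
    "default_ceac_thresholds",
]


# ---------------------------------------------------------------------------
# distribution fitting


@dataclass(frozen=True)
class _Sampler:
    family: str
    mean: float
    draw: Callable[[np.random.Generator, int], np.ndarray]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.draw(rng, n)


def fit_psa_distribution(
    family: str,
    base: float,
    se: float | None = None,
    ci: tuple[float, float] | None = None,
    name: str = "",
) -> _Sampler:
    """Build a sampler for one uncertain parameter.

    ``family`` is ``lognormal_or`` (``ci`` required, on the OR scale),
    ``beta`` (mean/SE method of moments) or ``normal`` (zero-truncated by
    resampling). ``se=None`` falls back to 20% of the base value. A zero SE
    yields a point mass.
    """
    if family == "lognormal_or":
        if base <= 0:
            raise ValueError(f"{name}: odds ratio must be positive")
        if ci is not None:
            lo, hi = ci
            sigma = (math.log(hi) - math.log(lo)) / (2.0 * _Z95)
        else:
            sigma = se if se is not None else 0.2
        mu = math.log(base)
        if sigma == 0.0:
            return _Sampler(family, base, lambda rng, n: np.full(n, base))
        return _Sampler(family, base, lambda rng, n: np.exp(rng.normal(mu, sigma, n)))

    if se is None:
        se = 0.2 * base

    if family == "beta":
        if not 0.0 <= base <= 1.0:
            raise ValueError(f"{name}: beta mean {base} outside [0,1]")
        if se == 0.0 or base in (0.0, 1.0):
            return _Sampler(family, base, lambda rng, n: np.full(n, base))
        if se * se >= base * (1.0 - base):
            raise ValueError(
                f"{name}: beta moments infeasible (SE^2={se*se:.3g} >= "
                f"m(1-m)={base*(1-base):.3g})"
            )
        alpha = base * (base * (1.0 - base) / (se * se) - 1.0)
        beta = alpha * (1.0 - base) / base
        return _Sampler(family, base, lambda rng, n: rng.beta(alpha, beta, n))

    if family == "normal":
        if base < 0:
            raise ValueError(f"{name}: truncated normal requires a non-negative mean")
        if se == 0.0:
            return _Sampler(family, base, lambda rng, n: np.full(n, base))

        def draw(rng: np.random.Generator, n: int, m=base, s=se) -> np.ndarray:
            out = rng.normal(m, s, n)
            bad = out < 0.0
            while bad.any():  # resample below-zero draws
                out[bad] = rng.normal(m, s, int(bad.sum()))
                bad = out < 0.0
            return out

        return _Sampler(family, base, draw)

    raise ValueError(f"{name}: unknown distribution family {family!r}")


def _sampler_for(params: ModelParameters, pid: str) -> _Sampler:
    spec = params.psa_spec[pid]
    family = spec["family"]
    base = get_param(params, pid)
    se_spec = spec.get("se", "frac20")
    if family == "lognormal_or":
        est = params.transitions.or_prePT if pid == "or_prePT" else params.transitions.or_bleed
        return fit_psa_distribution(family, base, ci=(est.ci_lower, est.ci_upper), name=pid)
    if se_spec == "ci":
        lo, hi = params.owsa_ranges[pid]
        se = (hi - lo) / (2.0 * _Z95)
    elif se_spec == "frac20":
        se = 0.2 * base
    else:
        se = float(se_spec)
    return fit_psa_distribution(family, base, se=se, name=pid)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass
class OwsaEntry:
    parameter: str
    base: float
    low: float
    high: float
    nmb_low: float
    nmb_high: float

    @property
    def range(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _nmb_with(params: ModelParameters, pid: str, value: float) -> float:
    p = params.copy_deep()
    set_param(p, pid, value)
    return run_comparison(p).nmb_at_threshold


def one_way_sa(params: ModelParameters) -> list[OwsaEntry]:
    """Tornado entries for every parameter with a published range,
    sorted by descending NMB range."""
    entries = []
    for pid in params.owsa_ranges:
        lo, hi = params.owsa_ranges[pid]
        entries.append(
            OwsaEntry(
                parameter=pid,
                base=get_param(params, pid),
                low=lo,
                high=hi,
                nmb_low=_nmb_with(params, pid, lo),
                nmb_high=_nmb_with(params, pid, hi),
            )
        )
    for pid in params.psa_spec:
        if pid not in params.owsa_ranges:
            logger.info("one-way SA: %s has no published range; skipped", pid)
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return entries


def owsa_table(entries: Sequence[OwsaEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "base": [e.base for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "nmb_low": [e.nmb_low for e in entries],
            "nmb_high": [e.nmb_high for e in entries],
            "range": [e.range for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PsaSummary:
    """Per-draw increments and the headline probabilities they imply."""

    n_iter: int
    seed: int
    p_dominant: float
    acceptability: dict[float, float]
    draws: pd.DataFrame  # one row per iteration: sampled values, delta_cost, delta_qaly

    @property
    def wtp_acceptability(self) -> float:
        return self.acceptability[min(self.acceptability, key=lambda t: abs(t - 5e6))]


def default_ceac_thresholds(upper: float = 1e7, n: int = 41) -> np.ndarray:
    return np.linspace(0.0, upper, n)


def run_psa(
    params: ModelParameters,
    n_iter: int | None = None,
    seed: int | None = None,
    thresholds: Sequence[float] | None = None,
) -> PsaSummary:
    """Monte-Carlo uncertainty analysis of the two-strategy comparison.

    Fully reproducible for a fixed ``(seed, n_iter)``: parameters are
    sampled in sorted-id order from a single seeded generator.
    """
    n_iter = params.settings.psa_iterations if n_iter is None else n_iter
    seed = params.settings.rng_seed if seed is None else seed
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)

    pids = sorted(params.psa_spec)
    samples = {pid: _sampler_for(params, pid).sample(rng, n_iter) for pid in pids}

    dc = np.empty(n_iter)
    dq = np.empty(n_iter)
    for i in range(n_iter):
        p = params.copy_deep()
        for pid in pids:
            set_param(p, pid, float(samples[pid][i]))
        res = run_comparison(p)
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly

    draws = pd.DataFrame({pid: samples[pid] for pid in pids})
    draws.insert(0, "iteration", np.arange(n_iter))
    draws["delta_cost"] = dc
    draws["delta_qaly"] = dq

    if thresholds is None:
        thresholds = default_ceac_thresholds()
    thresholds = list(dict.fromkeys([*thresholds, params.settings.wtp_threshold]))
    acceptability = {
        float(lam): float(np.mean(lam * dq - dc > 0.0)) for lam in thresholds
    }
    return PsaSummary(
        n_iter=n_iter,
        seed=seed,
        p_dominant=float(np.mean((dc < 0.0) & (dq > 0.0))),
        acceptability=acceptability,
        draws=draws,
    )


def ceac_table(summary: PsaSummary, thresholds: Sequence[float]) -> dict[float, float]:
    """Acceptability (probability of positive NMB) at each threshold."""
    if summary.draws.empty:
        raise ValueError("PSA summary contains no draws")
    dq = summary.draws["delta_qaly"].to_numpy()
    dc = summary.draws["delta_cost"].to_numpy()
    return {float(lam): float(np.mean(lam * dq - dc > 0.0)) for lam in thresholds}
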