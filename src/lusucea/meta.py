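"""Random-effects pooling of odds ratios from two-arm binary trials.

The treatment-effect inputs of the cost-effectiveness model are pooled
odds ratios from placebo-controlled trials. This module implements the
moment-based DerSimonian-Laird estimator on the log-odds-ratio scale:
per-study log-ORs with 1/a + 1/b + 1/c + 1/d variances, Cochran's Q,
tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1)) with S_r the sums of weight
powers, and an inverse-variance pool with weights 1/(v_i + tau^2). The
confidence interval is Wald on the log scale with z = 1.96.

A Haldane-Anscombe continuity correction (add 0.5 to all four cells) is
applied only when a study has an empty cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field, model_validator

_Z95 = 1.959963984540054

__all__ = ["Study2x2", "PooledEffect", "study_log_or", "pool_dersimonian_laird"]


class Study2x2(BaseModel):
    """Event counts of one two-arm trial with a binary outcome."""

    model_config = ConfigDict(extra="forbid")

    label: str
    events_treat: int = Field(ge=0)
    n_treat: int = Field(gt=0)
    events_ctrl: int = Field(ge=0)
    n_ctrl: int = Field(gt=0)

    @model_validator(mode="after")
    def _counts(self) -> "Study2x2":
        if self.events_treat > self.n_treat or self.events_ctrl > self.n_ctrl:
            raise ValueError("event counts cannot exceed arm sizes")
        return self


@dataclass(frozen=True)
class PooledEffect:
    """A pooled odds ratio on both the log and natural scales."""

    log_or: float
    se_log_or: float
    tau2: float
    q: float
    k_studies: int

    @property
    def or_point(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_lower(self) -> float:
        return math.exp(self.log_or - _Z95 * self.se_log_or)

    @property
    def ci_upper(self) -> float:
        return math.exp(self.log_or + _Z95 * self.se_log_or)


def study_log_or(study: Study2x2, continuity: float = 0.5) -> tuple[float, float]:
    """Log odds ratio and its variance for one study.

    ``continuity`` is added to all four cells if (and only if) any cell is
    zero; with ``continuity=0`` a zero cell raises, since the estimate is
    infinite.
    """
    if continuity < 0:
        raise ValueError("continuity correction must be non-negative")
    a = float(study.events_treat)
    b = float(study.n_treat - study.events_treat)
    c = float(study.events_ctrl)
    d = float(study.n_ctrl - study.events_ctrl)
    if min(a, b, c, d) == 0.0:
        if continuity == 0.0:
            raise ValueError(
                f"study {study.label!r} has an empty cell; the log odds ratio "
                "is infinite without a continuity correction"
            )
        a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
    log_or = math.log(a * d / (b * c))
    variance = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return log_or, variance


def pool_dersimonian_laird(
    studies: list[Study2x2], continuity: float = 0.5
) -> PooledEffect:
    """DerSimonian-Laird random-effects pool of study odds ratios."""
    if not studies:
        raise ValueError("at least one study is required")
    yv = [study_log_or(s, continuity) for s in studies]
    k = len(yv)

    w = [1.0 / v for _, v in yv]
    s1 = sum(w)
    fixed = sum(wi * yi for wi, (yi, _) in zip(w, yv)) / s1
    q = sum(wi * (yi - fixed) ** 2 for wi, (yi, _) in zip(w, yv))
    if k == 1:
        tau2 = 0.0
    else:
        s2 = sum(wi * wi for wi in w)
        denom = s1 - s2 / s1
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0

    w_re = [1.0 / (v + tau2) for _, v in yv]
    s_re = sum(w_re)
    pooled = sum(wi * yi for wi, (yi, _) in zip(w_re, yv)) / s_re
    return PooledEffect(
        log_or=pooled,
        se_log_or=math.sqrt(1.0 / s_re),
        tau2=tau2,
        q=q,
        k_studies=k,
    )
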