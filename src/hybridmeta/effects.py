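"""Effect-size conversions and sampling variances.

Raw summary statistics (t values and sample sizes, or correlations) are
converted onto an analysis scale on which all estimation happens: Hedges'
g for mean differences, Fisher's z for correlations. Each converted effect
carries its sampling variance and, for mean designs, the degrees of
freedom and noncentrality mapping needed by the exact t-distribution
probability backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Design(str, Enum):
    """Supported study designs."""

    TWO_SAMPLE_MEANS = "two_sample_means"
    ONE_SAMPLE_MEAN = "one_sample_mean"
    CORRELATION = "correlation"


class Metric(str, Enum):
    """Analysis scale a converted effect lives on."""

    HEDGES_G = "hedges_g"
    FISHER_Z = "fisher_z"


def small_sample_correction(df: int) -> float:
    """Hedges' small-sample correction factor J = 1 - 3/(4*df - 1).

    J is strictly between 0 and 1 for df >= 1, increases with df and
    tends to 1, so the corrected g tends to Cohen's d in large samples.
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


@dataclass(frozen=True)
class EffectEstimate:
    """A study's effect on the analysis scale.

    Parameters
    ----------
    metric
        Analysis scale (Hedges' g or Fisher z).
    y
        Effect value on the analysis scale.
    variance
        Sampling variance of ``y`` (treated as known downstream, the
        standard meta-analytic convention).
    df
        Degrees of freedom of the underlying t test (mean designs only).
    t_obs
        Observed t statistic (mean designs only).
    correction_J
        Small-sample correction factor applied to obtain g.
    ncp_scale
        Multiplier mapping a Cohen's-d-scale effect to the noncentrality
        parameter of the t statistic: ``ncp = (theta / J) * ncp_scale``.
        Equals sqrt(n1*n2/(n1+n2)) for two-group designs, sqrt(n) for
        one-group designs.
    n_effective
        Per-design record of the sample sizes.
    """

    metric: Metric
    y: float
    variance: float
    df: Optional[int] = None
    t_obs: Optional[float] = None
    correction_J: Optional[float] = None
    ncp_scale: Optional[float] = None
    n_effective: tuple = field(default=())

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"sampling variance must be positive, got {self.variance}")
        if self.metric is Metric.HEDGES_G:
            if self.df is None or self.t_obs is None or self.correction_J is None:
                raise ValueError("mean-design effects need df, t_obs and correction_J")
            if not 0 < self.correction_J < 1:
                raise ValueError(f"correction factor J out of (0, 1): {self.correction_J}")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    def mirrored(self) -> "EffectEstimate":
        """The same effect with its sign flipped (direction normalization)."""
        t = None if self.t_obs is None else -self.t_obs
        return EffectEstimate(
            metric=self.metric, y=-self.y, variance=self.variance, df=self.df,
            t_obs=t, correction_J=self.correction_J, ncp_scale=self.ncp_scale,
            n_effective=self.n_effective,
        )

    def to_report_scale(self, value: Optional[float] = None) -> float:
        """Back-transform an analysis-scale value for reporting.

        Fisher-z effects are reported as correlations; Hedges' g is its own
        report scale. The round trip report -> analysis is the identity.
        """
        v = self.y if value is None else value
        if self.metric is Metric.FISHER_Z:
            return math.tanh(v)
        return v


@dataclass(frozen=True)
class StudySummary:
    """User-facing summary statistics of a single study.

    Exactly the fields required by ``design`` must be present:

    * ``two_sample_means``: ``t`` with ``n1``/``n2`` (or per-group means
      and SDs from which t is derived),
    * ``one_sample_mean``: ``t`` and ``n`` (or ``mean1``/``sd1``),
    * ``correlation``: ``r`` and ``n``.
    """

    design: Design
    t: Optional[float] = None
    n1: Optional[int] = None
    n2: Optional[int] = None
    n: Optional[int] = None
    r: Optional[float] = None
    mean1: Optional[float] = None
    mean2: Optional[float] = None
    sd1: Optional[float] = None
    sd2: Optional[float] = None

    def __post_init__(self) -> None:
        design = Design(self.design)
        object.__setattr__(self, "design", design)
        if design is Design.TWO_SAMPLE_MEANS:
            if self.n1 is None or self.n2 is None:
                raise ValueError("two-sample design needs n1 and n2")
            if self.n1 < 2 or self.n2 < 2:
                raise ValueError("group sizes must be >= 2")
            derived = self._derived_t()
            if self.t is None:
                if derived is None:
                    raise ValueError("supply t or per-group means and SDs")
                object.__setattr__(self, "t", derived)
            elif derived is not None and abs(derived - self.t) > 1e-10:
                raise ValueError(
                    f"t derived from means/SDs ({derived:.12g}) disagrees with "
                    f"stored t ({self.t:.12g})"
                )
        elif design is Design.ONE_SAMPLE_MEAN:
            if self.n is None or self.n < 2:
                raise ValueError("one-sample design needs n >= 2")
            derived = self._derived_t()
            if self.t is None:
                if derived is None:
                    raise ValueError("supply t or mean1 and sd1")
                object.__setattr__(self, "t", derived)
            elif derived is not None and abs(derived - self.t) > 1e-10:
                raise ValueError("t derived from mean1/sd1 disagrees with stored t")
        elif design is Design.CORRELATION:
            if self.r is None or self.n is None:
                raise ValueError("correlation design needs r and n")
            if not abs(self.r) < 1:
                raise ValueError(f"|r| must be < 1, got {self.r}")
            if self.n < 4:
                raise ValueError("correlation design needs n >= 4 (so n - 3 > 0)")

    def _derived_t(self) -> Optional[float]:
        if self.design is Design.TWO_SAMPLE_MEANS:
            if None in (self.mean1, self.mean2, self.sd1, self.sd2):
                return None
            n1, n2 = self.n1, self.n2
            sp2 = ((n1 - 1) * self.sd1**2 + (n2 - 1) * self.sd2**2) / (n1 + n2 - 2)
            return (self.mean1 - self.mean2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        if self.design is Design.ONE_SAMPLE_MEAN:
            if None in (self.mean1, self.sd1):
                return None
            return self.mean1 / (self.sd1 / math.sqrt(self.n))
        return None

    def to_effect(self) -> EffectEstimate:
        """Convert to an :class:`EffectEstimate` on the analysis scale."""
        if self.design is Design.TWO_SAMPLE_MEANS:
            return g_from_t(self.t, self.n1, self.n2)
        if self.design is Design.ONE_SAMPLE_MEAN:
            return one_sample_g_from_t(self.t, self.n)
        return z_from_r(self.r, self.n)


def g_from_t(t: float, n1: int, n2: int) -> EffectEstimate:
    """Hedges' g from a two-independent-groups t statistic.

    g = J * t * sqrt(1/n1 + 1/n2) with df = n1 + n2 - 2 and
    J = 1 - 3/(4*df - 1). The sampling variance comes from
    :func:`g_variance`.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes must be >= 2, got n1={n1}, n2={n2}")
    df = n1 + n2 - 2
    J = small_sample_correction(df)
    g = J * t * math.sqrt(1.0 / n1 + 1.0 / n2)
    return EffectEstimate(
        metric=Metric.HEDGES_G,
        y=g,
        variance=g_variance(g, n1, n2),
        df=df,
        t_obs=t,
        correction_J=J,
        ncp_scale=math.sqrt(n1 * n2 / (n1 + n2)),
        n_effective=(n1, n2),
    )


def g_variance(g: float, n1: int, n2: int) -> float:
    """Unbiased sampling variance of a two-group Hedges' g.

    1/n1 + 1/n2 + (1 - (m - 2) / (m * J^2)) * g^2  with  m = n1 + n2 - 2.

    At g = 0 this reduces to 1/n1 + 1/n2; the g^2 term is strictly
    positive otherwise. Its reciprocal is the inverse-variance weight used
    in fixed-effect pooling.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes must be >= 2, got n1={n1}, n2={n2}")
    m = n1 + n2 - 2
    J = small_sample_correction(m)
    return 1.0 / n1 + 1.0 / n2 + (1.0 - (m - 2) / (m * J**2)) * g**2


def one_sample_g_from_t(t: float, n: int) -> EffectEstimate:
    """Hedges' g from a one-sample t statistic.

    One-group analogue of :func:`g_from_t`: g = J * t / sqrt(n) with
    df = n - 1 and variance 1/n + (1 - (n - 3)/((n - 1) * J^2)) * g^2.
    """
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    df = n - 1
    J = small_sample_correction(df)
    g = J * t / math.sqrt(n)
    variance = 1.0 / n + (1.0 - (n - 3) / ((n - 1) * J**2)) * g**2
    return EffectEstimate(
        metric=Metric.HEDGES_G,
        y=g,
        variance=variance,
        df=df,
        t_obs=t,
        correction_J=J,
        ncp_scale=math.sqrt(n),
        n_effective=(n,),
    )


def z_from_r(r: float, n: int) -> EffectEstimate:
    """Fisher-transformed correlation with variance 1/(n - 3).

    The variance does not depend on r, which is what makes the Fisher
    scale the convenient normal-theory scale for correlations.
    """
    if not abs(r) < 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    return EffectEstimate(
        metric=Metric.FISHER_Z,
        y=math.atanh(r),
        variance=1.0 / (n - 3),
        n_effective=(n,),
    )
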