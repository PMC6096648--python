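"""Conditional probabilities, the x statistic, and its null distribution.

The engine turns a (significant original, replication) pair into two
probabilities evaluated at a hypothesized common effect theta:

* ``q_O`` — the probability of an effect at least as large as the
  original's, *conditional on the original being significant*. This is
  the truncated-distribution probability-integral transform that undoes
  the winner's curse: at the true theta it is uniform on (0, 1) no matter
  how severe the selection.
* ``q_R`` — the plain upper-tail probability of the replication, uniform
  at the true theta because the replication was never selected.

Their sum ``x = q_O + q_R`` follows the two-term Irwin-Hall distribution
at the true theta, which supplies the test, the point estimate (x = 1)
and test-inversion confidence limits.

Two sampling backends are provided: exact noncentral-t probabilities for
mean designs (the scale on which the t statistics were actually
computed), and normal-theory probabilities on the analysis scale, the
standard meta-analytic assumption and the one used for Fisher-z
correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, ndtri

from .effects import EffectEstimate

__all__ = [
    "Backend",
    "SignificanceRule",
    "StudyPair",
    "HybridDiagnostics",
    "NonSignificantOriginalError",
    "critical_value",
    "cond_prob_original",
    "prob_replication",
    "x_statistic",
    "irwin_hall_cdf",
    "irwin_hall_quantile",
    "irwin_hall_two_tailed",
]

_Q_FLOOR = 1e-300


class Backend(str, Enum):
    AUTO = "auto"
    NORMAL = "normal"
    NCT = "nct"


class NonSignificantOriginalError(ValueError):
    """The original study does not pass the significance rule it was
    assumed to have been selected on."""


@dataclass(frozen=True)
class SignificanceRule:
    """Two-tailed significance rule that selected the original study.

    ``alpha`` is the two-tailed level (default .05); selection is
    effectively one-tailed at ``alpha / 2`` because only effects in the
    predicted direction count as successes.
    """

    alpha: float = 0.05
    direction: str = "positive"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"direction must be positive or negative, got {self.direction}")

    @property
    def one_tailed_alpha(self) -> float:
        return self.alpha / 2.0


def _resolve_backend(original: EffectEstimate, backend: Backend) -> Backend:
    backend = Backend(backend)
    if backend is not Backend.AUTO:
        return backend
    return Backend.NCT if original.df is not None else Backend.NORMAL


def critical_value(original: EffectEstimate, rule: SignificanceRule,
                   backend: Backend = Backend.AUTO) -> float:
    """Selection threshold of the original study, independent of theta.

    Normal backend: on the effect scale, z_{1-alpha/2} * SE. Noncentral-t
    backend: the central-t quantile on the t scale.
    """
    backend = _resolve_backend(original, backend)
    if backend is Backend.NCT:
        if original.df is None:
            raise ValueError("t backend needs degrees of freedom")
        return float(stats.t.ppf(1.0 - rule.one_tailed_alpha, original.df))
    return float(-ndtri(rule.one_tailed_alpha) * original.se)


# ---------------------------------------------------------------------------
# Guarded noncentral-t tails.
#
# scipy's nct.logsf (Boost) degrades for strongly negative noncentrality:
# it can return -0.0 (claiming a tail mass of 1) or -inf where the true
# log tail is merely very negative. The moment-matched normal
# approximation to the t tail below is smooth and monotone in ncp, so it
# serves as both a sanity bound and a fallback, keeping x(theta) monotone
# over the whole bisection bracket.
# ---------------------------------------------------------------------------

_SCIPY_TRUST_FLOOR = -25.0  # trust boost's nct tail down to ~1e-11
_QUAD_POINTS = 600


def _nct_logsf_quad(t: float, df: float, ncp: float) -> float:
    """log P(T(df, ncp) >= t) by log-space quadrature.

    Writes T = (Z + ncp) / W with W = sqrt(chi2_df / df) and integrates
    log[f_W(w) * Phi_bar(t*w - ncp)] with a trapezoid rule over W's
    effective support. Entirely in log space, so it stays accurate for
    tails far below the double-precision underflow of the direct CDF.
    """
    w_dist = stats.chi(df, scale=1.0 / math.sqrt(df))
    w = np.linspace(w_dist.ppf(1e-13), w_dist.isf(1e-13), _QUAD_POINTS)
    log_f = w_dist.logpdf(w) + log_ndtr(-(t * w - ncp))
    log_f[0] -= math.log(2.0)
    log_f[-1] -= math.log(2.0)  # trapezoid end weights
    m = float(np.max(log_f))
    if not math.isfinite(m):
        return -math.inf
    return m + math.log(float(np.sum(np.exp(log_f - m))) * (w[1] - w[0]))


def _nct_logsf(t: float, df: float, ncp: float) -> float:
    """Guarded log upper tail of the noncentral t.

    scipy (Boost) is used where its value is comfortably representable;
    below that it oscillates or saturates (returning -inf, -0.0, or
    finite-but-wrong values), so the quadrature evaluator takes over.
    """
    val = float(stats.nct.logsf(t, df, ncp))
    if math.isfinite(val) and _SCIPY_TRUST_FLOOR < val <= 0.0:
        return val
    return _nct_logsf_quad(t, df, ncp)


def _nct_log_tail_ratio(t_num: float, t_den: float, df: float, ncp: float) -> float:
    """log of P(T >= t_num) / P(T >= t_den), num and den from the *same*
    evaluator so the ratio stays monotone in ncp across the scipy /
    quadrature handover."""
    num = float(stats.nct.logsf(t_num, df, ncp))
    den = float(stats.nct.logsf(t_den, df, ncp))
    ok = (math.isfinite(num) and _SCIPY_TRUST_FLOOR < num <= 0.0
          and math.isfinite(den) and _SCIPY_TRUST_FLOOR < den <= 0.0)
    if not ok:
        num = _nct_logsf_quad(t_num, df, ncp)
        den = _nct_logsf_quad(t_den, df, ncp)
    return num - den


def _nct_sf(t: float, df: float, ncp: float) -> float:
    val = float(stats.nct.sf(t, df, ncp))
    if not math.isfinite(val):
        return math.exp(_nct_logsf_approx(t, df, ncp))
    return min(max(val, 0.0), 1.0)


@dataclass(frozen=True)
class StudyPair:
    """A significant original study paired with its replication.

    Construction enforces the method's selection assumption: the original
    must be significant in the predicted direction under ``rule``
    (``force=True`` bypasses the check for exploration, flagging the pair
    as outside the method's assumptions). If the predicted direction is
    negative both effects are mirrored so the analysis always runs on the
    positive side; estimators mirror their results back.
    """

    original: EffectEstimate
    replication: EffectEstimate
    rule: SignificanceRule = field(default_factory=SignificanceRule)
    backend: Backend = Backend.AUTO
    force: bool = False
    mirrored: bool = field(init=False, default=False)
    critical_value: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.original.metric is not self.replication.metric:
            raise ValueError("original and replication must share a metric")
        if self.rule.direction == "negative":
            object.__setattr__(self, "original", self.original.mirrored())
            object.__setattr__(self, "replication", self.replication.mirrored())
            object.__setattr__(self, "mirrored", True)
        object.__setattr__(self, "backend", _resolve_backend(self.original, self.backend))
        cv = critical_value(self.original, self.rule, self.backend)
        object.__setattr__(self, "critical_value", cv)
        if not self.force and not self._is_significant():
            raise NonSignificantOriginalError(
                "the original study is not statistically significant in the "
                f"predicted direction at two-tailed alpha={self.rule.alpha}; "
                "the hybrid method assumes selection on significance "
                "(use force=True to override)"
            )

    def _is_significant(self) -> bool:
        if self.backend is Backend.NCT:
            return self.original.t_obs >= self.critical_value
        return self.original.y >= self.critical_value

    def original_p_two_tailed(self) -> float:
        """Two-tailed p of the original under the pair's backend."""
        if self.backend is Backend.NCT:
            return float(2.0 * stats.t.sf(abs(self.original.t_obs), self.original.df))
        z = abs(self.original.y) / self.original.se
        return float(2.0 * stats.norm.sf(z))

    def _ncp(self, effect: EffectEstimate, theta: float) -> float:
        return (theta / effect.correction_J) * effect.ncp_scale


@dataclass(frozen=True)
class HybridDiagnostics:
    """q_O, q_R and their sum x, all evaluated at ``theta_at``."""

    q_O: float
    q_R: float
    theta_at: float

    @property
    def x(self) -> float:
        return self.q_O + self.q_R


def cond_prob_original(pair: StudyPair, theta: float) -> float:
    """Conditional upper-tail probability q_O of the original study.

    Ratio of the tail beyond the observed effect to the tail beyond the
    critical value, both at hypothesized effect theta. Computed in log
    space so the ratio survives theta values where both tails underflow;
    clipped into [1e-300, 1].
    """
    o = pair.original
    if pair.backend is Backend.NCT:
        ncp = pair._ncp(o, theta)
        log_q = _nct_log_tail_ratio(o.t_obs, pair.critical_value, o.df, ncp)
    else:
        a = 1.0 / o.se
        log_num = float(log_ndtr(a * (theta - o.y)))
        log_den = float(log_ndtr(a * (theta - pair.critical_value)))
        log_q = log_num - log_den
    log_q = min(log_q, 0.0)
    if not math.isfinite(log_q):
        return _Q_FLOOR
    return max(math.exp(log_q), _Q_FLOOR)


def prob_replication(pair: StudyPair, theta: float) -> float:
    """Upper-tail probability q_R of the replication at theta."""
    r = pair.replication
    if pair.backend is Backend.NCT:
        return _nct_sf(r.t_obs, r.df, pair._ncp(r, theta))
    return float(stats.norm.sf((r.y - theta) / r.se))


def x_statistic(pair: StudyPair, theta: float) -> HybridDiagnostics:
    """q_O, q_R and x = q_O + q_R at theta.

    x lies in [0, 2] and is non-decreasing in theta: raising the
    hypothesized effect inflates every upper-tail probability.
    """
    return HybridDiagnostics(
        q_O=cond_prob_original(pair, theta),
        q_R=prob_replication(pair, theta),
        theta_at=theta,
    )


# ---------------------------------------------------------------------------
# Irwin-Hall distribution of the sum of two independent standard uniforms
# ---------------------------------------------------------------------------

ArrayLike = Union[float, np.ndarray]


def irwin_hall_cdf(x: ArrayLike) -> ArrayLike:
    """CDF of the sum of two independent U(0,1) variables.

    F(x) = x^2/2 on [0, 1] and -x^2/2 + 2x - 1 on [1, 2]; inputs are
    clipped into [0, 2] to absorb floating-point noise in x.
    """
    xv = np.clip(np.asarray(x, dtype=float), 0.0, 2.0)
    out = np.where(xv <= 1.0, 0.5 * xv * xv, -0.5 * xv * xv + 2.0 * xv - 1.0)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def irwin_hall_quantile(p: ArrayLike) -> ArrayLike:
    """Inverse of :func:`irwin_hall_cdf` in closed form.

    sqrt(2p) for p <= 1/2, else 2 - sqrt(2(1-p)).
    """
    pv = np.asarray(p, dtype=float)
    if np.any((pv < 0.0) | (pv > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.where(pv <= 0.5, np.sqrt(2.0 * pv), 2.0 - np.sqrt(2.0 * (1.0 - pv)))
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def irwin_hall_two_tailed(x: ArrayLike) -> ArrayLike:
    """Two-tailed fold of the Irwin-Hall CDF: G(x) = 2 min(F(x), 1 - F(x)).

    Closed form x^2 on [0, 1] and (2 - x)^2 on [1, 2]; symmetric about
    x = 1 where it attains its maximum of 1.
    """
    xv = np.clip(np.asarray(x, dtype=float), 0.0, 2.0)
    out = np.where(xv <= 1.0, xv * xv, (2.0 - xv) ** 2)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out
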