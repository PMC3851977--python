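"""Grid posteriors on variant allele frequency.

The model: a sequenced site yields ``m`` reads of which ``n`` support the
variant allele.  Reads are misread with probability ``e``, so the chance of
observing a variant base is ``f + e - 2ef`` for true allele frequency ``f``.
The read error ``e`` is a nuisance parameter, uniform on ``[0, E]`` with
``E = 10**(-Q/10)`` derived from the average Phred quality ``Q`` of the
variant-supporting bases.  Marginalising ``e`` gives the averaged binomial
kernel

    B_{m,n}(a, b) = 1/(b-a) * integral_a^b x**n (1-x)**(m-n) dx

evaluated at ``a = f`` and ``b = f + E - 2Ef``.  Posteriors live on a
discrete frequency grid (1% resolution by default); hypotheses are subsets
of grid frequencies and credible sets collect the top-posterior frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import betainc, betaln

# ---------------------------------------------------------------------------
# Package-wide defaults
# ---------------------------------------------------------------------------

#: Frequency-grid spacing (1% resolution).
DEFAULT_RESOLUTION = 0.01
#: Per-site confidence level for presence/difference decisions.  With about
#: 10**7 tested positions, (1 - alpha)**N stays close to 1 for alpha = 1e-6,
#: a Bonferroni-style argument.
DEFAULT_ALPHA = 1e-6
#: Minimum frequency for a variant to be declared present.
DEFAULT_F_CUT = 0.01
#: Minimum tumor-minus-normal frequency difference for a somatic/LOH call.
DEFAULT_D_CUT = 0.10
#: Phred quality assumed for the error window when no variant base exists
#: (n = 0) to average a quality over.
DEFAULT_FLOOR_QUALITY = 20.0
#: Probability vectors must sum to 1 within this tolerance.
NORMALIZATION_TOL = 1e-9

#: Support of the three-point (diploid zygosity) prior.
THREE_POINT_VALUES = (0.0, 0.5, 1.0)

# Relative size below which the difference of regularized incomplete-beta
# values has lost more than half of its significand to cancellation.
_CANCEL_TOL = math.sqrt(np.finfo(float).eps)

# Fixed-order Gauss-Legendre rule used when the incomplete-beta difference
# is unstable; 64 nodes are ample for polynomial integrands of degree <= m.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyGrid:
    """Evenly spaced allele-frequency grid from 0 to 1 inclusive."""

    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if not 0.0 < self.resolution <= 1.0:
            raise ValueError(f"resolution must be in (0, 1], got {self.resolution}")
        steps = 1.0 / self.resolution
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(f"1/resolution must be an integer, got {self.resolution}")

    @property
    def n_values(self) -> int:
        return round(1.0 / self.resolution) + 1

    @property
    def values(self) -> np.ndarray:
        # rounded to the canonical decimals so grid values survive text
        # round trips exactly
        return np.round(np.linspace(0.0, 1.0, self.n_values), 12)


@dataclass(frozen=True)
class GridDistribution:
    """Probability vector over an ordered support of frequencies in [0, 1].

    Holds priors p(f) and posteriors P(f).  The support is usually the full
    1% grid but may be restricted (e.g. the three-point diploid support
    {0, 1/2, 1}).
    """

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)
        if values.ndim != 1 or values.shape != weights.shape:
            raise ValueError("values and weights must be 1-D and of equal length")
        if values.size == 0:
            raise ValueError("empty support")
        if values[0] < 0.0 or values[-1] > 1.0 or np.any(np.diff(values) <= 0):
            raise ValueError("support must be strictly increasing within [0, 1]")
        if np.any(weights < 0):
            raise ValueError("negative probability weight")
        total = float(weights.sum())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValueError(f"weights sum to {total!r}, not 1")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_unnormalized(
        cls, values: np.ndarray, weights: np.ndarray
    ) -> "GridDistribution":
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        if not np.isfinite(total) or total <= 0.0:
            raise ValueError("cannot normalize: total mass is zero or non-finite")
        return cls(np.asarray(values, dtype=float), weights / total)

    @classmethod
    def uniform(cls, grid: FrequencyGrid | None = None) -> "GridDistribution":
        grid = grid or FrequencyGrid()
        values = grid.values
        return cls(values, np.full(values.size, 1.0 / values.size))

    @classmethod
    def point_mass(
        cls, at: float, grid: FrequencyGrid | None = None
    ) -> "GridDistribution":
        grid = grid or FrequencyGrid()
        values = grid.values
        idx = _index_of(values, at)
        weights = np.zeros(values.size)
        weights[idx] = 1.0
        return cls(values, weights)

    @classmethod
    def three_point(cls, p_ref: float, p_het: float, p_hom: float) -> "GridDistribution":
        """Distribution on the diploid support {0, 1/2, 1}."""
        return cls.from_unnormalized(
            np.array(THREE_POINT_VALUES), np.array([p_ref, p_het, p_hom])
        )

    # -- helpers ------------------------------------------------------------

    @property
    def resolution(self) -> float:
        spacing = np.diff(self.values)
        if spacing.size and np.allclose(spacing, spacing[0], atol=1e-12):
            return float(spacing[0])
        raise ValueError("support is not evenly spaced")

    def support(self, atol: float = 0.0) -> np.ndarray:
        """Frequencies carrying weight greater than ``atol``."""
        return self.values[self.weights > atol]


@dataclass(frozen=True)
class SiteObservation:
    """Read evidence at one genomic site in one sample.

    ``q_avg`` is the average Phred score of the variant-supporting bases; it
    is undefined (None) only when no read supports the variant.
    """

    n_variant: int
    m_total: int
    q_avg: float | None = None

    def __post_init__(self) -> None:
        if self.m_total < 0 or self.n_variant < 0 or self.n_variant > self.m_total:
            raise ValueError(
                f"require 0 <= n <= m, got n={self.n_variant}, m={self.m_total}"
            )
        if self.q_avg is None:
            if self.n_variant > 0:
                raise ValueError("q_avg may be undefined only when n_variant = 0")
        elif self.q_avg < 0:
            raise ValueError(f"q_avg must be >= 0, got {self.q_avg}")

    def error_bound(self, floor_quality: float = DEFAULT_FLOOR_QUALITY) -> float:
        """Error window E = 10**(-Q/10), using ``floor_quality`` when n = 0."""
        q = self.q_avg if self.q_avg is not None else floor_quality
        return phred_to_error(q)

    @property
    def observed_frequency(self) -> float:
        if self.m_total == 0:
            raise ValueError("observed frequency undefined at zero depth")
        return self.n_variant / self.m_total


@dataclass(frozen=True)
class Hypothesis:
    """A set of grid frequencies, e.g. {1/2} ("heterozygous") or {f >= 0.02}."""

    members: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("hypothesis must be a non-empty set of frequencies")
        object.__setattr__(self, "members", tuple(sorted(set(self.members))))

    @classmethod
    def from_iterable(cls, members: Iterable[float]) -> "Hypothesis":
        return cls(tuple(members))


def _index_of(values: np.ndarray, f: float, atol: float = 1e-9) -> int:
    """Index of frequency ``f`` on the support, or raise if off-support."""
    idx = int(np.argmin(np.abs(values - f)))
    if abs(values[idx] - f) > atol:
        raise ValueError(f"frequency {f} is not on the grid")
    return idx


# ---------------------------------------------------------------------------
# Elementary model functions
# ---------------------------------------------------------------------------


def observed_variant_prob(f: float, e: float) -> float:
    """Probability of reading a variant base: f + e - 2ef.

    A variant base (probability f) is read correctly with probability 1 - e;
    a reference base is misread as the variant with probability e.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"e must be in [0, 1], got {e}")
    return f + e - 2.0 * e * f


def phred_to_error(q_avg: float) -> float:
    """Upper error bound E = 10**(-Q/10) for a Phred score Q."""
    if q_avg < 0:
        raise ValueError(f"Phred score must be >= 0, got {q_avg}")
    return 10.0 ** (-q_avg / 10.0)


# ---------------------------------------------------------------------------
# Averaged binomial kernel
# ---------------------------------------------------------------------------


def _log_integrand(x: np.ndarray, n: int, m: int) -> np.ndarray:
    """log(x**n (1-x)**(m-n)) with the conventions 0**0 = 1."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if n > 0:
        with np.errstate(divide="ignore"):
            out = out + n * np.log(x)
    if m - n > 0:
        with np.errstate(divide="ignore"):
            out = out + (m - n) * np.log1p(-x)
    return out


def log_averaged_kernel(
    n: int, m: int, a: np.ndarray | float, b: np.ndarray | float
) -> np.ndarray:
    """log B_{m,n}(a, b), vectorised over the interval bounds.

    Stable path: difference of regularized incomplete-beta values plus the
    log complete-beta factor.  Where that difference has lost more than half
    its significand to cancellation (narrow or far-tail intervals), a
    fixed-order Gauss-Legendre rule on [a, b] is used instead; a degenerate
    interval evaluates the integrand pointwise.
    """
    if not 0 <= n <= m:
        raise ValueError(f"require 0 <= n <= m, got n={n}, m={m}")
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    a, b = np.broadcast_arrays(a, b)
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("interval bounds must lie in [0, 1]")
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    width = hi - lo

    i_hi = betainc(n + 1, m - n + 1, hi)
    i_lo = betainc(n + 1, m - n + 1, lo)
    diff = i_hi - i_lo
    stable = (width > 0) & (diff > _CANCEL_TOL * np.maximum(i_hi, i_lo)) & (diff > 0)

    out = np.empty_like(lo)
    if np.any(stable):
        with np.errstate(divide="ignore"):
            out[stable] = (
                betaln(n + 1, m - n + 1)
                + np.log(diff[stable])
                - np.log(width[stable])
            )

    rest = ~stable
    if np.any(rest):
        degenerate = rest & (width == 0)
        if np.any(degenerate):
            out[degenerate] = _log_integrand(lo[degenerate], n, m)
        quad = rest & (width > 0)
        if np.any(quad):
            lo_q = lo[quad][:, None]
            w_q = width[quad][:, None]
            # 1/(b-a) * (b-a)/2 * sum w_i f(x_i) = sum (w_i/2) f(x_i)
            x = lo_q + w_q * (_GL_NODES[None, :] + 1.0) / 2.0
            logf = _log_integrand(x, n, m)
            shift = logf.max(axis=1, keepdims=True)
            vals = np.exp(logf - shift) @ (_GL_WEIGHTS / 2.0)
            with np.errstate(divide="ignore"):
                out[quad] = shift[:, 0] + np.log(vals)
    return out


def averaged_kernel(n: int, m: int, a: float, b: float) -> float:
    """Error-averaged binomial likelihood B_{m,n}(a, b).

    Symmetric in (a, b); at a = b it is the pointwise binomial kernel
    a**n (1-a)**(m-n); B_{0,0} is identically 1.
    """
    return float(np.exp(log_averaged_kernel(n, m, a, b)[0]))


def site_log_likelihood(
    obs: SiteObservation,
    values: np.ndarray,
    floor_quality: float = DEFAULT_FLOOR_QUALITY,
) -> np.ndarray:
    """log-likelihood B_{m,n}(f, f + E - 2Ef) at each support frequency."""
    values = np.asarray(values, dtype=float)
    if obs.m_total == 0:
        return np.zeros(values.size)
    e_bound = obs.error_bound(floor_quality)
    b = values + e_bound - 2.0 * e_bound * values
    return log_averaged_kernel(obs.n_variant, obs.m_total, values, b)


# ---------------------------------------------------------------------------
# Posterior machinery
# ---------------------------------------------------------------------------


def site_posterior(
    prior: GridDistribution,
    obs: SiteObservation,
    floor_quality: float = DEFAULT_FLOOR_QUALITY,
) -> GridDistribution:
    """Posterior P(f) proportional to p(f) * B_{m,n}(f, f + E - 2Ef).

    Computed in log space with a max shift, so arbitrarily deep sites do not
    underflow.  A site with no reads returns the prior unchanged.
    """
    if obs.m_total == 0:
        return prior
    logk = site_log_likelihood(obs, prior.values, floor_quality)
    with np.errstate(divide="ignore"):
        logw = np.where(prior.weights > 0, np.log(prior.weights), -np.inf)
    logpost = logw + logk
    peak = logpost.max()
    if not np.isfinite(peak):
        raise ValueError(
            "observation impossible under the prior: zero unnormalized mass"
        )
    mass = np.exp(logpost - peak)
    return GridDistribution.from_unnormalized(prior.values, mass)


def hypothesis_posterior(post: GridDistribution, h: Hypothesis) -> float:
    """Posterior of a hypothesis: total weight of its member frequencies."""
    idx = [_index_of(post.values, f) for f in h.members]
    return float(post.weights[idx].sum())


def credible_set(post: GridDistribution, alpha: float) -> Hypothesis:
    """Smallest set of top-posterior frequencies with total mass >= 1 - alpha.

    Frequencies are ranked by decreasing weight, equal weights by ascending
    frequency, and the shortest prefix reaching 1 - alpha is returned.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    order = np.lexsort((post.values, -post.weights))
    cumulative = np.cumsum(post.weights[order])
    l = int(np.searchsorted(cumulative, 1.0 - alpha - 1e-12)) + 1
    l = min(l, post.values.size)
    return Hypothesis(tuple(post.values[order[:l]]))


def tail_mass(post: GridDistribution, f: float) -> float:
    """Posterior mass of the event "frequency >= f"."""
    idx = _index_of(post.values, f)
    return float(post.weights[idx:].sum())


def max_confident_frequency(post: GridDistribution, alpha: float) -> float:
    """Largest grid f whose event "frequency >= f" has mass >= 1 - alpha.

    The one-sided credible bound used for presence cutoffs; f = 0 always
    qualifies since its tail mass is 1.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    tails = np.cumsum(post.weights[::-1])[::-1]
    ok = tails >= (1.0 - alpha) - 1e-12
    ok[0] = True
    return float(post.values[np.nonzero(ok)[0][-1]])


def map_frequency(post: GridDistribution) -> float:
    """Most likely frequency; ties resolve to the lowest frequency."""
    return float(post.values[int(np.argmax(post.weights))])


def expected_frequency(post: GridDistribution) -> float:
    """Posterior mean sum_f f * P(f)."""
    return float(np.dot(post.values, post.weights))
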