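"""Paired-sample comparison: frequency-difference posteriors and somatic calls.

Treating the tumor and normal posteriors as independent, the posterior of
the frequency difference D = f_tumor - f_normal is the discrete
cross-correlation

    P(D) = sum_{f1 - f2 = D} P_t(f1) * P_n(f2)

over the shared frequency grid.  A gain (e.g. somatic point mutation) is
called when "D >= d_cut" is credible at 1 - alpha; a loss when "D <= -d_cut"
is; loss of heterozygosity screens use the absolute version "|D| >= d_cut".

For strictly diploid analysis the somatic posterior combines the two
zygosity posteriors directly:

    P_som = P_t,var * P_n,ref + P_t,ref * P_n,var
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .calling import ZygosityPosterior, genotype_site, variant_presence_posterior
from .core_bayes import (
    DEFAULT_ALPHA,
    DEFAULT_D_CUT,
    DEFAULT_FLOOR_QUALITY,
    GridDistribution,
    SiteObservation,
    site_posterior,
)

logger = logging.getLogger(__name__)

DIRECTIONS = ("gain", "loss", "absolute")


@dataclass(frozen=True)
class PairedObservation:
    """Tumor and normal read evidence for the same site and variant allele."""

    tumor: SiteObservation
    normal: SiteObservation
    site_id: str = ""


@dataclass(frozen=True)
class DifferenceDistribution:
    """Probability vector over frequency differences D in [-1, 1]."""

    deltas: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        deltas = np.asarray(self.deltas, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "deltas", deltas)
        object.__setattr__(self, "weights", weights)
        if deltas.shape != weights.shape or deltas.ndim != 1:
            raise ValueError("deltas and weights must be 1-D and of equal length")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def _delta_index(self, d: float) -> int:
        idx = int(np.argmin(np.abs(self.deltas - d)))
        if abs(self.deltas[idx] - d) > 1e-9:
            raise ValueError(f"difference {d} is not on the delta grid")
        return idx

    def tail_at_least(self, d: float) -> float:
        """P(D >= d)."""
        return float(self.weights[self._delta_index(d):].sum())

    def tail_at_most(self, d: float) -> float:
        """P(D <= d)."""
        return float(self.weights[: self._delta_index(d) + 1].sum())

    def tail_abs_at_least(self, d: float) -> float:
        """P(|D| >= d) for d >= 0."""
        if d < 0:
            raise ValueError("absolute cutoff must be non-negative")
        hi = self.tail_at_least(d)
        lo = self.tail_at_most(-d)
        if abs(d) <= 1e-9:  # both tails count the D = 0 atom
            lo -= float(self.weights[self._delta_index(0.0)])
        return hi + lo

    def max_confident_delta(self, alpha: float) -> float:
        """Largest delta d with P(D >= d) >= 1 - alpha.

        One-sided credible bound on the frequency difference, the score used
        when calibrating a difference cutoff; the most negative delta always
        qualifies (its tail mass is 1).
        """
        if not 0.0 < alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
        tails = np.cumsum(self.weights[::-1])[::-1]
        ok = tails >= (1.0 - alpha) - 1e-12
        ok[0] = True
        return float(self.deltas[np.nonzero(ok)[0][-1]])

    def map_delta(self) -> float:
        """Most likely difference; ties resolve to the lowest delta."""
        return float(self.deltas[int(np.argmax(self.weights))])

    def expected_delta(self) -> float:
        return float(np.dot(self.deltas, self.weights))

    def credible_interval(self, alpha: float) -> tuple[float, float]:
        """Span of the smallest top-posterior delta set with mass >= 1 - alpha."""
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        order = np.lexsort((self.deltas, -self.weights))
        cumulative = np.cumsum(self.weights[order])
        l = int(np.searchsorted(cumulative, 1.0 - alpha - 1e-12)) + 1
        members = self.deltas[order[: min(l, self.deltas.size)]]
        return float(members.min()), float(members.max())


def difference_posterior(
    post_t: GridDistribution, post_n: GridDistribution
) -> DifferenceDistribution:
    """Exact cross-correlation posterior of D = f_tumor - f_normal.

    Products accumulate in ascending-f2-within-ascending-f1 order (the
    canonical double-loop order), so the result is bit-identical to the
    naive O(G^2) computation.
    """
    if not np.array_equal(post_t.values, post_n.values):
        raise ValueError("posteriors must share the same grid")
    values = post_t.values
    g = values.size
    span = values[-1] - values[0]
    deltas = np.round(np.linspace(-span, span, 2 * g - 1), 12)
    products = (post_t.weights[:, None] * post_n.weights[None, :]).ravel()
    idx = (np.arange(g)[:, None] - np.arange(g)[None, :] + g - 1).ravel()
    weights = np.zeros(2 * g - 1)
    np.add.at(weights, idx, products)
    total = weights.sum()
    return DifferenceDistribution(deltas, weights / total)


def somatic_posterior(
    zyg_t: ZygosityPosterior, zyg_n: ZygosityPosterior
) -> tuple[float, float]:
    """(P_som, P_nsom) from the two diploid zygosity posteriors.

    A variant is somatic when exactly one of the samples carries it:
    P_som = P_t,var * P_n,ref + P_t,ref * P_n,var.
    """
    pt_var, pt_ref = variant_presence_posterior(zyg_t)
    pn_var, pn_ref = variant_presence_posterior(zyg_n)
    p_som = pt_var * pn_ref + pt_ref * pn_var
    return p_som, 1.0 - p_som


@dataclass(frozen=True)
class FrequencyShiftCall:
    """Directional frequency-difference decision with posterior summaries."""

    site_id: str
    present: bool
    direction: str
    d_cut: float
    alpha: float
    map_delta: float
    expected_delta: float
    credible_interval: tuple[float, float]
    distribution: DifferenceDistribution


def call_frequency_shift(
    pair: PairedObservation,
    prior_t: GridDistribution,
    prior_n: GridDistribution,
    d_cut: float = DEFAULT_D_CUT,
    alpha: float = DEFAULT_ALPHA,
    direction: str = "gain",
    floor_quality: float = DEFAULT_FLOOR_QUALITY,
) -> FrequencyShiftCall:
    """Call a credible frequency shift between tumor and normal.

    gain:     P(D >=  d_cut) >= 1 - alpha  (e.g. somatic point mutation)
    loss:     P(D <= -d_cut) >= 1 - alpha  (allele loss)
    absolute: P(|D| >= d_cut) >= 1 - alpha (LOH screening, either direction)

    A zero-depth sample contributes its prior as the posterior, so the
    difference distribution is always defined.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    post_t = site_posterior(prior_t, pair.tumor, floor_quality)
    post_n = site_posterior(prior_n, pair.normal, floor_quality)
    dist = difference_posterior(post_t, post_n)
    if direction == "gain":
        conf = dist.tail_at_least(d_cut)
    elif direction == "loss":
        conf = dist.tail_at_most(-d_cut)
    else:
        conf = dist.tail_abs_at_least(d_cut)
    present = conf >= (1.0 - alpha) - 1e-12
    return FrequencyShiftCall(
        site_id=pair.site_id,
        present=bool(present),
        direction=direction,
        d_cut=d_cut,
        alpha=alpha,
        map_delta=dist.map_delta(),
        expected_delta=dist.expected_delta(),
        credible_interval=dist.credible_interval(alpha),
        distribution=dist,
    )


def candidate_somatic_filter(
    pair: PairedObservation,
    prior3: GridDistribution,
    alpha_zero: float = DEFAULT_ALPHA,
    min_tumor_obs_freq: float = 0.25,
    max_normal_obs_freq: float = 0.05,
    floor_quality: float = DEFAULT_FLOOR_QUALITY,
) -> bool:
    """Screen for candidate somatic variants worth validating.

    All four conditions must hold:
      * posterior confidence of zero frequency in tumor <= alpha_zero;
      * posterior confidence of non-zero frequency in normal <= alpha_zero;
      * observed tumor frequency n/m >= min_tumor_obs_freq;
      * observed normal frequency n/m <= max_normal_obs_freq.
    A zero-depth sample fails the filter (no observed frequency exists).
    """
    if pair.tumor.m_total == 0 or pair.normal.m_total == 0:
        logger.warning(
            "site %s: zero depth in tumor or normal, candidate filter fails",
            pair.site_id or "<unnamed>",
        )
        return False
    zyg_t = genotype_site(pair.tumor, prior3, floor_quality)
    zyg_n = genotype_site(pair.normal, prior3, floor_quality)
    return (
        zyg_t.p_ref <= alpha_zero
        and (zyg_n.p_het + zyg_n.p_hom) <= alpha_zero
        and pair.tumor.observed_frequency >= min_tumor_obs_freq
        and pair.normal.observed_frequency <= max_normal_obs_freq
    )
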