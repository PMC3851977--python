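"""Single-sample calls: diploid genotyping and variant presence.

Genotyping restricts the prior to the three diploid zygosity frequencies
{0, 1/2, 1} and picks the type with the highest posterior.  Presence of a
variant at arbitrary frequency is decided on the full grid: the variant is
called present when the event "frequency >= f_cut" holds with posterior
confidence at least 1 - alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_bayes import (
    DEFAULT_ALPHA,
    DEFAULT_F_CUT,
    DEFAULT_FLOOR_QUALITY,
    GridDistribution,
    Hypothesis,
    SiteObservation,
    THREE_POINT_VALUES,
    credible_set,
    expected_frequency,
    map_frequency,
    max_confident_frequency,
    site_posterior,
    tail_mass,
    _index_of,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZygosityPosterior:
    """Posteriors (P0, P1/2, P1) of the three diploid zygosity types."""

    p_ref: float
    p_het: float
    p_hom: float

    def __post_init__(self) -> None:
        probs = (self.p_ref, self.p_het, self.p_hom)
        if any(p < 0 for p in probs):
            raise ValueError("negative zygosity posterior")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("zygosity posteriors must sum to 1")

    @property
    def called_type(self) -> str:
        """Highest-posterior type; ties resolve toward the reference."""
        probs = (self.p_ref, self.p_het, self.p_hom)
        return ("ref", "het", "hom")[int(np.argmax(probs))]


@dataclass(frozen=True)
class VariantCall:
    """Presence decision plus posterior summaries for one site."""

    site_id: str
    present: bool
    map_frequency: float
    expected_frequency: float
    max_confident_frequency: float
    credible_set: Hypothesis
    f_cut: float
    alpha: float
    zygosity: ZygosityPosterior | None = None


def _check_three_point(prior: GridDistribution) -> None:
    support = tuple(prior.support())
    if not set(support) <= set(THREE_POINT_VALUES):
        raise ValueError(
            f"genotyping prior must be supported on {THREE_POINT_VALUES}, "
            f"got support {support}"
        )


def genotype_site(
    obs: SiteObservation,
    prior3: GridDistribution,
    floor_quality: float = DEFAULT_FLOOR_QUALITY,
) -> ZygosityPosterior:
    """Three-point posterior (P0, P1/2, P1) for a diploid site."""
    _check_three_point(prior3)
    post = site_posterior(prior3, obs, floor_quality)
    weights = {float(v): float(w) for v, w in zip(post.values, post.weights)}
    return ZygosityPosterior(
        p_ref=weights.get(0.0, 0.0),
        p_het=weights.get(0.5, 0.0),
        p_hom=weights.get(1.0, 0.0),
    )


def variant_presence_posterior(zyg: ZygosityPosterior) -> tuple[float, float]:
    """(P_var, P_ref): posterior of the site being variant vs reference."""
    return zyg.p_het + zyg.p_hom, zyg.p_ref


def call_variant(
    obs: SiteObservation,
    prior: GridDistribution,
    f_cut: float = DEFAULT_F_CUT,
    alpha: float = DEFAULT_ALPHA,
    site_id: str = "",
    floor_quality: float = DEFAULT_FLOOR_QUALITY,
) -> VariantCall:
    """Presence call: "frequency >= f_cut" credible at level 1 - alpha."""
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    _index_of(prior.values, f_cut)  # reject off-grid cutoffs
    post = site_posterior(prior, obs, floor_quality)
    present = tail_mass(post, f_cut) >= (1.0 - alpha) - 1e-12
    return VariantCall(
        site_id=site_id,
        present=bool(present),
        map_frequency=map_frequency(post),
        expected_frequency=expected_frequency(post),
        max_confident_frequency=max_confident_frequency(post, alpha),
        credible_set=credible_set(post, alpha),
        f_cut=f_cut,
        alpha=alpha,
    )


def aggregate_posteriors(
    posteriors: Sequence[GridDistribution], normalize: bool = False
) -> np.ndarray:
    """Component-wise sum of posteriors across sites.

    The aggregate carries total mass equal to the number of inputs (the
    field's convention for frequency-spectrum summaries); ``normalize``
    rescales it to a probability vector for plotting.
    """
    posteriors = list(posteriors)
    if not posteriors:
        return np.zeros(0)
    values = posteriors[0].values
    for p in posteriors[1:]:
        if not np.array_equal(p.values, values):
            raise ValueError("posteriors must share the same grid")
    total = np.sum([p.weights for p in posteriors], axis=0)
    if normalize:
        total = total / total.sum()
    return total
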