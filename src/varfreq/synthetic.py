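"""Seeded generators for count data with the assumed statistical structure.

The generators emulate exome-style count data: per-site true frequencies
drawn from a diploid zygosity mixture, read depths following a negative
binomial (depth heterogeneity along the genome makes the global depth
distribution a Poisson mixture, i.e. negative binomial), and variant read
counts that are binomial in the error-perturbed frequency f + e - 2ef with a
fresh nuisance error e ~ Uniform[0, 10**(-Q/10)] per site.  Paired
tumor/normal data add somatic point mutations and copy-neutral LOH events,
diluted by tumor purity.

Everything is driven by one integer seed, so any run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import PairedObservation
from .core_bayes import SiteObservation

#: Zygosity mixture used throughout the synthetic studies: heterozygous
#: sites twice as common as homozygous-variant ones, at a variant fraction
#: large enough that desk-scale simulations populate all three modes.
DEFAULT_ZYGOSITY = (0.90, 0.0667, 0.0333)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic sequencing experiment.

    ``depth_dispersion`` is the negative-binomial size parameter r (variance
    mean + mean**2/r); ``None`` fixes every site at ``depth_mean`` reads.
    """

    n_sites: int = 10_000
    zygosity_proportions: tuple[float, float, float] = DEFAULT_ZYGOSITY
    depth_mean: float = 55.0
    depth_dispersion: float | None = 5.0
    base_quality: float = 30.0
    quality_jitter: float = 0.0
    purity: float = 1.0
    somatic_rate: float = 0.01
    somatic_frequency: float = 0.5
    loh_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.zygosity_proportions, dtype=float)
        if props.size != 3 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-6:
            raise ValueError("zygosity proportions must be 3 non-negatives summing to 1")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.base_quality < 0 or self.quality_jitter < 0:
            raise ValueError("qualities must be non-negative")
        for name in ("purity", "somatic_rate", "somatic_frequency", "loh_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _draw_depths(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.depth_dispersion is None:
        return np.full(config.n_sites, int(round(config.depth_mean)))
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    return rng.negative_binomial(r, p, size=config.n_sites)


def _draw_observations(
    true_f: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> list[SiteObservation]:
    depths = _draw_depths(config, rng)
    if config.quality_jitter > 0:
        q_site = np.maximum(
            rng.normal(config.base_quality, config.quality_jitter, config.n_sites), 0.0
        )
    else:
        q_site = np.full(config.n_sites, config.base_quality)
    e_bounds = np.power(10.0, -q_site / 10.0)
    e = rng.uniform(0.0, 1.0, size=config.n_sites) * e_bounds
    p_obs = true_f + e - 2.0 * e * true_f
    n = rng.binomial(depths, p_obs)
    return [
        SiteObservation(
            n_variant=int(ni),
            m_total=int(mi),
            q_avg=float(qi) if ni > 0 else None,
        )
        for ni, mi, qi in zip(n, depths, q_site)
    ]


def _draw_zygosity(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(
        [0.0, 0.5, 1.0], size=config.n_sites, p=np.asarray(config.zygosity_proportions)
    )


def simulate_sample(
    config: SimulationConfig,
) -> tuple[list[SiteObservation], pd.DataFrame]:
    """One sample of per-site counts plus the underlying true frequencies.

    Returns the observations and a truth table with columns
    ``site`` (0-based index) and ``true_f``.
    """
    rng = np.random.default_rng(config.seed)
    true_f = _draw_zygosity(config, rng)
    observations = _draw_observations(true_f, config, rng)
    truth = pd.DataFrame({"site": np.arange(config.n_sites), "true_f": true_f})
    return observations, truth


def simulate_tumor_normal(
    config: SimulationConfig,
) -> tuple[list[PairedObservation], pd.DataFrame]:
    """Paired tumor/normal counts with somatic and LOH events injected.

    The normal sample reads the germline frequencies.  In the tumor,
    somatic point mutations arise at germline-reference sites at rate
    ``somatic_rate`` with tumor-cell frequency ``somatic_frequency``;
    copy-neutral LOH converts germline-heterozygous sites at rate
    ``loh_rate`` to frequency 0 or 1 in the tumor cells.  Tumor purity
    mixes either event back toward the germline frequency.

    Truth table columns: site, label (germline/somatic/loh), true_f_normal,
    true_f_tumor, true_delta.
    """
    rng = np.random.default_rng(config.seed)
    germline = _draw_zygosity(config, rng)
    tumor_f = germline.copy()
    labels = np.full(config.n_sites, "germline", dtype=object)

    ref_sites = germline == 0.0
    somatic = ref_sites & (rng.random(config.n_sites) < config.somatic_rate)
    tumor_f[somatic] = config.purity * config.somatic_frequency
    labels[somatic] = "somatic"

    het_sites = germline == 0.5
    loh = het_sites & (rng.random(config.n_sites) < config.loh_rate)
    loh_target = rng.choice([0.0, 1.0], size=config.n_sites)
    tumor_f[loh] = (
        config.purity * loh_target[loh] + (1.0 - config.purity) * 0.5
    )
    labels[loh] = "loh"

    normal_obs = _draw_observations(germline, config, rng)
    tumor_obs = _draw_observations(tumor_f, config, rng)
    pairs = [
        PairedObservation(tumor=t, normal=n, site_id=str(i))
        for i, (t, n) in enumerate(zip(tumor_obs, normal_obs))
    ]
    truth = pd.DataFrame(
        {
            "site": np.arange(config.n_sites),
            "label": labels,
            "true_f_normal": germline,
            "true_f_tumor": tumor_f,
            "true_delta": tumor_f - germline,
        }
    )
    return pairs, truth


def simulate_validation_set(
    n_items: int,
    separable_at: float,
    noise: float = 0.0,
    seed: int = 0,
    resolution: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores-plus-truth fixture for mutual-information cutoff selection.

    Truth-positive items receive max-confident-difference scores on the
    delta grid at or above ``separable_at``; negatives stay strictly below.
    One positive sits exactly at ``separable_at`` and one negative exactly
    one grid step under it, so with ``noise = 0`` the MI-optimal cutoff is
    ``separable_at`` itself.  ``noise`` flips that fraction of labels at
    random (seeded).
    """
    if n_items <= 0:
        raise ValueError("n_items must be positive")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    steps = separable_at / resolution
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError("separable_at must sit on the delta grid")
    if not -1.0 + resolution <= separable_at <= 1.0:
        raise ValueError("separable_at must leave room for both classes")

    rng = np.random.default_rng(seed)
    grid = np.round(np.linspace(-1.0, 1.0, 2 * round(1.0 / resolution) + 1), 12)
    above = grid[grid >= separable_at - 1e-12]
    below = grid[grid < separable_at - 1e-12]

    n_pos = (n_items + 1) // 2
    pos_scores = above[rng.integers(0, above.size, size=n_pos)]
    neg_scores = below[rng.integers(0, below.size, size=n_items - n_pos)]
    # pin the class boundaries one grid step apart so the planted cutoff is
    # the unique smallest perfect separator on the delta grid
    pos_scores[0] = above[0]
    if neg_scores.size:
        neg_scores[0] = below[-1]
    scores = np.concatenate([pos_scores, neg_scores])
    truth = np.concatenate(
        [np.ones(n_pos, dtype=bool), np.zeros(n_items - n_pos, dtype=bool)]
    )
    flips = rng.random(n_items) < noise
    truth = truth ^ flips
    order = rng.permutation(n_items)
    return scores[order], truth[order]
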