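"""Prospective-planning analytics.

Covers the cluster exclusion rules applied before planning, the count of
additional electrodes needed to sample unexplored clusters, and the cohort
power calculation (Monte-Carlo over simulated cohorts, with the exact
binomial tail as an independent cross-check).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .clustering import Cluster
from .seeg import (DEFAULT_DISTANCE_THRESHOLD_MM, ElectrodeSet,
                   cluster_contact_distance)
from .surface_io import HemisphereSurface, ValidationError


@dataclass
class PowerConfig:
    contribution_probability: float
    target_successes: int = 10
    confidence: float = 0.90
    n_cohorts: int = 1000
    seed: int = 0
    max_n: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 <= self.contribution_probability <= 1.0:
            raise ValidationError("contribution_probability must lie in [0, 1]")
        if not 0.0 < self.confidence < 1.0:
            raise ValidationError("confidence must lie in (0, 1)")
        if self.target_successes < 0 or self.n_cohorts < 1:
            raise ValidationError("invalid power configuration")


@dataclass
class PlanningConfig:
    top_k: int = 3
    distance_threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM
    exclude_contralateral: bool = True

    def __post_init__(self) -> None:
        if self.top_k < 1 or self.distance_threshold_mm <= 0:
            raise ValidationError("planning thresholds must be positive")


def filter_clusters_for_planning(clusters: Sequence[Cluster],
                                 implant_laterality: str,
                                 config: Optional[PlanningConfig] = None
                                 ) -> list[Cluster]:
    """Apply the planning exclusions in order: contralateral hemisphere (for
    unilateral implantations), flagged artifacts, then keep only the top-k
    ranked clusters."""
    config = config or PlanningConfig()
    kept = list(clusters)
    if config.exclude_contralateral and implant_laterality in ("left", "right"):
        kept = [c for c in kept if c.hemisphere == implant_laterality]
    kept = [c for c in kept if not c.artifact_flag]
    kept.sort(key=lambda c: c.rank if c.rank is not None else np.inf)
    return kept[:config.top_k]


def count_extra_electrodes(filtered_clusters: Sequence[Cluster],
                           electrodes: ElectrodeSet,
                           surfaces: Dict[str, HemisphereSurface],
                           config: Optional[PlanningConfig] = None) -> int:
    """Clusters with no contact of any class strictly within the distance
    threshold each require one additional electrode."""
    config = config or PlanningConfig()
    n_extra = 0
    for cluster in filtered_clusters:
        surface = surfaces[cluster.hemisphere]
        dmin = min(cluster_contact_distance(cluster, surface, c.coord)
                   for c in electrodes.contacts)
        if dmin >= config.distance_threshold_mm:
            n_extra += 1
    return n_extra


# ---------------------------------------------------------------------------
# Power calculation
# ---------------------------------------------------------------------------

def exact_success_fraction(n: int, config: PowerConfig) -> float:
    """P(Binomial(n, p) >= target) -- the closed-form oracle."""
    return float(binom.sf(config.target_successes - 1, n,
                          config.contribution_probability))


def simulated_success_fraction(n: int, config: PowerConfig,
                               rng: np.random.Generator) -> float:
    """Fraction of simulated cohorts of size ``n`` reaching the target.

    Cohort success counts are binomial draws via stratified inverse-CDF
    sampling (one uniform per cohort, jittered within equal strata and
    randomly permuted), which keeps each cohort marginally Binomial(n, p)
    while shrinking the Monte-Carlo error of the fraction estimate.
    """
    m = config.n_cohorts
    u = (rng.permutation(m) + rng.uniform(size=m)) / m
    successes = binom.ppf(u, n, config.contribution_probability)
    return float(np.mean(successes >= config.target_successes))


def power_min_cohort(config: PowerConfig, method: str = "monte-carlo"
                     ) -> Optional[int]:
    """Smallest cohort size whose probability of reaching the target number
    of positive contributions is at least the configured confidence.

    ``method='monte-carlo'`` simulates ``n_cohorts`` cohorts per candidate
    size (seeded); ``method='exact'`` uses the binomial tail directly.
    Returns None when no finite cohort can succeed (p == 0 with target > 0).
    """
    if config.contribution_probability == 0.0 and config.target_successes > 0:
        return None
    if config.target_successes == 0:
        return 0
    rng = np.random.default_rng(config.seed)
    n = config.target_successes
    while n <= config.max_n:
        if method == "exact":
            frac = exact_success_fraction(n, config)
        elif method == "monte-carlo":
            frac = simulated_success_fraction(n, config, rng)
        else:
            raise ValidationError(f"unknown power method {method!r}")
        if frac >= config.confidence:
            return n
        n += 1
    raise ValidationError(f"no cohort size up to {config.max_n} reaches the target")


def contribution_probability_from_records(records) -> float:
    """Default estimator: concordant focal patients over all sEEG patients."""
    if not records:
        raise ValidationError("empty cohort")
    concordant = sum(1 for r in records
                     if r.seeg_outcome == "focal" and r.concordance == "yes")
    return concordant / len(records)
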