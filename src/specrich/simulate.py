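"""Synthetic multi-site communities with occupancy heterogeneity.

The generator emulates the sampling situation of a regional inventory: a
species pool of known size, a lognormal abundance structure, each species
restricted to a subset of the sampling sites, and a controllable per-site
sampling effort.  Varying the effort sweeps the *coverage* of the species
pool (S_obs / S_true) from a few percent to essentially complete, which is
exactly the axis along which richness estimators are benchmarked.

Model
-----
* Per-species relative abundance ``w_j = exp(N(0, sigma))`` (lognormal
  species-abundance distribution).
* Occupancy: each species occupies a random subset of sites.  Under the
  default heterogeneous model the per-species occupancy probability is
  itself random (uniform on an interval with mean 0.3), producing a
  realistic mix of widespread and highly localized species.  Every species
  occupies at least one site (it is part of the regional pool by
  definition).
* Sampling: within each site, specimen counts are independent Poisson draws
  with rates proportional to ``w_j`` over the species present there,
  normalised so the expected total catch per site equals
  ``effort_per_site``.

Everything is driven by the seed in the spec; the same spec yields a
bit-identical community.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix

__all__ = ["CommunitySpec", "SyntheticCommunity", "simulate_community", "subsample"]

OccupancyModel = Union[str, float, int]

#: bounds of the uniform distribution the default heterogeneous model draws
#: per-species occupancy probabilities from (mean occupancy 0.3)
HETEROGENEOUS_OCCUPANCY_RANGE = (0.05, 0.55)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic regional community and its sampling design.

    occupancy:
        ``"heterogeneous"`` (default) — per-species occupancy probability
        drawn uniformly from :data:`HETEROGENEOUS_OCCUPANCY_RANGE`;
        a float p in (0, 1] — homogeneous Bernoulli(p) occupancy;
        an int m — every species occupies exactly m random sites.
    abundance_sigma:
        standard deviation of log relative abundance (lognormal SAD).
    effort_per_site:
        expected number of specimens caught per site.
    """

    pool_size: int
    n_sites: int
    occupancy: OccupancyModel = "heterogeneous"
    abundance_sigma: float = 1.5
    effort_per_site: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.effort_per_site < 0:
            raise ValueError("effort_per_site must be >= 0")
        if isinstance(self.occupancy, bool):
            raise ValueError("occupancy must be a model name, probability or site count")
        if isinstance(self.occupancy, int):
            if not 1 <= self.occupancy <= self.n_sites:
                raise ValueError(
                    f"fixed occupancy {self.occupancy} impossible with "
                    f"{self.n_sites} sites"
                )
        elif isinstance(self.occupancy, float):
            if not 0.0 < self.occupancy <= 1.0:
                raise ValueError("occupancy probability must be in (0, 1]")
        elif self.occupancy != "heterogeneous":
            raise ValueError(f"unknown occupancy model {self.occupancy!r}")


@dataclass(frozen=True)
class SyntheticCommunity:
    """A simulated community: the truth plus the sampled matrix."""

    spec: CommunitySpec
    true_occupancy: pd.DataFrame  # sites x pool, boolean
    sampled: AbundanceMatrix

    @property
    def true_richness(self) -> int:
        return self.spec.pool_size

    @property
    def observed_richness(self) -> int:
        return self.sampled.n_species

    @property
    def coverage(self) -> float:
        return self.observed_richness / self.true_richness


def _draw_occupancy(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    n, s = spec.n_sites, spec.pool_size
    if isinstance(spec.occupancy, int):
        occ = np.zeros((n, s), dtype=bool)
        for j in range(s):
            occ[rng.choice(n, size=spec.occupancy, replace=False), j] = True
        return occ
    if spec.occupancy == "heterogeneous":
        lo, hi = HETEROGENEOUS_OCCUPANCY_RANGE
        p = rng.uniform(lo, hi, size=s)
    else:  # homogeneous probability
        p = np.full(s, float(spec.occupancy))
    occ = rng.random((n, s)) < p
    # every pool species occupies at least one site
    empty = ~occ.any(axis=0)
    if empty.any():
        occ[rng.integers(0, n, size=int(empty.sum())), np.flatnonzero(empty)] = True
    return occ


def simulate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Draw one synthetic community and its sampled site-by-species matrix."""
    rng = np.random.default_rng(spec.seed)
    site_ids = [f"site{i + 1:03d}" for i in range(spec.n_sites)]
    species_ids = [f"sp{j + 1:04d}" for j in range(spec.pool_size)]
    weights = np.exp(rng.normal(0.0, spec.abundance_sigma, size=spec.pool_size))
    occupancy = _draw_occupancy(spec, rng)

    counts = np.zeros((spec.n_sites, spec.pool_size), dtype=np.int64)
    if spec.effort_per_site > 0:
        for i in range(spec.n_sites):
            local = weights * occupancy[i]
            total = local.sum()
            if total > 0:
                counts[i] = rng.poisson(spec.effort_per_site * local / total)

    frame = pd.DataFrame(counts, index=site_ids, columns=species_ids)
    sampled = AbundanceMatrix.from_frame(frame, prune=True)
    return SyntheticCommunity(
        spec=spec,
        true_occupancy=pd.DataFrame(occupancy, index=site_ids, columns=species_ids),
        sampled=sampled,
    )


def subsample(
    matrix: AbundanceMatrix, fraction: float, seed: int
) -> AbundanceMatrix:
    """Binomial thinning: keep each specimen independently with probability ``fraction``.

    Emulates processing only part of the catch.  Species and sites left with
    no specimens are dropped.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return AbundanceMatrix.from_frame(matrix.counts.copy(), prune=True)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(matrix.counts.to_numpy(), fraction)
    frame = pd.DataFrame(thinned, index=matrix.counts.index, columns=matrix.counts.columns)
    return AbundanceMatrix.from_frame(frame, prune=True)
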