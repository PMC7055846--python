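"""The combined non-parametric estimator (CNE) of species richness.

Chao1-type extrapolation uses within-sample singletons/doubletons and so
estimates the fauna of the sampled sites rather than of the whole region;
Chao2-type extrapolation uses across-site uniques/duplicates and accounts
for site heterogeneity, but undersampling of each site depresses the
observed numbers of unique and duplicate species.  The CNE combines the
two: a Chao1-type correction at each site first extrapolates how many
unique and duplicate species would have been observed with exhaustive
sampling there, and those extrapolated counts then feed a Chao2-type
across-site extrapolation.

Per site i (with F1/F2 the within-site singleton/doubleton species counts,
and "uniques"/"duplicates" the species observed only at site i / at site i
plus exactly one other site):

    extra_i  = F1_i * (F1_i - 1) / denom(F2_i)
    s_hat_i  = S_obs_i + extra_i
    s1_hat_i = uniques_i    + extra_i * uniques_i    / S_obs_i
    s2_hat_i = duplicates_i + extra_i * duplicates_i / S_obs_i

then

    Q1_hat = sum_i s1_hat_i
    Q2_hat = (1/2) * sum_i s2_hat_i
    S_CNE  = S_obs + Q1_hat * (Q1_hat - 1) / denom(Q2_hat)

The denominator convention is shared between the within-site and the final
step: ``corrected`` (default) uses the small-sample bias-corrected Chao
denominator ``2*(x+1)``; ``as_printed`` uses ``2*x+1``.

The estimator needs within-site abundance counts, so incidence-only input
is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import AbundanceMatrix, IncidenceMatrix
from .estimators import register_estimator
from .result import RichnessEstimate

__all__ = [
    "SiteStatistics",
    "SiteExtrapolation",
    "CNEBreakdown",
    "site_statistics",
    "site_extrapolation",
    "cne_estimate",
]

_DENOMS = ("corrected", "as_printed")


@dataclass(frozen=True)
class SiteStatistics:
    """Per-site counts feeding the CNE recursion."""

    site_id: str
    s_obs_i: int  # species observed at site i
    f1_i: int  # species observed exactly once at site i
    f2_i: int  # species observed exactly twice at site i
    uniques_obs_i: int  # observed species occurring only at site i
    duplicates_obs_i: int  # observed species occurring at site i and one other


@dataclass(frozen=True)
class SiteExtrapolation:
    """Chao1-type within-site extrapolations for one site."""

    site_id: str
    s_hat: float  # estimated species at the site
    s1_hat: float  # estimated unique species at the site
    s2_hat: float  # estimated duplicate species at the site


@dataclass(frozen=True)
class CNEBreakdown:
    """Full CNE computation: per-site extrapolations and the final estimate."""

    per_site: tuple[SiteExtrapolation, ...]
    q1_hat: float
    q2_hat: float
    s_obs: int
    point: float

    def to_estimate(self) -> RichnessEstimate:
        return RichnessEstimate(
            "cne",
            self.point,
            inputs={
                "s_obs": self.s_obs,
                "Q1_hat": self.q1_hat,
                "Q2_hat": self.q2_hat,
                "n_sites": len(self.per_site),
            },
        )


def site_statistics(matrix: AbundanceMatrix) -> list[SiteStatistics]:
    """Within-site singleton/doubleton counts and across-site occupancy roles.

    Sites with zero specimens are excluded (they carry no information).
    """
    if isinstance(matrix, IncidenceMatrix):
        raise TypeError(
            "CNE needs within-site abundance counts; incidence-only data "
            "cannot supply F1(i)/F2(i) — use chao2 or the jackknife instead"
        )
    counts = matrix.counts.to_numpy()
    occupancy = (counts > 0).sum(axis=0)  # sites per species
    stats: list[SiteStatistics] = []
    for i, site_id in enumerate(matrix.site_ids):
        row = counts[i]
        present = row > 0
        if not present.any():
            continue
        stats.append(
            SiteStatistics(
                site_id=str(site_id),
                s_obs_i=int(present.sum()),
                f1_i=int((row == 1).sum()),
                f2_i=int((row == 2).sum()),
                uniques_obs_i=int((present & (occupancy == 1)).sum()),
                duplicates_obs_i=int((present & (occupancy == 2)).sum()),
            )
        )
    return stats


def _denom(x: float, convention: str) -> float:
    if convention == "corrected":
        return 2.0 * (x + 1.0)
    if convention == "as_printed":
        return 2.0 * x + 1.0
    raise ValueError(f"cne denominator must be one of {_DENOMS}, got {convention!r}")


def site_extrapolation(
    stats: SiteStatistics, denominator: str = "corrected"
) -> SiteExtrapolation:
    """Extrapolate site richness and unique/duplicate species counts at one site."""
    if stats.s_obs_i < 1:
        raise ValueError(f"site {stats.site_id!r} has no observed species")
    extra = stats.f1_i * (stats.f1_i - 1) / _denom(stats.f2_i, denominator)
    frac_u = stats.uniques_obs_i / stats.s_obs_i
    frac_d = stats.duplicates_obs_i / stats.s_obs_i
    return SiteExtrapolation(
        site_id=stats.site_id,
        s_hat=stats.s_obs_i + extra,
        s1_hat=stats.uniques_obs_i + extra * frac_u,
        s2_hat=stats.duplicates_obs_i + extra * frac_d,
    )


def cne_estimate(
    matrix: AbundanceMatrix, denominator: str = "corrected"
) -> CNEBreakdown:
    """Combined non-parametric estimate of total richness from a site-by-species matrix."""
    stats = site_statistics(matrix)
    if len(stats) < 2:
        raise ValueError(
            "the combined non-parametric estimator needs at least 2 sites "
            f"with specimens (got {len(stats)}); across-site extrapolation "
            "is undefined otherwise"
        )
    per_site = tuple(site_extrapolation(s, denominator) for s in stats)
    q1_hat = float(sum(e.s1_hat for e in per_site))
    q2_hat = 0.5 * float(sum(e.s2_hat for e in per_site))
    s_obs = int((matrix.counts.to_numpy().sum(axis=0) > 0).sum())
    point = s_obs + q1_hat * (q1_hat - 1.0) / _denom(q2_hat, denominator)
    return CNEBreakdown(
        per_site=per_site, q1_hat=q1_hat, q2_hat=q2_hat, s_obs=s_obs, point=point
    )


register_estimator(
    "cne", lambda m, denominator="corrected": cne_estimate(m, denominator).to_estimate()
)
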