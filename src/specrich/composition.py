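"""Compositional analyses: trait proportions across site groupings, a
permutation test for trends in those proportions, and species-area scaling
diagnostics.

The permutation test asks whether, say, the proportion of Diptera species
differs across biogeographic zones more than expected if traps were
assigned to zones at random: trap-to-group labels are permuted, the test
statistic recomputed, and the observed value compared with that null
distribution.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import AbundanceMatrix, IncidenceMatrix

__all__ = [
    "proportion_by_group",
    "PermutationTestResult",
    "permutation_test",
    "species_area_exponent",
    "AreaLatitudeResult",
    "area_controlled_richness",
]


def _presence_frame(matrix: AbundanceMatrix | IncidenceMatrix) -> pd.DataFrame:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.counts > 0
    return matrix.presence


def _focal_mask(
    species: Sequence[str], traits: Mapping[str, str], focal: str
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over species: (has a trait label, label == focal)."""
    labelled = np.array([s in traits for s in species])
    if not labelled.all():
        missing = [s for s, ok in zip(species, labelled) if not ok]
        warnings.warn(
            f"{len(missing)} species lack a trait label and are excluded "
            f"(e.g. {missing[:3]})",
            stacklevel=3,
        )
    is_focal = np.array([traits.get(s) == focal for s in species])
    return labelled, is_focal


def _group_proportions(
    presence: np.ndarray,
    labelled: np.ndarray,
    is_focal: np.ndarray,
    group_of_site: np.ndarray,
    groups: Sequence[str],
) -> np.ndarray:
    props = np.empty(len(groups))
    for g, group in enumerate(groups):
        pooled = presence[group_of_site == g].any(axis=0)
        denom = int((pooled & labelled).sum())
        if denom == 0:
            raise ValueError(f"group {group!r} contains no labelled species")
        props[g] = (pooled & labelled & is_focal).sum() / denom
    return props


def proportion_by_group(
    matrix: AbundanceMatrix | IncidenceMatrix,
    traits: Mapping[str, str],
    trap_groups: Mapping[str, str],
    focal: str,
) -> dict[str, float]:
    """Fraction of distinct species carrying the focal trait label, per site group.

    Species are pooled over each group's sites; species without a trait
    label are excluded (with a warning).
    """
    presence = _presence_frame(matrix)
    unassigned = [s for s in presence.index if s not in trap_groups]
    if unassigned:
        raise ValueError(f"sites without a group assignment: {unassigned}")
    groups = sorted({trap_groups[s] for s in presence.index})
    group_of_site = np.array(
        [groups.index(trap_groups[s]) for s in presence.index]
    )
    labelled, is_focal = _focal_mask(list(presence.columns), traits, focal)
    props = _group_proportions(
        presence.to_numpy(), labelled, is_focal, group_of_site, groups
    )
    return dict(zip(groups, props))


@dataclass(frozen=True)
class PermutationTestResult:
    observed_statistic: float
    p_value: float
    null_mean: float
    null_sd: float
    n_permutations: int
    seed: int | None
    statistic: str
    group_proportions: Mapping[str, float]


def _statistic(props: np.ndarray, kind: str) -> float:
    if kind == "extreme_diff":
        return float(props[-1] - props[0])
    if kind == "trend":  # OLS slope of proportion on group rank
        x = np.arange(len(props), dtype=float)
        x = x - x.mean()
        return float((x * (props - props.mean())).sum() / (x * x).sum())
    raise ValueError(f"unknown statistic {kind!r}")


def permutation_test(
    matrix: AbundanceMatrix | IncidenceMatrix,
    traits: Mapping[str, str],
    trap_groups: Mapping[str, str],
    focal: str,
    statistic: str = "extreme_diff",
    group_order: Sequence[str] | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alternative: str = "observed",
    method: str = "random",
) -> PermutationTestResult:
    """Permutation test for a trend in trait proportions across site groups.

    Trap-to-group assignments are permuted uniformly (group sizes held
    fixed); the statistic is either the difference in focal-trait proportion
    between the last and first group of ``group_order`` (``extreme_diff``,
    default) or the slope of proportion on group rank (``trend``).

    ``alternative``: ``"observed"`` (one-sided in the direction of the
    observed statistic, the default), ``"greater"``, ``"less"`` or
    ``"two-sided"``.  With ``method="random"`` the p-value uses the add-one
    Monte-Carlo convention ``(1 + #{null at least as extreme}) /
    (n_permutations + 1)``; ``method="exact"`` enumerates all distinct
    assignments (small designs only) and divides by their number.
    """
    presence = _presence_frame(matrix)
    unassigned = [s for s in presence.index if s not in trap_groups]
    if unassigned:
        raise ValueError(f"sites without a group assignment: {unassigned}")
    groups = list(group_order) if group_order else sorted(
        {trap_groups[s] for s in presence.index}
    )
    if len(groups) < 2:
        raise ValueError("permutation test needs at least 2 groups")
    labels = np.array([groups.index(trap_groups[s]) for s in presence.index])
    labelled, is_focal = _focal_mask(list(presence.columns), traits, focal)
    pres = presence.to_numpy()

    def stat(lab: np.ndarray) -> float:
        return _statistic(
            _group_proportions(pres, labelled, is_focal, lab, groups), statistic
        )

    observed = stat(labels)

    if alternative == "observed":
        direction = "less" if observed < 0 else "greater"
    else:
        direction = alternative

    def as_extreme(null: float) -> bool:
        if direction == "greater":
            return null >= observed
        if direction == "less":
            return null <= observed
        if direction == "two-sided":
            return abs(null) >= abs(observed)
        raise ValueError(f"unknown alternative {alternative!r}")

    if method == "exact":
        perms = {p for p in itertools.permutations(labels.tolist())}
        hits = sum(as_extreme(stat(np.array(p))) for p in perms)
        nulls = [stat(np.array(p)) for p in perms]
        n_used = len(perms)
        p_value = hits / n_used
    elif method == "random":
        rng = np.random.default_rng(seed)
        nulls = []
        hits = 0
        for _ in range(n_permutations):
            null = stat(rng.permutation(labels))
            nulls.append(null)
            hits += as_extreme(null)
        n_used = n_permutations
        p_value = (1 + hits) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    nulls_arr = np.asarray(nulls)
    props = _group_proportions(pres, labelled, is_focal, labels, groups)
    return PermutationTestResult(
        observed_statistic=observed,
        p_value=float(p_value),
        null_mean=float(nulls_arr.mean()),
        null_sd=float(nulls_arr.std()),
        n_permutations=n_used,
        seed=seed,
        statistic=statistic,
        group_proportions=dict(zip(groups, props)),
    )


# ---------------------------------------------------------------------------
# species-area scaling


def species_area_exponent(richness: int, area: float) -> float:
    """Power-law exponent z implied by one (richness, area) point: ln(S)/ln(A)."""
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if area <= 1:
        raise ValueError("area must exceed 1 (log-log exponent undefined otherwise)")
    return math.log(richness) / math.log(area)


@dataclass(frozen=True)
class AreaLatitudeResult:
    """Species-area regression and latitude effect on its residuals."""

    area_slope: float
    area_intercept: float
    area_r2: float
    latitude_slope: float
    latitude_r2: float
    latitude_pvalue: float
    residuals: pd.Series
    excluded: tuple[str, ...]


def area_controlled_richness(
    fauna_table: pd.DataFrame, exclude: Sequence[str] = ()
) -> AreaLatitudeResult:
    """Latitudinal gradient in richness after removing the area effect.

    ``fauna_table`` is indexed by country with columns ``richness``,
    ``area`` and ``latitude``.  ln(richness) is regressed on ln(area) by
    OLS; the residuals are then regressed on latitude.  ``exclude`` drops
    listed countries (outliers) before both fits.
    """
    table = fauna_table.drop(index=list(exclude), errors="ignore")
    if len(table) < 3:
        raise ValueError("need at least 3 countries after exclusions")
    log_s = np.log(table["richness"].astype(float))
    log_a = np.log(table["area"].astype(float))
    area_fit = sm.OLS(log_s, sm.add_constant(log_a)).fit()
    residuals = pd.Series(area_fit.resid, index=table.index, name="residual")
    lat_fit = sm.OLS(
        residuals, sm.add_constant(table["latitude"].astype(float))
    ).fit()
    return AreaLatitudeResult(
        area_slope=float(area_fit.params.iloc[1]),
        area_intercept=float(area_fit.params.iloc[0]),
        area_r2=float(area_fit.rsquared),
        latitude_slope=float(lat_fit.params.iloc[1]),
        latitude_r2=float(lat_fit.rsquared),
        latitude_pvalue=float(lat_fit.pvalues.iloc[1]),
        residuals=residuals,
        excluded=tuple(exclude),
    )
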