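"""Chapman mark-recapture estimation of total species richness.

A faunal inventory can be read as a mark-recapture experiment on species:
the checklist of species known before sampling plays the role of the marked
cohort, and the fraction of already-known ("recaptured") species in the new
sample extrapolates the checklist to the total species pool.  The Chapman
small-sample form is

    S_MR = (S_obs + 1) / (S_obs,known + 1) * (S_known + 1) - 1

which, unlike the plain Lincoln-Petersen index, is defined even when no
species of the group were known before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .result import RichnessEstimate

__all__ = ["MRInput", "chapman_mr", "mr_from_table_row", "mr_from_species_sets"]


@dataclass(frozen=True)
class MRInput:
    """Tallies for the mark-recapture estimator.

    s_obs:
        number of species observed in the sample.
    s_obs_known:
        number of observed species that were already on the prior checklist.
    s_known:
        size of the prior checklist.
    """

    s_obs: int
    s_obs_known: int
    s_known: int

    def __post_init__(self) -> None:
        for name in ("s_obs", "s_obs_known", "s_known"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.s_obs_known > self.s_obs:
            raise ValueError(
                f"s_obs_known ({self.s_obs_known}) cannot exceed s_obs ({self.s_obs})"
            )
        if self.s_obs_known > self.s_known:
            raise ValueError(
                f"s_obs_known ({self.s_obs_known}) cannot exceed s_known ({self.s_known})"
            )


def chapman_mr(inp: MRInput) -> RichnessEstimate:
    """Chapman mark-recapture estimate of the total species pool."""
    point = (inp.s_obs + 1) / (inp.s_obs_known + 1) * (inp.s_known + 1) - 1
    return RichnessEstimate(
        estimator="mr",
        point=point,
        inputs={
            "s_obs": inp.s_obs,
            "s_obs_known": inp.s_obs_known,
            "s_known": inp.s_known,
        },
    )


def mr_from_table_row(known_prior: int, spp: int, new: int) -> RichnessEstimate:
    """Mark-recapture estimate from summary tallies as printed in inventory tables.

    ``known_prior`` is the checklist size before the inventory, ``spp`` the
    number of species found, and ``new`` how many of those were not on the
    checklist (so ``spp - new`` were recaptures).
    """
    if new > spp:
        raise ValueError(f"new species ({new}) cannot exceed species observed ({spp})")
    return chapman_mr(MRInput(s_obs=spp, s_obs_known=spp - new, s_known=known_prior))


def mr_from_species_sets(
    observed: Iterable[str], known_pool: Iterable[str]
) -> RichnessEstimate:
    """Mark-recapture estimate from an observed species list and a prior checklist.

    Overlap is computed by exact label match after whitespace trimming.
    """
    obs = {str(s).strip() for s in observed}
    known = {str(s).strip() for s in known_pool}
    return chapman_mr(
        MRInput(s_obs=len(obs), s_obs_known=len(obs & known), s_known=len(known))
    )
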