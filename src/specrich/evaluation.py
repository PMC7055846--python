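"""Estimator-performance framework: log-scale accuracy, effort diagnostics,
species accumulation curves, and the multi-dataset benchmark harness.

Accuracy is measured on the natural-log scale: for an estimate S_hat of a
true richness S, the bias is ``ln(S_hat) - ln(S)`` and the squared error its
square.  A mean squared log-error of e corresponds to a typical
multiplicative error factor of ``exp(sqrt(e))`` (e.g. 0.4 -> off by a factor
of about 1.9).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import AbundanceMatrix, IncidenceMatrix
from .estimators import ESTIMATORS, AbundanceSummary, IncidenceSummary

__all__ = [
    "evaluate",
    "EffortMeasures",
    "effort_measures",
    "benchmark",
    "AccumulationCurve",
    "accumulation_curve",
    "expected_accumulation",
]

logger = logging.getLogger(__name__)


def evaluate(s_hat: float, s_true: float) -> tuple[float, float]:
    """Return ``(squared_log_error, log_bias)`` of an estimate, natural log."""
    if not (s_hat > 0 and s_true > 0):
        raise ValueError(f"estimates and truths must be positive, got ({s_hat}, {s_true})")
    log_bias = math.log(s_hat) - math.log(s_true)
    return log_bias * log_bias, log_bias


@dataclass(frozen=True)
class EffortMeasures:
    """Sampling-effort diagnostics of a dataset.

    Abundance-based: proportion of singleton species (F1/S_obs) and
    specimens per species (N/S_obs).  Incidence-based: proportion of unique
    species (Q1/S_obs) and site occurrences per species.  The abundance
    measures are ``None`` for incidence-only data.
    """

    singleton_proportion: float | None
    specimens_per_species: float | None
    unique_proportion: float
    occurrences_per_species: float


def effort_measures(matrix: AbundanceMatrix | IncidenceMatrix) -> EffortMeasures:
    inc = IncidenceSummary.from_matrix(matrix)
    if inc.s_obs == 0:
        raise ValueError("empty matrix")
    occurrences = float(sum(inc.occupancies))
    singleton_prop = specimens_per = None
    if isinstance(matrix, AbundanceMatrix):
        ab = AbundanceSummary.from_matrix(matrix)
        singleton_prop = ab.f1 / ab.s_obs
        specimens_per = ab.n_specimens / ab.s_obs
    return EffortMeasures(
        singleton_proportion=singleton_prop,
        specimens_per_species=specimens_per,
        unique_proportion=inc.q1 / inc.s_obs,
        occurrences_per_species=occurrences / inc.s_obs,
    )


def _dataset_size(matrix: AbundanceMatrix | IncidenceMatrix) -> tuple[int, int]:
    """(specimens-or-occurrences, sites) used for inclusion thresholds."""
    if isinstance(matrix, AbundanceMatrix):
        return matrix.n_specimens, matrix.n_sites
    return int(matrix.presence.to_numpy().sum()), matrix.n_sites


def benchmark(
    datasets: Iterable[tuple[AbundanceMatrix | IncidenceMatrix, float, str]],
    estimators: Sequence[str] = ("chao1", "chao2", "cne"),
    min_specimens: int = 100,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Evaluate estimators on datasets with known true richness.

    Parameters
    ----------
    datasets:
        iterables of ``(matrix, s_true, group_label)``; the true richness is
        supplied as data (expert totals, a prior checklist size, or a
        simulation's pool size), never computed here.
    estimators:
        names from the estimator registry.
    min_specimens, min_sites:
        inclusion thresholds: a dataset enters the benchmark only with
        *more than* ``min_specimens`` specimens from *more than*
        ``min_sites`` sites (defaults 100 and 5).  Excluded datasets are
        logged.

    Returns a table with one row per (dataset, estimator): the estimate, the
    truth, coverage of the species pool, squared log-error, log bias, and
    effort diagnostics.  Estimators inapplicable to a dataset's data type
    yield a row with status ``not_applicable`` rather than an error.
    """
    rows: list[dict] = []
    for matrix, s_true, group in datasets:
        size, n_sites = _dataset_size(matrix)
        if not (size > min_specimens and n_sites > min_sites):
            logger.info(
                "benchmark: excluding %r (%d specimens, %d sites)", group, size, n_sites
            )
            continue
        inc = IncidenceSummary.from_matrix(matrix)
        coverage = inc.s_obs / s_true
        effort = effort_measures(matrix)
        for name in estimators:
            row = {
                "group": group,
                "estimator": name,
                "s_true": float(s_true),
                "s_obs": inc.s_obs,
                "coverage": coverage,
                "n_sites": n_sites,
                "singleton_proportion": effort.singleton_proportion,
                "specimens_per_species": effort.specimens_per_species,
                "unique_proportion": effort.unique_proportion,
                "occurrences_per_species": effort.occurrences_per_species,
            }
            try:
                est = ESTIMATORS[name](matrix)
                sq, bias = evaluate(est.point, s_true)
                row |= {
                    "s_hat": est.point,
                    "sq_log_error": sq,
                    "log_bias": bias,
                    "status": "ok",
                }
            except (TypeError, ValueError) as exc:
                row |= {
                    "s_hat": np.nan,
                    "sq_log_error": np.nan,
                    "log_bias": np.nan,
                    "status": "not_applicable",
                }
                logger.debug("benchmark: %s on %r not applicable: %s", name, group, exc)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# accumulation curves


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean species accumulation over random site orderings."""

    n_sites_axis: np.ndarray
    mean_richness: np.ndarray
    quantile_low: np.ndarray
    quantile_high: np.ndarray
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_sites": self.n_sites_axis,
                "mean_richness": self.mean_richness,
                "q_low": self.quantile_low,
                "q_high": self.quantile_high,
            }
        )


def accumulation_curve(
    matrix: AbundanceMatrix | IncidenceMatrix,
    n_permutations: int = 10_000,
    seed: int | None = None,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> AccumulationCurve:
    """Species accumulation curve from random perturbations of site order.

    For each prefix length k, the mean (over random site orderings) of the
    number of distinct species among the first k sites.  Deterministic for a
    given seed.
    """
    presence = (
        matrix.counts.to_numpy() > 0
        if isinstance(matrix, AbundanceMatrix)
        else matrix.presence.to_numpy()
    )
    n_sites = presence.shape[0]
    if n_sites < 1:
        raise ValueError("accumulation curve needs at least one site")
    rng = np.random.default_rng(seed)
    richness = np.empty((n_permutations, n_sites), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n_sites)
        seen = np.logical_or.accumulate(presence[order], axis=0)
        richness[p] = seen.sum(axis=1)
    lo, hi = quantiles
    return AccumulationCurve(
        n_sites_axis=np.arange(1, n_sites + 1),
        mean_richness=richness.mean(axis=0),
        quantile_low=np.quantile(richness, lo, axis=0),
        quantile_high=np.quantile(richness, hi, axis=0),
        n_permutations=n_permutations,
        seed=seed,
    )


def expected_accumulation(
    matrix: AbundanceMatrix | IncidenceMatrix,
) -> np.ndarray:
    """Exact expected accumulation curve under uniformly random site order.

    E[S(k)] = sum_j (1 - C(n - o_j, k) / C(n, k)) with o_j the number of
    sites occupied by species j — the hypergeometric limit the permutation
    curve converges to.
    """
    presence = (
        matrix.counts.to_numpy() > 0
        if isinstance(matrix, AbundanceMatrix)
        else matrix.presence.to_numpy()
    )
    n = presence.shape[0]
    occ = presence.sum(axis=0)

    def log_choose(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(n)
    for k in range(1, n + 1):
        miss = n - occ
        prob_absent = np.where(
            miss >= k, np.exp(log_choose(miss, k) - log_choose(np.array(n), k)), 0.0
        )
        out[k - 1] = (1.0 - prob_absent).sum()
    return out
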