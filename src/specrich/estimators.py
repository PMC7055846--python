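"""Classical species richness estimators.

Two families, following the usual division in community ecology software:

* abundance-based, computed from the pooled specimen counts of the whole
  sample — Chao1, ACE, and the Preston lognormal (parametric) estimator;
* incidence-based, computed from species occurrences across sampling
  sites — Chao2, first- and second-order jackknife, and the bootstrap.

Abundance-based estimators deliberately ignore site structure; asking for
one on incidence-only data is an error rather than a silent approximation.

Formula conventions match the vegan R package (``estimateR``/``specpool``/
``prestonfit``): Chao estimators default to the small-sample bias-corrected
denominators ``2*(F2+1)`` / ``2*(Q2+1)``, and Chao2 carries the
``(n-1)/n`` factor.  The classic uncorrected forms are available via
``variant="classic"``.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .datamodel import AbundanceMatrix, IncidenceMatrix
from .result import RichnessEstimate

__all__ = [
    "AbundanceSummary",
    "IncidenceSummary",
    "PrestonFit",
    "chao1",
    "ace",
    "chao2",
    "jackknife",
    "bootstrap_richness",
    "preston",
    "octave_frequencies",
    "fit_preston_octaves",
    "ESTIMATORS",
    "estimate_richness",
    "register_estimator",
]


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class AbundanceSummary:
    """Pooled abundance frequency counts: F_k = number of species with k specimens."""

    s_obs: int
    f_counts: Mapping[int, int]
    n_specimens: int

    @property
    def f1(self) -> int:
        return self.f_counts.get(1, 0)

    @property
    def f2(self) -> int:
        return self.f_counts.get(2, 0)

    @classmethod
    def from_abundances(cls, abundances: Iterable[int]) -> "AbundanceSummary":
        abund = [int(a) for a in abundances if a > 0]
        counts = Counter(abund)
        return cls(
            s_obs=len(abund), f_counts=dict(counts), n_specimens=int(sum(abund))
        )

    @classmethod
    def from_matrix(cls, matrix: AbundanceMatrix) -> "AbundanceSummary":
        if isinstance(matrix, IncidenceMatrix):
            raise TypeError(
                "abundance-based estimators require specimen counts; this "
                "group has incidence data only — use chao2/jackknife/bootstrap"
            )
        totals = matrix.counts.sum(axis=0).to_numpy()
        return cls.from_abundances(totals)

    @property
    def abundances(self) -> np.ndarray:
        out: list[int] = []
        for k, f in sorted(self.f_counts.items()):
            out.extend([k] * f)
        return np.asarray(out, dtype=np.int64)


@dataclass(frozen=True)
class IncidenceSummary:
    """Occupancy frequency counts: Q_m = number of species occurring at m sites."""

    s_obs: int
    n_sites: int
    q_counts: Mapping[int, int]
    occupancies: tuple[int, ...]

    @property
    def q1(self) -> int:
        return self.q_counts.get(1, 0)

    @property
    def q2(self) -> int:
        return self.q_counts.get(2, 0)

    @classmethod
    def from_matrix(
        cls, matrix: AbundanceMatrix | IncidenceMatrix
    ) -> "IncidenceSummary":
        if isinstance(matrix, AbundanceMatrix):
            presence = matrix.counts.to_numpy() > 0
        else:
            presence = matrix.presence.to_numpy()
        occ = presence.sum(axis=0).astype(int)
        occ = occ[occ > 0]
        return cls(
            s_obs=int(occ.size),
            n_sites=int(presence.shape[0]),
            q_counts=dict(Counter(occ.tolist())),
            occupancies=tuple(int(o) for o in occ),
        )


def _require_nonempty(s_obs: int, name: str) -> None:
    if s_obs < 1:
        raise ValueError(f"{name}: summary contains no observed species")


# ---------------------------------------------------------------------------
# abundance-based estimators


def chao1(
    summary: AbundanceSummary | Iterable[int], variant: str = "bias_corrected"
) -> RichnessEstimate:
    """Chao1 estimator from pooled singleton/doubleton counts.

    ``bias_corrected`` (default): S_obs + F1*(F1-1)/(2*(F2+1)).
    ``classic``: S_obs + F1^2/(2*F2), falling back to the bias-corrected
    term when F2 = 0 (where the classic form is undefined).
    """
    if not isinstance(summary, AbundanceSummary):
        summary = AbundanceSummary.from_abundances(summary)
    _require_nonempty(summary.s_obs, "chao1")
    f1, f2 = summary.f1, summary.f2
    if variant == "bias_corrected" or f2 == 0:
        extra = f1 * (f1 - 1) / (2.0 * (f2 + 1))
    elif variant == "classic":
        extra = f1 * f1 / (2.0 * f2)
    else:
        raise ValueError(f"unknown chao variant {variant!r}")
    return RichnessEstimate(
        "chao1",
        summary.s_obs + extra,
        inputs={"s_obs": summary.s_obs, "F1": f1, "F2": f2, "variant": variant},
    )


def ace(
    summary: AbundanceSummary | Iterable[int], rare_cutoff: int = 10
) -> RichnessEstimate:
    """Abundance-based coverage estimator (ACE).

    Species with total abundance <= ``rare_cutoff`` form the rare group on
    which sample coverage and the heterogeneity coefficient are estimated.
    When every rare species is a singleton (coverage 0) the estimator is
    undefined; Chao1 is returned instead, with a warning.
    """
    if not isinstance(summary, AbundanceSummary):
        summary = AbundanceSummary.from_abundances(summary)
    _require_nonempty(summary.s_obs, "ace")
    f = summary.f_counts
    s_rare = sum(v for k, v in f.items() if k <= rare_cutoff)
    s_abund = summary.s_obs - s_rare
    n_rare = sum(k * v for k, v in f.items() if k <= rare_cutoff)
    f1 = summary.f1
    if s_rare == 0:
        return RichnessEstimate(
            "ace", float(summary.s_obs), inputs={"s_obs": summary.s_obs, "S_rare": 0}
        )
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        warnings.warn(
            "ACE undefined (all rare species are singletons); "
            "falling back to Chao1",
            stacklevel=2,
        )
        fallback = chao1(summary)
        return RichnessEstimate("ace", fallback.point, inputs=dict(fallback.inputs))
    ssq = sum(k * (k - 1) * v for k, v in f.items() if k <= rare_cutoff)
    gamma_sq = max(
        s_rare / coverage * ssq / (n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0,
        0.0,
    )
    point = s_abund + s_rare / coverage + f1 / coverage * gamma_sq
    return RichnessEstimate(
        "ace",
        point,
        inputs={
            "s_obs": summary.s_obs,
            "S_rare": s_rare,
            "N_rare": n_rare,
            "coverage": coverage,
            "gamma_sq": gamma_sq,
            "rare_cutoff": rare_cutoff,
        },
    )


# ---------------------------------------------------------------------------
# incidence-based estimators


def _as_incidence(
    summary: IncidenceSummary | AbundanceMatrix | IncidenceMatrix,
) -> IncidenceSummary:
    if isinstance(summary, IncidenceSummary):
        return summary
    return IncidenceSummary.from_matrix(summary)


def chao2(
    summary: IncidenceSummary | AbundanceMatrix | IncidenceMatrix,
    variant: str = "bias_corrected",
) -> RichnessEstimate:
    """Chao2 estimator from across-site unique/duplicate species counts.

    ``bias_corrected`` (default): S_obs + ((n-1)/n) * Q1*(Q1-1)/(2*(Q2+1)).
    ``classic``: S_obs + ((n-1)/n) * Q1^2/(2*Q2), with the bias-corrected
    term as fallback when Q2 = 0 (vegan's specpool convention).
    """
    summary = _as_incidence(summary)
    n = summary.n_sites
    if n < 2:
        raise ValueError(f"chao2 requires at least 2 sites, got {n}")
    q1, q2 = summary.q1, summary.q2
    if variant == "bias_corrected" or q2 == 0:
        extra = (n - 1) / n * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    elif variant == "classic":
        extra = (n - 1) / n * q1 * q1 / (2.0 * q2)
    else:
        raise ValueError(f"unknown chao variant {variant!r}")
    return RichnessEstimate(
        "chao2",
        summary.s_obs + extra,
        inputs={
            "s_obs": summary.s_obs,
            "Q1": q1,
            "Q2": q2,
            "n_sites": n,
            "variant": variant,
        },
    )


def jackknife(
    summary: IncidenceSummary | AbundanceMatrix | IncidenceMatrix, order: int = 1
) -> RichnessEstimate:
    """First- or second-order jackknife richness estimator."""
    summary = _as_incidence(summary)
    n = summary.n_sites
    if order not in (1, 2):
        raise ValueError(f"jackknife order must be 1 or 2, got {order}")
    if n < order + 1:
        raise ValueError(f"jackknife order {order} requires >= {order + 1} sites, got {n}")
    q1, q2 = summary.q1, summary.q2
    if order == 1:
        point = summary.s_obs + q1 * (n - 1) / n
    else:
        point = summary.s_obs + q1 * (2 * n - 3) / n - q2 * (n - 2) ** 2 / (n * (n - 1))
    return RichnessEstimate(
        f"jack{order}",
        point,
        inputs={"s_obs": summary.s_obs, "Q1": q1, "Q2": q2, "n_sites": n},
    )


def bootstrap_richness(
    summary: IncidenceSummary | AbundanceMatrix | IncidenceMatrix,
) -> RichnessEstimate:
    """Smith & van Belle bootstrap: S_obs + sum_k (1 - p_k)^n over species."""
    summary = _as_incidence(summary)
    _require_nonempty(summary.s_obs, "bootstrap")
    n = summary.n_sites
    p = np.asarray(summary.occupancies, dtype=float) / n
    point = summary.s_obs + float(((1.0 - p) ** n).sum())
    return RichnessEstimate(
        "bootstrap", point, inputs={"s_obs": summary.s_obs, "n_sites": n}
    )


# ---------------------------------------------------------------------------
# Preston lognormal


@dataclass(frozen=True)
class PrestonFit:
    """Gaussian fit to octave-binned abundance frequencies.

    ``veiled_richness`` is the total area under the fitted Gaussian,
    ``mode_height * width * sqrt(2*pi)`` — the estimated richness including
    species hidden behind the sampling veil line.
    """

    mode_height: float
    mode_location: float
    width: float
    observed_richness: int

    @property
    def veiled_richness(self) -> float:
        return self.mode_height * self.width * math.sqrt(2.0 * math.pi)

    @property
    def estimate(self) -> RichnessEstimate:
        return RichnessEstimate(
            "preston",
            max(self.veiled_richness, float(self.observed_richness)),
            inputs={
                "s_obs": self.observed_richness,
                "mode_height": self.mode_height,
                "mode_location": self.mode_location,
                "width": self.width,
            },
        )


def octave_frequencies(abundances: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
    """Bin abundances into log2 octaves, splitting boundary ties.

    Octave k has upper limit 2^k.  A species whose abundance is exactly a
    power of two sits on an octave boundary and contributes half a species
    to each adjacent octave (the prestonfit tie-split convention).
    """
    abund = np.asarray([a for a in abundances if a > 0], dtype=np.int64)
    if abund.size == 0:
        return np.array([], dtype=int), np.array([])
    max_oct = int(math.ceil(math.log2(max(int(abund.max()), 1)))) + 1
    freqs = np.zeros(max_oct + 1)
    for a in abund:
        if a & (a - 1) == 0:  # power of two: boundary tie
            k = int(round(math.log2(a)))
            freqs[k] += 0.5
            freqs[k + 1] += 0.5
        else:
            freqs[int(math.ceil(math.log2(a)))] += 1.0
    octaves = np.arange(freqs.size)
    keep = freqs > 0
    # trim trailing/leading empty octaves but keep internal zeros for fitting
    lo, hi = np.argmax(keep), len(keep) - np.argmax(keep[::-1])
    return octaves[lo:hi], freqs[lo:hi]


def _gaussian(x: np.ndarray, height: float, mode: float, width: float) -> np.ndarray:
    return height * np.exp(-((x - mode) ** 2) / (2.0 * width**2))


def fit_preston_octaves(
    octaves: np.ndarray, freqs: np.ndarray, s_obs: int | None = None
) -> PrestonFit:
    """Least-squares Gaussian fit to octave frequencies."""
    octaves = np.asarray(octaves, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.count_nonzero(freqs > 0) < 3:
        raise ValueError(
            "Preston fit needs at least 3 occupied octaves; the "
            "abundance distribution is too narrow to fit"
        )
    p0 = [float(freqs.max()), float(octaves[int(np.argmax(freqs))]), 1.5]
    try:
        popt, _ = curve_fit(
            _gaussian,
            octaves,
            freqs,
            p0=p0,
            bounds=([1e-9, -10.0, 1e-9], [np.inf, octaves.max() + 20.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"Preston fit failed to converge: {exc}") from exc
    height, mode, width = (float(v) for v in popt)
    return PrestonFit(
        mode_height=height,
        mode_location=mode,
        width=width,
        observed_richness=int(s_obs if s_obs is not None else round(freqs.sum())),
    )


def preston(summary: AbundanceSummary | Iterable[int]) -> PrestonFit:
    """Preston lognormal richness estimate from pooled abundances."""
    if not isinstance(summary, AbundanceSummary):
        summary = AbundanceSummary.from_abundances(summary)
    _require_nonempty(summary.s_obs, "preston")
    octaves, freqs = octave_frequencies(summary.abundances)
    return fit_preston_octaves(octaves, freqs, s_obs=summary.s_obs)


# ---------------------------------------------------------------------------
# matrix-level dispatch

EstimatorFunc = Callable[..., RichnessEstimate]

#: registry of matrix -> RichnessEstimate estimator functions, keyed by the
#: names used in output tables and the CLI.  Plug-in estimators (e.g.
#: sampling-effort-corrected variants) may be added via
#: :func:`register_estimator`.
ESTIMATORS: dict[str, EstimatorFunc] = {}


def register_estimator(name: str, func: EstimatorFunc) -> None:
    ESTIMATORS[name] = func


def _abundance_only(func: Callable) -> Callable:
    def wrapper(matrix, **kw):
        if isinstance(matrix, IncidenceMatrix):
            raise TypeError(
                f"{func.__name__} is abundance-based and cannot run on "
                "incidence-only data"
            )
        return func(AbundanceSummary.from_matrix(matrix), **kw)

    return wrapper


register_estimator("chao1", _abundance_only(chao1))
register_estimator("ace", _abundance_only(ace))
register_estimator("preston", lambda m, **kw: _abundance_only(preston)(m, **kw).estimate)
register_estimator("chao2", lambda m, **kw: chao2(m, **kw))
register_estimator("jack1", lambda m, **kw: jackknife(m, order=1))
register_estimator("jack2", lambda m, **kw: jackknife(m, order=2))
register_estimator("bootstrap", lambda m, **kw: bootstrap_richness(m))


def estimate_richness(
    matrix: AbundanceMatrix | IncidenceMatrix,
    methods: Sequence[str] = ("chao1", "ace", "chao2", "jack1", "jack2", "bootstrap"),
    **options,
) -> dict[str, RichnessEstimate]:
    """Run several estimators on one matrix.

    ``options`` are passed through to estimators that accept them (e.g.
    ``variant`` for the Chao estimators).
    """
    out: dict[str, RichnessEstimate] = {}
    for name in methods:
        if name not in ESTIMATORS:
            raise KeyError(f"unknown estimator {name!r}; known: {sorted(ESTIMATORS)}")
        func = ESTIMATORS[name]
        kw = {}
        if name in ("chao1", "chao2") and "variant" in options:
            kw["variant"] = options["variant"]
        if name == "ace" and "rare_cutoff" in options:
            kw["rare_cutoff"] = options["rare_cutoff"]
        if name == "cne" and "denominator" in options:
            kw["denominator"] = options["denominator"]
        out[name] = func(matrix, **kw)
    return out
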