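"""Domain types and delimited-text I/O for multi-site inventory data.

The analysis unit throughout the package is the *site-by-species matrix*:
rows are sampling sites (one Malaise trap = one site), columns are species,
cells are specimen counts (:class:`AbundanceMatrix`) or presences
(:class:`IncidenceMatrix`).  Raw inventory files are lists of records
(taxon, site, count); this module parses them, applies the standard
record-filtering rules for richness analyses, and aggregates them into
matrices.

Filtering rules
---------------
Records determined only to genus level (a taxon label ending in an
unqualified ``"sp."``) carry no species identity and are removed before any
richness analysis.  Records of unnamed but putatively distinct species
(flagged ``"sp. indet."`` in the author field) are kept, each treated as a
distinct species.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRecord",
    "AbundanceMatrix",
    "IncidenceMatrix",
    "KnownPool",
    "FilterTally",
    "ColumnConfigError",
    "read_records",
    "filter_records",
    "build_matrix",
]


class ColumnConfigError(KeyError):
    """A required column role is missing from the column mapping or file."""


_GENUS_ONLY_RE = re.compile(r"\bsp\.$")
_INDET_RE = re.compile(r"\bsp\.\s*indet\.")


@dataclass(frozen=True)
class SpeciesRecord:
    """One inventory data row: a taxon observed at a site.

    ``count`` is ``None`` for incidence-only records.  ``genus_only`` marks
    records identified only to genus (taxon label ends in an unqualified
    ``"sp."``); ``indet_distinct`` marks unnamed-but-distinct species
    (``"sp. indet."``).  The two flags are mutually exclusive.
    """

    taxon: str
    site: str
    count: int | None = None
    sample: str | None = None
    genus_only: bool = False
    indet_distinct: bool = False
    known_prior: bool = False

    def __post_init__(self) -> None:
        if self.count is not None and self.count < 1:
            raise ValueError(
                f"record for {self.taxon!r} at {self.site!r} has count "
                f"{self.count}; counts must be >= 1 when present"
            )
        if self.genus_only and self.indet_distinct:
            raise ValueError(
                f"record {self.taxon!r}: genus_only and indet_distinct are "
                "mutually exclusive"
            )


def classify_taxon(taxon: str, author: str | None = None) -> tuple[bool, bool]:
    """Return ``(genus_only, indet_distinct)`` flags for a taxon label.

    ``indet_distinct`` wins when the author field carries ``"sp. indet."``;
    otherwise a label ending in a bare ``"sp."`` is genus-only.
    """
    taxon = taxon.strip()
    if not isinstance(author, str):  # None or a NaN cell
        author = ""
    author = author.strip()
    if _INDET_RE.search(author) or _INDET_RE.search(taxon):
        return False, True
    return bool(_GENUS_ONLY_RE.search(taxon)), False


@dataclass(frozen=True)
class KnownPool:
    """The checklist of species known for a group before the inventory."""

    group_name: str
    species: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.species)

    @classmethod
    def from_file(cls, path: str | Path, group_name: str | None = None) -> "KnownPool":
        """Read a one-label-per-line checklist (blank lines and # comments skipped)."""
        path = Path(path)
        labels = [
            line.strip()
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        return cls(group_name or path.stem, frozenset(labels))


def _validated_frame(frame: pd.DataFrame, prune: bool) -> pd.DataFrame:
    if frame.size:
        if prune:
            frame = frame.loc[frame.sum(axis=1) > 0, frame.sum(axis=0) > 0]
        else:
            if (frame.sum(axis=1) == 0).any():
                raise ValueError("matrix has an all-zero site row")
            if (frame.sum(axis=0) == 0).any():
                raise ValueError("matrix has an all-zero species column")
    return frame


@dataclass
class AbundanceMatrix:
    """Site-by-species specimen counts (sites as rows, species as columns)."""

    counts: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, prune: bool = True) -> "AbundanceMatrix":
        frame = frame.fillna(0)
        arr = frame.to_numpy()
        if arr.size and ((arr < 0).any() or (arr != np.floor(arr)).any()):
            raise ValueError("abundance matrix cells must be non-negative integers")
        return cls(_validated_frame(frame.astype(np.int64), prune))

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def n_specimens(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_incidence(self) -> "IncidenceMatrix":
        return IncidenceMatrix(self.counts > 0)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.counts.to_csv(path, sep=sep, index_label="site")

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None) -> "AbundanceMatrix":
        frame = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        frame.index = frame.index.astype(str)
        frame.index.name = None
        return cls.from_frame(frame)


@dataclass
class IncidenceMatrix:
    """Site-by-species presence/absence (boolean)."""

    presence: pd.DataFrame

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)

    @property
    def site_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_sites(self) -> int:
        return self.presence.shape[0]

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.presence.astype(int).to_csv(path, sep=sep, index_label="site")

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None) -> "IncidenceMatrix":
        frame = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        frame.index = frame.index.astype(str)
        frame.index.name = None
        return cls(frame > 0)


# ---------------------------------------------------------------------------
# record ingestion


#: default column-role mapping for :func:`read_records`
DEFAULT_COLUMNS: Mapping[str, str] = {
    "taxon": "taxon",
    "site": "site",
    "count": "count",
}


def read_records(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    known_pool: KnownPool | None = None,
) -> list[SpeciesRecord]:
    """Parse a delimited-text record file into :class:`SpeciesRecord` objects.

    Parameters
    ----------
    path:
        CSV or TSV file with one header row; the delimiter is auto-detected
        unless ``delimiter`` is given.
    columns:
        Mapping from column *roles* to the column names used in the file.
        Roles: ``taxon`` and ``site`` (required); ``count``, ``sample`` and
        ``author`` (optional).  A missing ``count`` column yields
        incidence-only records.
    known_pool:
        When given, records whose taxon label is in the pool get
        ``known_prior=True``.

    Raises
    ------
    ColumnConfigError
        When a required role cannot be resolved to a file column.
    ValueError
        When a count cell is not a non-negative integer (the offending row
        is named).
    """
    columns = dict(DEFAULT_COLUMNS) | dict(columns or {})
    frame = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    for role in ("taxon", "site"):
        if columns[role] not in frame.columns:
            raise ColumnConfigError(
                f"required column {columns[role]!r} (role {role!r}) not found "
                f"in {path}; available: {list(frame.columns)}"
            )
    count_col = columns.get("count")
    has_counts = count_col is not None and count_col in frame.columns
    sample_col = columns.get("sample")
    author_col = columns.get("author")
    known = known_pool.species if known_pool is not None else frozenset()

    records: list[SpeciesRecord] = []
    n_zero = 0
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        taxon = str(row[columns["taxon"]]).strip()
        site = str(row[columns["site"]]).strip()
        count: int | None = None
        if has_counts:
            raw = row[count_col]
            try:
                count = int(str(raw).strip())
                if count < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {row_no} of {path}: count {raw!r} is not a "
                    "non-negative integer"
                ) from None
            if count == 0:
                n_zero += 1
                continue
        author = row.get(author_col) if author_col else None
        genus_only, indet = classify_taxon(taxon, author)
        records.append(
            SpeciesRecord(
                taxon=taxon,
                site=site,
                count=count,
                sample=(str(row[sample_col]).strip() if sample_col and sample_col in row else None),
                genus_only=genus_only,
                indet_distinct=indet,
                known_prior=taxon in known,
            )
        )
    if n_zero:
        warnings.warn(
            f"{path}: dropped {n_zero} record(s) with count 0 (non-observations)",
            stacklevel=2,
        )
    return records


@dataclass(frozen=True)
class FilterTally:
    """Summary of what :func:`filter_records` removed."""

    records_removed: int
    taxa_removed: int


def filter_records(
    records: Sequence[SpeciesRecord],
) -> tuple[list[SpeciesRecord], FilterTally]:
    """Drop genus-level records; keep ``sp. indet.`` records as distinct species.

    Returns the retained records plus a tally of removed records and taxa.
    Idempotent: filtering a filtered list removes nothing further.
    """
    kept = [r for r in records if not r.genus_only]
    removed = [r for r in records if r.genus_only]
    tally = FilterTally(
        records_removed=len(removed),
        taxa_removed=len({r.taxon for r in removed}),
    )
    return kept, tally


def build_matrix(
    records: Sequence[SpeciesRecord],
) -> AbundanceMatrix | IncidenceMatrix:
    """Aggregate records to a site-by-species matrix, pooling samples per site.

    Counts are summed per (site, species).  If *any* record lacks a count the
    whole group is demoted to an :class:`IncidenceMatrix` (with a warning when
    abundance information is discarded), mirroring groups whose abundances
    were not reported consistently.
    """
    if not records:
        raise ValueError("cannot build a matrix from an empty record list")
    incidence_only = any(r.count is None for r in records)
    if incidence_only and any(r.count is not None for r in records):
        warnings.warn(
            "mixed abundance/incidence records: group demoted to incidence",
            stacklevel=2,
        )
    frame = pd.DataFrame(
        {
            "site": [r.site for r in records],
            "taxon": [r.taxon for r in records],
            "count": [1 if r.count is None else r.count for r in records],
        }
    )
    table = frame.pivot_table(
        index="site", columns="taxon", values="count", aggfunc="sum", fill_value=0
    )
    table = table.sort_index(axis=0).sort_index(axis=1)
    table.index.name = None
    table.columns.name = None
    if incidence_only:
        return IncidenceMatrix(table > 0)
    return AbundanceMatrix.from_frame(table)
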