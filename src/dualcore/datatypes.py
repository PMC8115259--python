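"""Shared domain types.

All tabular types wrap pandas objects and validate on construction; they are
deliberately thin so that every module works directly on the underlying
DataFrame when convenient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TaxonomyTable",
    "GenomeContentTable",
    "FunctionTable",
    "CoreSet",
    "CoreSummary",
    "TAXONOMY_RANKS",
    "UNASSIGNED",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

_REL_TOL = 1e-9


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dup}")


@dataclass
class AbundanceTable:
    """Feature-by-sample abundance matrix with per-sample metadata.

    Parameters
    ----------
    data : pd.DataFrame
        Rows are ASV ids, columns are sample ids. Non-negative.
    metadata : pd.DataFrame, optional
        Indexed by sample id; typical columns are ``study``, ``habitat``
        and ``group``. Must cover every sample in ``data``.
    is_relative : bool
        If True, each sample column must sum to 1 (within 1e-9).
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        _check_unique(self.data.index, "ASV")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative entry at ASV {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.metadata is not None:
            missing = self.data.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing sample(s): {missing.tolist()}")
        if self.is_relative and self.data.shape[1]:
            sums = values.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > _REL_TOL):
                bad = self.data.columns[np.abs(sums - 1.0) > _REL_TOL]
                raise ValueError(
                    f"relative table columns must sum to 1: {bad.tolist()}"
                )

    @property
    def asv_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_asvs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_metadata(self, samples) -> pd.DataFrame | None:
        if self.metadata is None:
            return None
        return self.metadata.loc[list(samples)]

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        if self.is_relative != other.is_relative:
            return False
        if not self.data.equals(other.data):
            return False
        if (self.metadata is None) != (other.metadata is None):
            return False
        if self.metadata is not None and not self.metadata.equals(other.metadata):
            return False
        return True


@dataclass
class TaxonomyTable:
    """ASV id -> six-rank lineage, with an explicit 'unassigned' sentinel."""

    data: pd.DataFrame  # index: asv_id, columns: TAXONOMY_RANKS

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ASV")
        if tuple(self.data.columns) != TAXONOMY_RANKS:
            raise ValueError(
                f"taxonomy columns must be {TAXONOMY_RANKS}, got "
                f"{tuple(self.data.columns)}"
            )

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        return tuple(self.data.loc[asv_id])


@dataclass
class GenomeContentTable:
    """Per-ASV KO copy numbers plus 16S rRNA gene copy numbers."""

    ko_copies: pd.DataFrame  # index: asv_id, columns: ko_id, integer >= 0
    ssu_copies: pd.Series  # index: asv_id, integer >= 1

    def __post_init__(self) -> None:
        _check_unique(self.ko_copies.index, "ASV")
        _check_unique(self.ko_copies.columns, "KO")
        if self.ko_copies.size and self.ko_copies.to_numpy().min() < 0:
            raise ValueError("negative KO copy number")
        missing = self.ko_copies.index.difference(self.ssu_copies.index)
        if len(missing):
            raise ValueError(f"16S copy number missing for: {missing.tolist()}")
        if len(self.ssu_copies) and self.ssu_copies.min() < 1:
            bad = self.ssu_copies.index[self.ssu_copies < 1].tolist()
            raise ValueError(f"16S copy number must be >= 1: {bad}")

    @property
    def asv_ids(self) -> list[str]:
        return self.ko_copies.index.tolist()

    @property
    def ko_ids(self) -> list[str]:
        return self.ko_copies.columns.tolist()


@dataclass
class FunctionTable:
    """Predicted KO- or pathway-level abundances (features x samples)."""

    level: str  # "KO" | "pathway" | "aggregated" (taxonomy-rank sums)
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in ("KO", "pathway", "aggregated"):
            raise ValueError(
                f"level must be 'KO', 'pathway' or 'aggregated', got {self.level!r}"
            )
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        if self.data.size and self.data.to_numpy().min() < 0:
            raise ValueError("negative abundance in function table")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()


@dataclass
class CoreSet:
    """A named set of core ASVs with the cut-off that produced it."""

    kind: str  # "taxonomic" | "functional"
    member_ids: frozenset[str]
    cutoff: float
    prevalence: dict[str, float] = field(default_factory=dict)
    # functional kind only: member id -> qualifying core KO ids
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("taxonomic", "functional"):
            raise ValueError(f"kind must be taxonomic|functional, got {self.kind!r}")
        if not 0 < self.cutoff <= 1:
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")
        self.member_ids = frozenset(self.member_ids)
        if self.kind == "functional":
            empty = [m for m in self.member_ids if not self.provenance.get(m)]
            if empty:
                raise ValueError(
                    f"functional core members without provenance: {sorted(empty)}"
                )

    def __len__(self) -> int:
        return len(self.member_ids)

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self.member_ids


@dataclass
class CoreSummary:
    pct_of_all_asvs: float
    pct_of_total_relative_abundance: float
    n_shared_with_other_core: int
    pct_shared: float

    def __post_init__(self) -> None:
        for name in (
            "pct_of_all_asvs",
            "pct_of_total_relative_abundance",
            "pct_shared",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
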