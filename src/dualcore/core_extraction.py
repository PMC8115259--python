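"""Taxonomic and functional core extraction.

Two core definitions over the same ASV table:

* taxonomic core — ASVs whose presence prevalence (count > 0) reaches the
  cut-off;
* functional core — ASVs qualified through "core KOs" (KOs whose predicted
  abundance reaches the cut-off prevalence), with the ASV-level condition
  selectable via ``prevalence_mode`` (see :func:`functional_core`).

Presence is raw count > 0 by default; an optional minimum-abundance floor is
exposed on :func:`prevalence`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, CoreSet, CoreSummary, FunctionTable, GenomeContentTable

__all__ = [
    "prevalence",
    "taxonomic_core",
    "core_kos",
    "functional_core",
    "filter_to_core",
    "shared_core",
    "goods_coverage",
    "core_summary",
]

logger = logging.getLogger(__name__)


def _check_cutoff(cutoff: float) -> None:
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")


def prevalence(table: AbundanceTable, min_count: float = 0.0) -> pd.Series:
    """Fraction of samples in which each ASV is present (count > ``min_count``)."""
    if table.n_samples == 0:
        raise ValueError("prevalence undefined for a table with no samples")
    return (table.data > min_count).mean(axis=1)


def taxonomic_core(
    table: AbundanceTable, cutoff: float = 0.75, min_count: float = 0.0
) -> CoreSet:
    """ASVs present in at least ``cutoff`` fraction of samples."""
    _check_cutoff(cutoff)
    prev = prevalence(table, min_count=min_count)
    members = prev.index[prev >= cutoff]
    return CoreSet(
        kind="taxonomic",
        member_ids=frozenset(members),
        cutoff=cutoff,
        prevalence={a: float(prev[a]) for a in members},
    )


def core_kos(ko_table: FunctionTable, cutoff: float = 0.75) -> frozenset[str]:
    """KOs with predicted abundance > 0 in at least ``cutoff`` fraction of samples."""
    _check_cutoff(cutoff)
    if ko_table.level != "KO":
        raise ValueError(f"core_kos requires a KO-level table, got {ko_table.level!r}")
    if not ko_table.sample_ids:
        raise ValueError("core_kos undefined for a table with no samples")
    prev = (ko_table.data > 0).mean(axis=1)
    return frozenset(prev.index[prev >= cutoff])


def functional_core(
    table: AbundanceTable,
    genome_content: GenomeContentTable,
    core_ko_ids: frozenset[str] | set[str],
    cutoff: float = 0.75,
    prevalence_mode: str = "carrier",
) -> CoreSet:
    """ASVs qualified through core KOs.

    ``prevalence_mode`` controls the ASV-level prevalence condition:

    * ``"carrier"`` (default) — the ASV carries >= 1 core KO (copy number >= 1)
      and is observed in at least one sample. This is the redundancy-inclusive
      reading: taxa below the taxonomic cut-off still enter the functional
      core when they contribute a core function.
    * ``"all_samples"`` — carrier, and additionally present in >= ``cutoff``
      fraction of all samples (makes the functional core a subset of the
      taxonomic core).
    * ``"ko_samples"`` — carrier, and present in >= ``cutoff`` fraction of the
      samples in which at least one of its core KOs is detected (requires the
      carried-KO presence pattern; approximated by the ASV's own carried KOs'
      union prevalence support from the table itself).

    Provenance records, per member, the core KOs that qualified it; ASVs
    carrying several core KOs appear once with multi-KO provenance.
    """
    _check_cutoff(cutoff)
    if prevalence_mode not in ("carrier", "all_samples", "ko_samples"):
        raise ValueError(f"unknown prevalence_mode {prevalence_mode!r}")
    core_ko_ids = frozenset(core_ko_ids)
    unknown = core_ko_ids - set(genome_content.ko_ids)
    if unknown:
        raise ValueError(f"core KO id(s) not in genome content: {sorted(unknown)}")
    if not core_ko_ids:
        logger.warning("empty core KO set: functional core is empty")
        return CoreSet(kind="functional", member_ids=frozenset(), cutoff=cutoff)

    prev = prevalence(table)
    core_ko_list = sorted(core_ko_ids)
    kc = genome_content.ko_copies
    members: dict[str, frozenset[str]] = {}
    member_prev: dict[str, float] = {}
    for a in table.asv_ids:
        if a not in kc.index:
            continue
        carried = frozenset(k for k in core_ko_list if kc.at[a, k] >= 1)
        if not carried:
            continue
        if prev[a] <= 0:
            continue  # never observed; cannot contribute in any sample
        if prevalence_mode == "all_samples" and prev[a] < cutoff:
            continue
        if prevalence_mode == "ko_samples":
            # samples where any of the ASV's carried core KOs could be
            # contributed by the community (predicted-support samples)
            carriers = kc.index[(kc[list(carried)] >= 1).any(axis=1)]
            carriers = [c for c in carriers if c in table.data.index]
            ko_present = (table.data.loc[carriers] > 0).any(axis=0)
            n_support = int(ko_present.sum())
            if n_support == 0:
                continue
            asv_present = table.data.loc[a] > 0
            cond_prev = float((asv_present & ko_present).sum()) / n_support
            if cond_prev < cutoff:
                continue
        members[a] = carried
        member_prev[a] = float(prev[a])
    return CoreSet(
        kind="functional",
        member_ids=frozenset(members),
        cutoff=cutoff,
        prevalence=member_prev,
        provenance=members,
    )


def filter_to_core(table: AbundanceTable, core: CoreSet) -> AbundanceTable:
    """Restrict rows to core members; drop samples left all-zero (logged)."""
    missing = core.member_ids - set(table.asv_ids)
    if missing:
        raise ValueError(f"core member(s) absent from table: {sorted(missing)}")
    keep_rows = [a for a in table.asv_ids if a in core.member_ids]
    sub = table.data.loc[keep_rows]
    nonzero = sub.sum(axis=0) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info(
            "filter_to_core: dropped %d sample(s) with no core reads", n_dropped
        )
    sub = sub.loc[:, nonzero]
    return AbundanceTable(
        sub.copy(),
        metadata=table.subset_metadata(sub.columns),
        is_relative=False,
    )


def shared_core(tax: CoreSet, fun: CoreSet) -> tuple[frozenset[str], float]:
    """Intersection of two cores and 100 * |intersection| / |union|."""
    inter = tax.member_ids & fun.member_ids
    union = tax.member_ids | fun.member_ids
    pct = 100.0 * len(inter) / len(union) if union else 0.0
    return frozenset(inter), pct


def goods_coverage(sample_column: pd.Series | np.ndarray) -> float:
    """Good's coverage 1 - S/N.

    S = ASVs observed exactly once (singletons), N = ASVs with count > 0.
    """
    col = np.asarray(sample_column)
    n_observed = int((col > 0).sum())
    if n_observed == 0:
        raise ValueError("goods_coverage undefined for an all-zero sample")
    n_singletons = int((col == 1).sum())
    return 1.0 - n_singletons / n_observed


def core_summary(
    table: AbundanceTable, core: CoreSet, other_core: CoreSet
) -> CoreSummary:
    """Share of ASV richness / relative abundance held by a core, plus overlap."""
    n_asvs = table.n_asvs
    pct_asvs = 100.0 * len(core.member_ids) / n_asvs if n_asvs else 0.0
    rows = [a for a in table.asv_ids if a in core.member_ids]
    totals = table.data.sum(axis=0)
    ok = totals > 0
    if rows and ok.any():
        frac = (table.data.loc[rows, ok].sum(axis=0) / totals[ok]).mean()
    else:
        frac = 0.0
    shared, pct_shared = shared_core(core, other_core)
    return CoreSummary(
        pct_of_all_asvs=float(pct_asvs),
        pct_of_total_relative_abundance=float(100.0 * frac),
        n_shared_with_other_core=len(shared),
        pct_shared=float(pct_shared),
    )
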