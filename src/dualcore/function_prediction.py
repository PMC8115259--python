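"""Predicted KO and pathway abundances from ASV counts and genome content.

KO abundance in a sample is the sum over ASVs of (count, optionally divided
by the ASV's 16S copy number) times the ASV's KO copy number. Pathway
abundance is the plain sum of member-KO abundances; a KO mapping to several
pathways contributes fully to each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, FunctionTable, GenomeContentTable

__all__ = ["predict_metagenome", "ko_to_pathway"]


def predict_metagenome(
    table: AbundanceTable,
    gc: GenomeContentTable,
    normalize_16s: bool = True,
) -> FunctionTable:
    """KO-level metagenome prediction: (copy numbers)^T @ (16S-normalized counts)."""
    missing = set(table.asv_ids) - set(gc.asv_ids)
    if missing:
        raise ValueError(
            f"ASV(s) missing from genome content table: {sorted(missing)}"
        )
    counts = table.data.to_numpy(dtype=float)
    if normalize_16s:
        ssu = gc.ssu_copies.loc[table.asv_ids].to_numpy(dtype=float)
        counts = counts / ssu[:, None]
    copies = gc.ko_copies.loc[table.asv_ids].to_numpy(dtype=float)
    ko = copies.T @ counts
    return FunctionTable(
        level="KO",
        data=pd.DataFrame(ko, index=gc.ko_ids, columns=table.sample_ids),
    )


def ko_to_pathway(
    ko_table: FunctionTable, ko_pathway_map: dict[str, frozenset[str]]
) -> FunctionTable:
    """Aggregate a KO table to pathways by summation over member KOs."""
    if ko_table.level != "KO":
        raise ValueError(f"ko_to_pathway requires a KO-level table, got {ko_table.level!r}")
    pathways = sorted({p for pwys in ko_pathway_map.values() for p in pwys})
    data = np.zeros((len(pathways), len(ko_table.sample_ids)))
    index = {p: i for i, p in enumerate(pathways)}
    for ko in ko_table.feature_ids:
        for p in ko_pathway_map.get(ko, ()):  # unmapped KOs contribute nowhere
            data[index[p]] += ko_table.data.loc[ko].to_numpy()
    return FunctionTable(
        level="pathway",
        data=pd.DataFrame(data, index=pathways, columns=ko_table.sample_ids),
    )
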