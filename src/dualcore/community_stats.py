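"""Beta-diversity ordination and group-comparison statistics.

Distances: Bray-Curtis (direct formula) and unweighted UniFrac (scikit-bio).
Ordination: classical PCoA (double-centering + eigendecomposition, negative
eigenvalues dropped). Tests: rank-based ANOSIM and PERMANOVA with seeded
label permutations, Welch's t per feature with Benjamini-Hochberg FDR.

Normalization is total-sum scaling (proportions), never rarefaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable, FunctionTable, TaxonomyTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "AnosimResult",
    "PermanovaResult",
    "DifferentialAbundanceResult",
    "relative_abundance",
    "bray_curtis",
    "unweighted_unifrac",
    "pcoa",
    "anosim",
    "permanova",
    "aggregate_rank",
    "welch_bh",
    "bh_adjust",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} != ({n}, {n})")
        if np.any(np.abs(np.diag(self.data)) > 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.max(np.abs(self.data - self.data.T), initial=0.0) > _SYM_TOL:
            raise ValueError("distance matrix must be symmetric to 1e-12")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive, non-increasing
    proportion_explained: np.ndarray


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int


@dataclass
class PermanovaResult:
    R2: float
    F: float
    p: float
    n_permutations: int
    seed: int


@dataclass
class DifferentialAbundanceResult:
    feature_id: str
    mean_pct_a: float
    mean_pct_b: float
    welch_t: float
    df: float
    p_raw: float
    q_bh: float
    significant: bool


# ---------------------------------------------------------------------------
# normalization and distances


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: each sample column sums to 1."""
    if table.is_relative:
        return table
    sums = table.data.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    return AbundanceTable(
        table.data / sums, metadata=table.metadata, is_relative=True
    )


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """d(j, k) = sum |x_j - x_k| / sum (x_j + x_k) over features."""
    if table.n_samples < 2:
        raise ValueError("bray_curtis requires at least 2 samples")
    x = table.data.to_numpy(dtype=float)
    sums = x.sum(axis=0)
    if (sums == 0).sum() >= 1:
        raise ValueError("bray_curtis undefined with an all-zero sample")
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    tot = sums[:, None] + sums[None, :]
    d = diff / tot
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry
    return DistanceMatrix(ids=table.sample_ids, data=d, metric="braycurtis")


def unweighted_unifrac(table: AbundanceTable, tree) -> DistanceMatrix:
    """Unweighted UniFrac over presence sets, via scikit-bio."""
    from skbio.diversity import beta_diversity

    tips = {t.name for t in tree.tips()}
    missing = set(table.asv_ids) - tips
    if missing:
        raise ValueError(f"ASV(s) missing from tree: {sorted(missing)}")
    counts = (table.data.to_numpy().T > 0).astype(int)
    dm = beta_diversity(
        "unweighted_unifrac",
        counts,
        ids=table.sample_ids,
        taxa=table.asv_ids,
        tree=tree,
    )
    data = np.array(dm.data, dtype=float)
    data = (data + data.T) / 2
    return DistanceMatrix(ids=table.sample_ids, data=data, metric="unweighted_unifrac")


# ---------------------------------------------------------------------------
# ordination


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Classical metric MDS; negative eigenvalues are dropped (logged)."""
    n = dm.n
    if n < 3:
        raise ValueError("pcoa requires at least 3 samples")
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int((eigvals < -eig_tol * max(abs(eigvals[0]), 1.0)).sum())
    if n_neg:
        logger.info("pcoa: dropped %d negative eigenvalue(s)", n_neg)
    keep = eigvals > eig_tol * max(abs(eigvals[0]), 1.0)
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = eigvals / eigvals.sum() if eigvals.size else eigvals
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# permutation tests


def _check_groups(ids, groups) -> np.ndarray:
    labels = np.asarray([groups[i] for i in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2].tolist()
    if small:
        raise ValueError(f"group(s) of size 1: {small}")
    return labels


def anosim(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> AnosimResult:
    """Clarke's ANOSIM R with a seeded permutation p-value.

    ``groups`` maps sample id -> label. R = (mean between-group rank - mean
    within-group rank) / (M/2) with M = n(n-1)/2, midranks for ties;
    p = (1 + #{perm R >= observed R}) / (n_permutations + 1).
    """
    labels = _check_groups(dm.ids, groups)
    n = dm.n
    iu = np.triu_indices(n, k=1)
    ranks = scipy.stats.rankdata(dm.data[iu])
    m = n * (n - 1) // 2
    denom = m / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= observed:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return AnosimResult(R=float(observed), p=float(p), n_permutations=n_permutations, seed=seed)


def permanova(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson) with a seeded permutation p-value."""
    labels = _check_groups(dm.ids, groups)
    n = dm.n
    d2 = dm.data**2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    uniq = np.unique(labels)
    a = len(uniq)

    def ss_within(lab: np.ndarray) -> float:
        ss = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ss += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        return ss

    def f_stat(lab: np.ndarray) -> float:
        ssw = ss_within(lab)
        ssa = ss_total - ssw
        if ssw <= 0:
            return np.inf if ssa > 0 else 0.0
        return (ssa / (a - 1)) / (ssw / (n - a))

    ssw_obs = ss_within(labels)
    ssa_obs = ss_total - ssw_obs
    r2 = ssa_obs / ss_total if ss_total > 0 else 0.0
    f_obs = f_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(labels)) >= f_obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PermanovaResult(
        R2=float(r2), F=float(f_obs), p=float(p),
        n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# differential abundance


def aggregate_rank(
    table: AbundanceTable, taxonomy: TaxonomyTable, rank: str
) -> FunctionTable:
    """Sum ASV abundances by taxonomy label at ``rank`` (unassigned kept)."""
    if rank not in taxonomy.data.columns:
        raise ValueError(f"unknown rank {rank!r}")
    missing = set(table.asv_ids) - set(taxonomy.data.index)
    if missing:
        raise ValueError(f"ASV(s) without taxonomy: {sorted(missing)}")
    labels = taxonomy.data.loc[table.asv_ids, rank]
    agg = table.data.groupby(labels.values).sum().sort_index()
    return FunctionTable(level="aggregated", data=agg)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return qvals


def welch_bh(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    alpha: float = 0.05,
) -> list[DifferentialAbundanceResult]:
    """Per-feature Welch's t between two feature-by-sample proportion tables,
    with Benjamini-Hochberg FDR over all tested features.

    Features present in only one table, or with fewer than 2 observations in
    a group, are skipped (logged). Identical constant groups give t = 0,
    p = 1; constant groups with different means give p -> 0.
    """
    shared = features_a.index.intersection(features_b.index)
    skipped = set(features_a.index).symmetric_difference(features_b.index)
    results: list[tuple[str, float, float, float, float, float]] = []
    for f in shared:
        xa = features_a.loc[f].to_numpy(dtype=float)
        xb = features_b.loc[f].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            skipped.add(f)
            continue
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        if va == 0 and vb == 0:
            if xa.mean() == xb.mean():
                t, df, p = 0.0, float(len(xa) + len(xb) - 2), 1.0
            else:
                t, df, p = np.inf, float(len(xa) + len(xb) - 2), 0.0
        else:
            res = scipy.stats.ttest_ind(xa, xb, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        results.append((f, xa.mean() * 100, xb.mean() * 100, t, df, p))
    if skipped:
        logger.info("welch_bh: skipped %d feature(s)", len(skipped))
    if not results:
        return []
    pvals = np.array([r[5] for r in results])
    qvals = bh_adjust(pvals)
    reject = qvals < alpha
    return [
        DifferentialAbundanceResult(
            feature_id=f,
            mean_pct_a=ma,
            mean_pct_b=mb,
            welch_t=t,
            df=df,
            p_raw=p,
            q_bh=float(q),
            significant=bool(rej),
        )
        for (f, ma, mb, t, df, p), q, rej in zip(results, qvals, reject)
    ]
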