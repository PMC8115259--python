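"""Synthetic rhizobiome scenarios with planted ground truth.

The generator emits everything a study analysis consumes — counts, taxonomy,
genome content, KO->pathway map, tree, metadata — together with the planted
truth (taxonomic core, core KOs, functional core, habitat labels), so every
downstream stage can be tested against known structure.

Count model: Dirichlet-multinomial over per-sample presence-masked base
proportions. Planted core ASVs get a boosted base abundance so that presence
(count > 0) tracks the Bernoulli presence mask at realistic depth. Habitat
effects multiply base proportions on the log scale before renormalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import (
    TAXONOMY_RANKS,
    UNASSIGNED,
    AbundanceTable,
    GenomeContentTable,
    TaxonomyTable,
)

__all__ = ["SyntheticScenario", "GroundTruth", "generate_scenario", "generate_tree"]

# factor by which planted core base proportions exceed the background median;
# keeps presence-after-sequencing close to the Bernoulli presence mask
_CORE_BOOST = 25.0
# redundant (functional-core-only) ASVs carry real abundance weight so the
# two filtered core rhizobiomes are compositionally distinguishable
_REDUNDANT_BOOST = 8.0
_HABITAT_ASV_FRACTION = 0.2


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration for one synthetic multi-sample scenario."""

    n_samples: int = 60
    n_asvs: int = 40
    n_kos: int = 30
    n_pathways: int = 8
    n_habitats: int = 2
    planted_tax_core_size: int = 8
    planted_redundant_asvs: int = 4
    core_prevalence: float = 0.9
    background_prevalence: float = 0.3
    sequencing_depth_mean: int = 20000
    overdispersion: float = 200.0  # Dirichlet concentration; inf = no overdispersion
    habitat_effect: float = 1.0  # log-scale shift applied to a random ASV subset
    hub_strength: float = 0.0  # shared log-normal factor over the core union
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            "n_samples",
            "n_asvs",
            "n_kos",
            "n_pathways",
            "n_habitats",
            "sequencing_depth_mean",
        )
        for name in counts:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("planted_tax_core_size", "planted_redundant_asvs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.planted_tax_core_size + self.planted_redundant_asvs > self.n_asvs:
            raise ValueError(
                "planted_tax_core_size + planted_redundant_asvs exceeds n_asvs"
            )
        if not 0 <= self.background_prevalence < self.core_prevalence <= 1:
            raise ValueError(
                "require 0 <= background_prevalence < core_prevalence <= 1 "
                f"(background_prevalence={self.background_prevalence}, "
                f"core_prevalence={self.core_prevalence})"
            )
        if not self.overdispersion > 0:
            raise ValueError(f"overdispersion must be positive, got {self.overdispersion}")
        if self.habitat_effect < 0:
            raise ValueError(f"habitat_effect must be non-negative, got {self.habitat_effect}")
        if self.hub_strength < 0:
            raise ValueError(f"hub_strength must be non-negative, got {self.hub_strength}")
        if self.n_samples < self.n_habitats:
            raise ValueError("n_samples must be >= n_habitats")


@dataclass
class GroundTruth:
    """Planted structure of a scenario."""

    tax_core_ids: frozenset[str]
    core_ko_ids: frozenset[str]
    functional_core_ids: frozenset[str]
    redundant_ids: frozenset[str]
    habitat_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.core_ko_ids and not self.functional_core_ids:
            raise ValueError("functional core empty despite planted core KOs")


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_scenario(config: SyntheticScenario):
    """Generate one scenario.

    Returns
    -------
    (AbundanceTable, TaxonomyTable, GenomeContentTable, ko_pathway_map,
    TreeNode, GroundTruth)
    """
    rng = np.random.default_rng(config.seed)
    asv_ids = _ids("ASV_", config.n_asvs, 4)
    sample_ids = _ids("S", config.n_samples, 4)
    ko_ids = _ids("K", config.n_kos, 5)
    pathway_ids = _ids("PWY_", config.n_pathways, 3)

    n_core = config.planted_tax_core_size
    n_red = config.planted_redundant_asvs
    tax_core = asv_ids[:n_core]
    redundant = asv_ids[n_core : n_core + n_red]
    background = asv_ids[n_core + n_red :]

    # --- base proportions ---------------------------------------------------
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_asvs)
    if background:
        scale = np.median(base[n_core + n_red :])
    else:
        scale = np.median(base) if base.size else 1.0
    base[:n_core] = _CORE_BOOST * scale * rng.uniform(0.5, 1.5, size=n_core)
    base[n_core : n_core + n_red] = _REDUNDANT_BOOST * scale * rng.uniform(
        0.5, 1.5, size=n_red
    )

    # --- habitat structure --------------------------------------------------
    habitats = [f"H{h + 1}" for h in range(config.n_habitats)]
    habitat_of = {s: habitats[i % config.n_habitats] for i, s in enumerate(sample_ids)}
    habitat_factor = np.ones((config.n_habitats, config.n_asvs))
    n_shift = max(1, int(round(_HABITAT_ASV_FRACTION * config.n_asvs)))
    for h in range(1, config.n_habitats):
        shifted = rng.choice(config.n_asvs, size=n_shift, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_shift)
        habitat_factor[h, shifted] = np.exp(config.habitat_effect * signs)

    # --- presence masks and counts ------------------------------------------
    presence_prob = np.full(config.n_asvs, config.background_prevalence)
    presence_prob[:n_core] = config.core_prevalence
    counts = np.zeros((config.n_asvs, config.n_samples), dtype=np.int64)
    finite_od = math.isfinite(config.overdispersion)
    n_union = n_core + n_red
    # per-ASV couplings to a shared per-sample latent factor; heterogeneous
    # slopes survive the compositional renormalization, so core-union members
    # co-vary in relative abundance
    couplings = rng.uniform(-1.5, 1.5, size=n_union)
    for j, s in enumerate(sample_ids):
        mask = rng.random(config.n_asvs) < presence_prob
        h = habitats.index(habitat_of[s])
        w = base * habitat_factor[h] * mask
        if config.hub_strength > 0:
            w = w.copy()
            w[:n_union] *= np.exp(config.hub_strength * couplings * rng.normal())
        total = w.sum()
        if total == 0:
            continue
        p = w / total
        if finite_od:
            pos = p > 0
            alpha = config.overdispersion * p[pos]
            p_pos = rng.dirichlet(alpha)
            p = np.zeros_like(p)
            p[pos] = p_pos
        counts[:, j] = rng.multinomial(config.sequencing_depth_mean, p)

    metadata = pd.DataFrame(
        {
            "study": "synthetic",
            "habitat": [habitat_of[s] for s in sample_ids],
            "group": [habitat_of[s] for s in sample_ids],
        },
        index=pd.Index(sample_ids),
    )
    table = AbundanceTable(
        pd.DataFrame(counts, index=asv_ids, columns=sample_ids), metadata=metadata
    )

    # --- genome content -----------------------------------------------------
    carriers = tax_core + redundant
    # no carrier ASVs -> nothing can make a KO community-core by construction
    n_core_kos = max(2, min(config.n_kos // 3, 10)) if carriers else 0
    core_kos = ko_ids[:n_core_kos]
    other_kos = ko_ids[n_core_kos:]
    ko_copies = pd.DataFrame(
        0, index=asv_ids, columns=ko_ids, dtype=int
    )
    # every core KO is carried by >= 1 planted core ASV; every planted core /
    # redundant ASV carries >= 1 core KO (redundancy groups share KOs)
    for i, ko in enumerate(core_kos):
        if carriers:
            ko_copies.loc[carriers[i % len(carriers)], ko] = int(rng.integers(1, 4))
    for a in carriers:
        picks = rng.choice(n_core_kos, size=int(rng.integers(1, 3)), replace=False)
        for k in picks:
            ko_copies.loc[a, core_kos[k]] = int(rng.integers(1, 4))
    # non-core KOs only on background/redundant ASVs, <= 2 carriers each, so
    # their community prevalence stays safely below any sensible cut-off
    low_prev_pool = background + redundant
    for ko in other_kos:
        if not low_prev_pool:
            break
        n_carry = int(rng.integers(1, 3))
        picks = rng.choice(len(low_prev_pool), size=min(n_carry, len(low_prev_pool)), replace=False)
        for k in picks:
            ko_copies.loc[low_prev_pool[k], ko] = int(rng.integers(1, 4))
    ssu = pd.Series(rng.integers(1, 8, size=config.n_asvs), index=asv_ids)
    gc = GenomeContentTable(ko_copies=ko_copies, ssu_copies=ssu)

    # --- KO -> pathway map ---------------------------------------------------
    ko_pathway_map: dict[str, frozenset[str]] = {}
    for ko in ko_ids:
        n_p = int(rng.integers(0, 3))
        if n_p:
            picks = rng.choice(config.n_pathways, size=n_p, replace=False)
            ko_pathway_map[ko] = frozenset(pathway_ids[k] for k in picks)
        else:
            ko_pathway_map[ko] = frozenset()

    taxonomy = _generate_taxonomy(asv_ids, rng)
    tree = generate_tree(asv_ids, seed=int(rng.integers(0, 2**31)))

    # planted functional core: carriers of >= 1 core KO that can actually be
    # observed (expected presence > 0)
    functional = {
        a
        for a in carriers
        if presence_prob[asv_ids.index(a)] > 0
        and (ko_copies.loc[a, core_kos] >= 1).any()
    }
    truth = GroundTruth(
        tax_core_ids=frozenset(tax_core),
        core_ko_ids=frozenset(core_kos),
        functional_core_ids=frozenset(functional),
        redundant_ids=frozenset(redundant),
        habitat_labels=dict(habitat_of),
    )
    return table, taxonomy, gc, ko_pathway_map, tree, truth


def _generate_taxonomy(asv_ids: list[str], rng: np.random.Generator) -> TaxonomyTable:
    n = len(asv_ids)
    phyla = [f"Phylum_{i}" for i in range(1, 7)]
    rows = []
    for a in asv_ids:
        p = phyla[int(rng.integers(0, len(phyla)))]
        c = f"{p}_c{int(rng.integers(1, 3))}"
        o = f"{c}_o{int(rng.integers(1, 3))}"
        f = f"{o}_f{int(rng.integers(1, 3))}"
        g = f"{f}_g{int(rng.integers(1, 4))}"
        if rng.random() < 0.1:  # some unresolved assignments, like real data
            g = UNASSIGNED
        rows.append(("Bacteria", p, c, o, f, g))
    df = pd.DataFrame(rows, index=asv_ids, columns=list(TAXONOMY_RANKS))
    return TaxonomyTable(df)


def generate_tree(asv_ids: list[str], seed: int) -> TreeNode:
    """Random rooted bifurcating tree over ``asv_ids``.

    Branch lengths are exponential(1) draws; deterministic under ``seed``.
    """
    ids = list(asv_ids)
    if len(ids) < 2:
        raise ValueError("generate_tree requires at least 2 ids")
    if len(set(ids)) != len(ids):
        raise ValueError("tip ids must be unique")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))

    def build(tips: list[str]) -> TreeNode:
        if len(tips) == 1:
            node = TreeNode(name=tips[0])
        else:
            split = int(rng.integers(1, len(tips)))
            node = TreeNode(children=[build(tips[:split]), build(tips[split:])])
        node.length = float(rng.exponential(1.0))
        return node

    root = build(order)
    root.length = None  # root has no branch
    return root
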