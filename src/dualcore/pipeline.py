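"""Whole-study orchestration: dual core extraction, comparison statistics,
habitat-corrected MIC network, and the cut-off sensitivity sweep.

Every stage writes its artifacts to the output directory as TSV/JSON/newick/
GraphML so each intermediate can be re-read by the stage CLIs. All
randomness flows from one master seed through per-stage derived seeds, and
no output embeds timestamps, so identical configs give byte-identical
artifacts (the log file records timing and is excluded from that contract).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_stats as cs
from . import core_extraction as ce
from . import function_prediction as fp
from . import io_formats as io
from . import network_mic as nm
from .datatypes import AbundanceTable, CoreSet, FunctionTable

__all__ = ["RunConfig", "ReportBundle", "StageError", "run_study", "cutoff_sensitivity"]

logger = logging.getLogger(__name__)

DEFAULT_SWEEP = (0.70, 0.75, 0.80, 0.85, 0.90)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    table: str
    genome_content: str
    ko_pathway_map: str
    tree: str
    metadata: str
    out_dir: str
    taxonomy: str | None = None
    cutoff: float = 0.75
    cutoff_sweep: tuple[float, ...] = DEFAULT_SWEEP
    permutations: int = 999
    mic_permutations: int = 200
    fdr_alpha: float = 0.05
    seed: int = 0
    functional_mode: str = "carrier"

    def __post_init__(self) -> None:
        for c in (self.cutoff, *self.cutoff_sweep):
            if not 0 < c <= 1:
                raise ValueError(f"cutoff {c} outside (0, 1]")
        if self.seed is None:
            raise ValueError("seed must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping")
        if "cutoff_sweep" in raw:
            raw["cutoff_sweep"] = tuple(raw["cutoff_sweep"])
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ValueError(f"{path}: {exc}") from exc
        for name in ("table", "genome_content", "ko_pathway_map", "tree", "metadata"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")
        return cfg

    def config_hash(self) -> str:
        # out_dir is where results land, not part of the analysis identity
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    out_dir: Path
    tax_core: CoreSet
    fun_core: CoreSet
    core_kos: frozenset[str]
    anosim: dict = field(default_factory=dict)
    permanova: dict = field(default_factory=dict)
    network: nm.Network | None = None
    hub_report: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def _derived_seed(master: int, stage: int) -> int:
    return int(
        np.random.SeedSequence(entropy=master, spawn_key=(stage,)).generate_state(1)[0]
    )


def _write_coreset(core: CoreSet, path) -> None:
    rows = []
    for m in sorted(core.member_ids):
        rows.append(
            {
                "asv_id": m,
                "prevalence": core.prevalence.get(m, float("nan")),
                "provenance": ";".join(sorted(core.provenance.get(m, ()))),
            }
        )
    pd.DataFrame(rows, columns=["asv_id", "prevalence", "provenance"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def _combine_cores(
    tax_tbl: AbundanceTable, fun_tbl: AbundanceTable
) -> tuple[AbundanceTable, dict[str, str]]:
    """Stack the two core rhizobiomes side by side (samples prefixed by kind)."""
    asvs = sorted(set(tax_tbl.asv_ids) | set(fun_tbl.asv_ids))
    parts = []
    groups: dict[str, str] = {}
    for kind, tbl in (("taxonomic", tax_tbl), ("functional", fun_tbl)):
        sub = tbl.data.reindex(index=asvs, fill_value=0)
        sub.columns = [f"{kind}|{s}" for s in tbl.sample_ids]
        for s in sub.columns:
            groups[s] = kind
        parts.append(sub)
    combined = pd.concat(parts, axis=1)
    return AbundanceTable(combined), groups


def _proportions(ft: FunctionTable) -> pd.DataFrame:
    sums = ft.data.sum(axis=0)
    ok = sums > 0
    return ft.data.loc[:, ok] / sums[ok]


def run_study(config: RunConfig) -> ReportBundle:
    """Execute the full per-study analysis. See module docstring for layout."""
    out = io.ensure_dir(config.out_dir)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("dualcore")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    warnings_: list[str] = []
    stage_times: dict[str, float] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                stage_times[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s: FAILED: %s", name, exc)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done (%.2fs)", name, stage_times[name])
                return False

        return _Ctx()

    try:
        with stage("load"):
            metadata = io.read_metadata(config.metadata)
            table = io.read_abundance(config.table, metadata=metadata)
            gc = io.read_genome_content(config.genome_content)
            ko_map = io.read_ko_pathway_map(config.ko_pathway_map)
            tree = io.read_tree(config.tree)
            taxonomy = (
                io.read_taxonomy(config.taxonomy) if config.taxonomy else None
            )

        with stage("predict_metagenome"):
            ko_table = fp.predict_metagenome(table, gc)
            io.write_function_table(ko_table, out / "ko_metagenome.tsv")
            pwy_table = fp.ko_to_pathway(ko_table, ko_map)
            io.write_function_table(pwy_table, out / "pathway_abundance.tsv")

        with stage("taxonomic_core"):
            tax_core = ce.taxonomic_core(table, cutoff=config.cutoff)
            _write_coreset(tax_core, out / "taxonomic_core.tsv")
            tax_tbl = ce.filter_to_core(table, tax_core)
            io.write_abundance(tax_tbl, out / "taxonomic_core_rhizobiome.tsv")

        with stage("functional_core"):
            kos = ce.core_kos(ko_table, cutoff=config.cutoff)
            (out / "core_kos.tsv").write_text(
                "#KO ID\n" + "".join(f"{k}\n" for k in sorted(kos))
            )
            fun_core = ce.functional_core(
                table, gc, kos, cutoff=config.cutoff,
                prevalence_mode=config.functional_mode,
            )
            _write_coreset(fun_core, out / "functional_core.tsv")
            fun_tbl = ce.filter_to_core(table, fun_core)
            io.write_abundance(fun_tbl, out / "functional_core_rhizobiome.tsv")

        with stage("core_summary"):
            summary = {
                "taxonomic": ce.core_summary(table, tax_core, fun_core).__dict__,
                "functional": ce.core_summary(table, fun_core, tax_core).__dict__,
                "n_core_kos": len(kos),
            }
            (out / "core_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n"
            )

        with stage("core_function_tables"):
            for kind, tbl in (("taxonomic", tax_tbl), ("functional", fun_tbl)):
                if tbl.n_asvs == 0 or tbl.n_samples == 0:
                    warnings_.append(f"{kind} core rhizobiome is empty")
                    continue
                kt = fp.predict_metagenome(tbl, gc)
                io.write_function_table(kt, out / f"{kind}_core_ko_metagenome.tsv")
                pt = fp.ko_to_pathway(kt, ko_map)
                io.write_function_table(pt, out / f"{kind}_core_pathway_abundance.tsv")

        bundle = ReportBundle(
            out_dir=out, tax_core=tax_core, fun_core=fun_core, core_kos=kos,
            warnings=warnings_,
        )

        cores_ok = (
            len(tax_core) > 0
            and len(fun_core) > 0
            and tax_tbl.n_samples >= 4
            and fun_tbl.n_samples >= 4
        )
        if not cores_ok:
            warnings_.append(
                "empty or near-empty core(s): comparison statistics and "
                "network stages skipped"
            )

        if cores_ok:
            with stage("beta_diversity"):
                combined, groups = _combine_cores(tax_tbl, fun_tbl)
                rel = cs.relative_abundance(combined)
                dms = {"braycurtis": cs.bray_curtis(rel)}
                try:
                    dms["unweighted_unifrac"] = cs.unweighted_unifrac(rel, tree)
                except ValueError as exc:
                    warnings_.append(f"unifrac skipped: {exc}")
                for name, dm in dms.items():
                    dm.to_frame().to_csv(
                        out / f"distance_{name}.tsv", sep="\t",
                        float_format="%.12g",
                    )
                    ordination = cs.pcoa(dm)
                    ordination.coordinates.to_csv(
                        out / f"pcoa_{name}.tsv", sep="\t", float_format="%.12g"
                    )
                    res_a = cs.anosim(
                        dm, groups, n_permutations=config.permutations,
                        seed=_derived_seed(config.seed, 1),
                    )
                    res_p = cs.permanova(
                        dm, groups, n_permutations=config.permutations,
                        seed=_derived_seed(config.seed, 2),
                    )
                    bundle.anosim[f"asv_{name}"] = res_a.__dict__
                    bundle.permanova[f"asv_{name}"] = res_p.__dict__
                # function-level comparisons (bray-curtis on predicted tables)
                for level in ("ko", "pathway"):
                    pa = out / f"taxonomic_core_{'ko_metagenome' if level == 'ko' else 'pathway_abundance'}.tsv"
                    pb = out / f"functional_core_{'ko_metagenome' if level == 'ko' else 'pathway_abundance'}.tsv"
                    if not (pa.exists() and pb.exists()):
                        continue
                    fta = io.read_function_table(pa, "KO" if level == "ko" else "pathway")
                    ftb = io.read_function_table(pb, "KO" if level == "ko" else "pathway")
                    if fta.data.shape[0] == 0 or ftb.data.shape[0] == 0:
                        continue
                    comb, grp = _combine_cores(
                        AbundanceTable(fta.data), AbundanceTable(ftb.data)
                    )
                    if comb.data.sum(axis=0).min() <= 0:
                        continue
                    dm = cs.bray_curtis(cs.relative_abundance(comb))
                    res_a = cs.anosim(
                        dm, grp, n_permutations=config.permutations,
                        seed=_derived_seed(config.seed, 3),
                    )
                    res_p = cs.permanova(
                        dm, grp, n_permutations=config.permutations,
                        seed=_derived_seed(config.seed, 4),
                    )
                    bundle.anosim[f"{level}_braycurtis"] = res_a.__dict__
                    bundle.permanova[f"{level}_braycurtis"] = res_p.__dict__
                (out / "beta_diversity_tests.json").write_text(
                    json.dumps(
                        {"anosim": bundle.anosim, "permanova": bundle.permanova},
                        indent=2, sort_keys=True,
                    )
                    + "\n"
                )

            with stage("differential_abundance"):
                rel_tax = cs.relative_abundance(tax_tbl)
                rel_fun = cs.relative_abundance(fun_tbl)
                levels: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
                if taxonomy is not None:
                    for rank in ("phylum", "genus"):
                        levels[rank] = (
                            cs.aggregate_rank(rel_tax, taxonomy, rank).data,
                            cs.aggregate_rank(rel_fun, taxonomy, rank).data,
                        )
                for level, suffix in (("ko", "ko_metagenome"), ("pathway", "pathway_abundance")):
                    pa = out / f"taxonomic_core_{suffix}.tsv"
                    pb = out / f"functional_core_{suffix}.tsv"
                    if pa.exists() and pb.exists():
                        fta = io.read_function_table(pa, "KO" if level == "ko" else "pathway")
                        ftb = io.read_function_table(pb, "KO" if level == "ko" else "pathway")
                        if fta.data.shape[0] and ftb.data.shape[0]:
                            levels[level] = (_proportions(fta), _proportions(ftb))
                for level, (fa, fb) in levels.items():
                    results = cs.welch_bh(fa, fb, alpha=config.fdr_alpha)
                    pd.DataFrame([r.__dict__ for r in results]).to_csv(
                        out / f"diff_abundance_{level}.tsv", sep="\t",
                        index=False, float_format="%.12g",
                    )

            with stage("network"):
                union_ids = sorted(tax_core.member_ids | fun_core.member_ids)
                union_tbl = AbundanceTable(
                    table.data.loc[union_ids], metadata=table.metadata
                )
                habitat_labels = metadata["habitat"].to_dict()
                corrected = nm.habitat_correct(
                    cs.relative_abundance(
                        AbundanceTable(
                            union_tbl.data.loc[:, union_tbl.data.sum(axis=0) > 0],
                            metadata=table.metadata,
                        )
                    ),
                    habitat_labels,
                )
                labels = {}
                for a in union_ids:
                    in_tax = a in tax_core.member_ids
                    in_fun = a in fun_core.member_ids
                    labels[a] = (
                        "both" if in_tax and in_fun
                        else "taxonomic" if in_tax else "functional"
                    )
                params = nm.MicParams(
                    n_permutations=config.mic_permutations,
                    fdr_alpha=config.fdr_alpha,
                    seed=_derived_seed(config.seed, 5),
                )
                edges = nm.edge_scan(corrected, labels, params)
                edges, nonlinear_frac = nm.classify_nonlinear(edges)
                network = nm.build_network(edges, labels)
                bundle.network = network
                if network.n_nodes:
                    bundle.hub_report = nm.hub_taxa(network)
                    bundle.hub_report.to_csv(
                        out / "hub_report.tsv", sep="\t", float_format="%.12g"
                    )
                else:
                    warnings_.append("no significant edges: empty network")
                io.write_network(network, out / "network.graphml", format="graphml")
                io.write_network(network, out / "network_edges.tsv", format="edge_tsv")
                (out / "network_summary.json").write_text(
                    json.dumps(
                        {
                            "n_nodes": network.n_nodes,
                            "n_edges": network.n_edges,
                            "nonlinear_fraction": nonlinear_frac,
                            "n_hubs": int(bundle.hub_report["is_hub"].sum())
                            if bundle.hub_report is not None else 0,
                        },
                        indent=2, sort_keys=True,
                    )
                    + "\n"
                )

        with stage("manifest"):
            from . import __version__

            manifest = {
                "dualcore_version": __version__,
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "cutoff": config.cutoff,
                "n_samples": table.n_samples,
                "n_asvs": table.n_asvs,
                "tax_core_size": len(tax_core),
                "fun_core_size": len(fun_core),
                "n_core_kos": len(kos),
                "warnings": warnings_,
            }
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n"
            )
        for w in warnings_:
            logger.warning("%s", w)
        return bundle
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def cutoff_sensitivity(config: RunConfig) -> pd.DataFrame:
    """Core sizes and between-core test statistics per cut-off in the sweep."""
    metadata = io.read_metadata(config.metadata)
    table = io.read_abundance(config.table, metadata=metadata)
    gc = io.read_genome_content(config.genome_content)
    ko_table = fp.predict_metagenome(table, gc)
    rows = []
    for cutoff in sorted(config.cutoff_sweep):
        tax_core = ce.taxonomic_core(table, cutoff=cutoff)
        kos = ce.core_kos(ko_table, cutoff=cutoff)
        fun_core = ce.functional_core(
            table, gc, kos, cutoff=cutoff, prevalence_mode=config.functional_mode
        )
        anosim_r = float("nan")
        permanova_r2 = float("nan")
        if len(tax_core) and len(fun_core):
            tax_tbl = ce.filter_to_core(table, tax_core)
            fun_tbl = ce.filter_to_core(table, fun_core)
            if tax_tbl.n_samples >= 4 and fun_tbl.n_samples >= 4:
                combined, groups = _combine_cores(tax_tbl, fun_tbl)
                dm = cs.bray_curtis(cs.relative_abundance(combined))
                anosim_r = cs.anosim(
                    dm, groups, n_permutations=config.permutations,
                    seed=_derived_seed(config.seed, 11),
                ).R
                permanova_r2 = cs.permanova(
                    dm, groups, n_permutations=config.permutations,
                    seed=_derived_seed(config.seed, 12),
                ).R2
        rows.append(
            {
                "cutoff": cutoff,
                "tax_core_size": len(tax_core),
                "n_core_kos": len(kos),
                "fun_core_size": len(fun_core),
                "anosim_R": anosim_r,
                "permanova_R2": permanova_r2,
            }
        )
    df = pd.DataFrame(rows)
    monotone_cols = ["tax_core_size", "n_core_kos"]
    if config.functional_mode != "ko_samples":
        # conditional-prevalence mode has a shrinking denominator, so its
        # core size is not guaranteed monotone
        monotone_cols.append("fun_core_size")
    for col in monotone_cols:
        sizes = df[col].to_numpy()
        if np.any(np.diff(sizes) > 0):
            raise AssertionError(
                f"{col} not monotone non-increasing across increasing cutoffs"
            )
    out = io.ensure_dir(config.out_dir)
    df.to_csv(out / "cutoff_sensitivity.tsv", sep="\t", index=False,
              float_format="%.12g")
    return df
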