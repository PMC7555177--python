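"""Config-driven orchestration of the full analysis chain.

One :func:`run_pipeline` call takes a cohort of expression datasets grouped
by tissue and phenotype and produces, per tissue group: harmonized
differential expression tables, enrichment results with cross-dataset
consistent terms, pathway expression scores and gene-consistency tables for
the target pathways, guided/topology walk odds ratios with pathway
communities, and a PPI subnetwork with ECC modules for the consistent genes.
All randomness flows from the seeds recorded in the manifest, and every
artifact is written with fixed float formatting, so a rerun with the same
config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from cohortpath.errors import CohortPathError, ConfigurationError
from cohortpath import expression_io, diffexpr, enrichment, pathway_expression
from cohortpath import pathwalks, ppi as ppi_mod

FLOAT_FMT = "%.10g"


@dataclass
class DatasetEntry:
    """One expression dataset in the cohort config."""

    path: str
    group_map: str | dict[str, str]
    tissue: str
    phenotype: str = "ataxia"
    is_log2: bool | None = None
    name: str | None = None


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; mirrors the YAML config layout."""

    datasets: list[DatasetEntry]
    gene_sets: str  # GMT path
    pathway_network: str  # 2-column edge list path
    ppi_table: str | None = None
    target_pathways: list[str] = field(default_factory=list)
    seed_proteins: list[str] = field(default_factory=list)
    out_dir: str = "cohortpath_run"
    p_thresh: float = 0.05
    abs_lfc_thresh: float = 0.585
    top_n: int = 500
    min_fraction: float = 1 / 3
    ppi_threshold: float = 0.700
    n_walkers: int = 6
    n_steps: int = 10_000
    restart_every: int = 50
    seed: int = 0
    rp_prefix_mode: str = "literal"
    annotation: dict[str, str] | None = None

    def validate(self) -> None:
        if not self.datasets:
            raise ConfigurationError("config lists 0 datasets")
        for thr_name in ("p_thresh", "abs_lfc_thresh", "min_fraction", "ppi_threshold"):
            if getattr(self, thr_name) <= 0:
                raise ConfigurationError(f"{thr_name} must be positive")
        for path_field in ("gene_sets", "pathway_network"):
            p = getattr(self, path_field)
            if not Path(p).exists():
                raise ConfigurationError(f"{path_field} path does not exist: {p}")
        if self.ppi_table is not None and not Path(self.ppi_table).exists():
            raise ConfigurationError(f"ppi_table path does not exist: {self.ppi_table}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        datasets = [DatasetEntry(**d) for d in raw.pop("datasets", [])]
        return cls(datasets=datasets, **raw)


class PipelineStageError(CohortPathError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("differential_expression")
def _run_de(entry: DatasetEntry, cfg: PipelineConfig) -> pd.DataFrame:
    ds = expression_io.read_series_matrix(
        entry.path, entry.group_map, is_log2=entry.is_log2, name=entry.name,
    )
    ds = expression_io.harmonize(ds)
    fits = diffexpr.fit_linear_model(ds)
    mod = diffexpr.moderate_variances(fits)
    degs = diffexpr.filter_degs(mod.table, p_thresh=cfg.p_thresh)
    return diffexpr.coding_filter(
        degs, annotation=cfg.annotation, rp_prefix_mode=cfg.rp_prefix_mode
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write a report bundle under ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) mapping each
    tissue group to its artifact paths and headline counts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    collection = enrichment.read_gmt(config.gene_sets)
    network = pathwalks.read_edge_list(config.pathway_network)

    # ------------------------------------------------------------------ DE
    deg_tables: dict[str, pd.DataFrame] = {}
    universes: dict[str, list[str]] = {}
    groups: dict[tuple[str, str], list[str]] = {}
    for i, entry in enumerate(config.datasets):
        name = entry.name or f"ds{i + 1:02d}"
        entry.name = name
        deg_tables[name] = _run_de(entry, config)
        ds_genes = expression_io.read_series_matrix(
            entry.path, entry.group_map, is_log2=entry.is_log2, name=name
        ).gene_ids
        universes[name] = ds_genes
        groups.setdefault((entry.tissue, entry.phenotype), []).append(name)

    from cohortpath import __version__  # deferred: avoids import cycle

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "p": config.p_thresh, "abs_log2FC": config.abs_lfc_thresh,
            "top_n": config.top_n, "min_fraction": config.min_fraction,
            "ppi_score": config.ppi_threshold,
            "walk": [config.n_walkers, config.n_steps, config.restart_every],
        },
        "tissues": {},
    }

    for (tissue, phenotype), names in sorted(groups.items()):
        tag = f"{tissue}_{phenotype}"
        tdir = out / tag
        tdir.mkdir(exist_ok=True)
        entry_art: dict = {"datasets": names, "artifacts": {}}

        for name in names:
            p = tdir / f"degs_{name}.tsv"
            deg_tables[name].to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
            entry_art["artifacts"][f"degs_{name}"] = str(p)

        # ------------------------------------------------------ enrichment
        try:
            per_ds_results = []
            for name in names:
                restricted = collection.restrict(universes[name])
                top = diffexpr.select_top(
                    deg_tables[name], abs_lfc_thresh=config.abs_lfc_thresh,
                    top_n=config.top_n,
                )
                per_ds_results.append(
                    enrichment.over_representation(top, restricted, alpha=config.p_thresh)
                )
            terms = enrichment.consistent_terms(per_ds_results, config.min_fraction)
            p = tdir / "consistent_terms.tsv"
            terms.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
            entry_art["artifacts"]["consistent_terms"] = str(p)
            entry_art["n_consistent_terms"] = int(len(terms))
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("enrichment", exc) from exc

        # -------------------------------------------- pathway expression
        try:
            targets = config.target_pathways or list(collection.sets)
            score_rows = []
            per_ds_member_degs: dict[str, pd.DataFrame] = {}
            target_members: set[str] = set()
            for t in targets:
                target_members |= set(collection.members(t))
            for name in names:
                for t in targets:
                    s = pathway_expression.score_pathway(
                        deg_tables[name], collection, t, universes[name]
                    )
                    score_rows.append({
                        "dataset": name, "pathway_id": t, "n_deg": s.n_deg,
                        "n_total": s.n_total, "rateFC": s.rate_fc,
                        "normMeanFC": s.norm_mean_fc, "combinedFC": s.combined_fc,
                    })
                member = deg_tables[name][deg_tables[name]["gene"].isin(target_members)]
                per_ds_member_degs[name] = member
            scores = pd.DataFrame(score_rows)
            p = tdir / "pathway_scores.tsv"
            scores.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
            entry_art["artifacts"]["pathway_scores"] = str(p)

            if len(names) >= 2:
                consistency = pathway_expression.consistency_scores(
                    per_ds_member_degs, min_fraction=config.min_fraction
                )
            else:
                consistency = pd.DataFrame(
                    columns=["gene", "majority_sign", "score", "consistent"]
                )
            p = tdir / "gene_consistency.tsv"
            consistency.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
            entry_art["artifacts"]["gene_consistency"] = str(p)
            consistent_genes = (
                consistency.loc[consistency["consistent"], "gene"].tolist()
                if len(consistency) else []
            )
            entry_art["n_consistent_genes"] = len(consistent_genes)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("pathway_expression", exc) from exc

        # ------------------------------------------------------- pathwalks
        try:
            if consistent_genes:
                guides = pathwalks.guide_scores(consistent_genes, collection)
                wcfg = pathwalks.WalkConfig(
                    n_walkers=config.n_walkers, n_steps=config.n_steps,
                    restart_every=config.restart_every, seed=config.seed,
                )
                gcounts = pathwalks.guided_walk(network, guides, wcfg)
                tcfg = pathwalks.WalkConfig(
                    n_walkers=config.n_walkers, n_steps=config.n_steps,
                    restart_every=config.restart_every, seed=config.seed + 1,
                )
                tcounts = pathwalks.topology_walk(network, tcfg)
                or_table = pathwalks.odds_ratio(gcounts, tcounts)
                p = tdir / "odds_ratios.tsv"
                or_table.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
                entry_art["artifacts"]["odds_ratios"] = str(p)
                clusters = pathwalks.cluster_pathways(network, gcounts, seed=config.seed)
                p = tdir / "pathway_clusters.tsv"
                pd.DataFrame(
                    sorted(clusters.items()), columns=["pathway", "cluster"]
                ).to_csv(p, sep="\t", index=False)
                entry_art["artifacts"]["pathway_clusters"] = str(p)
                p = tdir / "or_gt1_network.graphml"
                pathwalks.write_or_subnetwork_graphml(network, or_table, p)
                entry_art["artifacts"]["or_gt1_network"] = str(p)
                entry_art["n_or_gt_1"] = int(or_table["or_gt_1"].sum())
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("pathwalks", exc) from exc

        # ------------------------------------------------------------- PPI
        try:
            if config.ppi_table and consistent_genes:
                graph = ppi_mod.read_ppi_table(config.ppi_table, config.ppi_threshold)
                keep = set(consistent_genes) | set(config.seed_proteins)
                sub = graph.subgraph(keep).copy()
                sig = set()
                met = set()
                if config.target_pathways:
                    sig = set(collection.members(config.target_pathways[0]))
                    if len(config.target_pathways) > 1:
                        met = set(collection.members(config.target_pathways[1]))
                ppi_mod.annotate_membership(
                    sub, sorted(sig), sorted(met), config.seed_proteins
                )
                modules, unassigned = ppi_mod.fag_ec_modules(sub)
                p = tdir / "ppi_network.graphml"
                ppi_mod.write_annotated_graphml(sub, p)
                entry_art["artifacts"]["ppi_network"] = str(p)
                p = tdir / "ppi_modules.tsv"
                rows = [
                    {"module": mid, "protein": prot}
                    for mid, members in modules.items() for prot in sorted(members)
                ] + [{"module": -1, "protein": prot} for prot in sorted(unassigned)]
                pd.DataFrame(rows, columns=["module", "protein"]).to_csv(
                    p, sep="\t", index=False
                )
                entry_art["artifacts"]["ppi_modules"] = str(p)
                entry_art["n_ppi_modules"] = len(modules)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("ppi", exc) from exc

        manifest["tissues"][tag] = entry_art

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
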