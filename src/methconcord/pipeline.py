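"""End-to-end orchestration: QC -> differential -> overlap -> enrichment ->
concordance network -> PPI enrichment, driven by one flat YAML config.

Every stage is a self-contained function that reads its prerequisites from
the run directory (or the raw inputs) and writes its outputs there, so any
stage can be re-run alone once its predecessors have completed. All
randomness flows from the single configured seed; result tables are written
with fixed float formatting and no timestamps, so identical config + seed
gives byte-identical outputs. A manifest records the package version, seed,
config hash and completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concord_network import (build_concordance_network, degree_stats,
                              hierarchical_cluster, kept_subgraph,
                              network_to_edge_table, network_to_node_table)
from .differential import DesignSpec, call_differential, differential_test, directional_gene_map
from .enrichment import activation_zscore, build_seed_network, fisher_ora, ppi_enrichment_ztest
from .io_formats import (read_beta_matrix, read_detection_pvalues, read_expression_matrix,
                         read_gene_list, read_gene_sets, read_network,
                         read_probe_annotation, read_sample_sheet, write_results_table)
from .overlap import intersect_directional, overlap_permutation_test, overlap_pvalue_analytic
from .preprocess import (beta_matrix_to_m, detected_probes, flag_outlier_samples,
                         normalize_expression, pca_scores, replicate_correlation)

logger = logging.getLogger(__name__)

STAGES = ("qc", "differential", "overlap", "enrichment", "concordance_network", "ppi_enrichment")

DISEASE_CELL_TYPES = ("iPS", "ONS", "fibroblast")


class StageError(RuntimeError):
    """A pipeline stage failed or a prerequisite output is missing."""


@dataclass
class PipelineConfig:
    """Flat key-value configuration for a full run (YAML-serializable)."""

    beta: str
    methylation_sheet: str
    outdir: str
    expression: str | None = None
    expression_sheet: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    network: str | None = None
    seeds: str | None = None
    detection_pvalues: str | None = None
    alpha_celltype: float = 1e-4
    alpha_disease: float = 0.05
    epsilon: float = 1e-3
    k_sd: float = 4.0
    remove_outliers: bool = False
    n_sims: int = 10_000
    seed: int = 0
    eq1_n_binding: str = "universe"
    replicate_policy: str = "average"

    def __post_init__(self) -> None:
        for name in ("alpha_celltype", "alpha_disease"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.eq1_n_binding not in ("universe", "query"):
            raise ValueError("eq1_n_binding must be 'universe' or 'query'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage {stage!r}: missing prerequisite file {path}")
    return path


def _load_annotation(config: PipelineConfig):
    return read_probe_annotation(config.annotation) if config.annotation else None


def _kept_samples(matrix: pd.DataFrame, config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    flagged_file = outdir / "qc" / "flagged_outliers.txt"
    if config.remove_outliers and flagged_file.exists():
        flagged = {l.strip() for l in flagged_file.read_text().splitlines() if l.strip()}
        keep = [c for c in matrix.columns if c not in flagged]
        return matrix[keep]
    return matrix


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_qc(config: PipelineConfig, outdir: Path) -> None:
    qc_dir = outdir / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    beta = read_beta_matrix(config.beta)
    sheet = read_sample_sheet(config.methylation_sheet)
    detection = read_detection_pvalues(config.detection_pvalues) if config.detection_pvalues else None
    detected = detected_probes(detection, beta.index)
    m = beta_matrix_to_m(beta.loc[detected], epsilon=config.epsilon)

    pairs, summary = replicate_correlation(m, sheet)
    write_results_table(pairs, qc_dir / "replicate_r2.tsv")
    n_comp = min(4, min(m.shape) - 1) or 1
    scores, var = pca_scores(m, n_components=n_comp)
    write_results_table(scores.reset_index(names="sample_id"), qc_dir / "pca_scores.tsv")
    flagged = flag_outlier_samples(scores, k_sd=config.k_sd)
    (qc_dir / "flagged_outliers.txt").write_text("".join(f"{s}\n" for s in flagged))
    summary_out = dict(summary, n_detected_probes=int(len(detected)),
                       variance_explained=[round(float(v), 6) for v in var],
                       flagged_outliers=flagged)
    (qc_dir / "qc_summary.json").write_text(json.dumps(summary_out, indent=1, sort_keys=True))


def stage_differential(config: PipelineConfig, outdir: Path) -> None:
    diff_dir = outdir / "differential"
    diff_dir.mkdir(parents=True, exist_ok=True)
    annotation = _load_annotation(config)
    beta = read_beta_matrix(config.beta)
    sheet = read_sample_sheet(config.methylation_sheet)
    m = _kept_samples(beta_matrix_to_m(beta, epsilon=config.epsilon), config, outdir)
    sheet = sheet.subset(m.columns)

    # patient-control contrast within each cell type (methylation)
    for ct in DISEASE_CELL_TYPES:
        ids = sheet.frame.loc[sheet.frame["cell_type"] == ct, "sample_id"]
        sub = m[[c for c in m.columns if c in set(ids)]]
        design = DesignSpec(("patient", "control"), "status", config.replicate_policy)
        res = differential_test(sub, sheet.subset(sub.columns), design, annotation)
        write_results_table(_result_table(res), diff_dir / f"dm_{ct}.tsv")

    # pairwise cell-type contrasts (methylation), union of significant probes
    union: set[str] = set()
    cts = [ct for ct in DISEASE_CELL_TYPES
           if (sheet.frame["cell_type"] == ct).sum() >= 2]
    for i in range(len(cts)):
        for j in range(i + 1, len(cts)):
            a, b = cts[i], cts[j]
            ids = sheet.frame.loc[sheet.frame["cell_type"].isin([a, b]), "sample_id"]
            sub = m[[c for c in m.columns if c in set(ids)]]
            design = DesignSpec((a, b), "cell_type", config.replicate_policy)
            res = differential_test(sub, sheet.subset(sub.columns), design, annotation)
            write_results_table(_result_table(res), diff_dir / f"dm_celltype_{a}_vs_{b}.tsv")
            union.update(res.index[res["q"] < config.alpha_celltype])
    (diff_dir / "celltype_probes_union.txt").write_text(
        "".join(f"{p}\n" for p in sorted(union)))

    # patient-control contrast within each cell type (expression)
    if config.expression and config.expression_sheet:
        raw = read_expression_matrix(config.expression)
        expr = normalize_expression(raw)
        esheet = read_sample_sheet(config.expression_sheet)
        for ct in DISEASE_CELL_TYPES:
            ids = esheet.frame.loc[esheet.frame["cell_type"] == ct, "sample_id"]
            sub = expr[[c for c in expr.columns if c in set(ids)]]
            design = DesignSpec(("patient", "control"), "status", config.replicate_policy)
            res = differential_test(sub, esheet.subset(sub.columns), design, annotation=None)
            write_results_table(_result_table(res), diff_dir / f"de_{ct}.tsv")


def _result_table(res: pd.DataFrame) -> pd.DataFrame:
    out = res.reset_index()
    cols = ["probe_id", "gene_symbol", "effect", "t", "p", "q", "direction"]
    return out[[c for c in cols if c in out.columns]]


def _read_calls(diff_dir: Path, prefix: str, stage: str) -> dict[str, pd.DataFrame]:
    tables = {}
    for ct in DISEASE_CELL_TYPES:
        path = diff_dir / f"{prefix}_{ct}.tsv"
        if path.exists():
            tables[ct] = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if not tables:
        raise StageError(f"stage {stage!r}: missing prerequisite file {diff_dir}/{prefix}_<celltype>.tsv")
    return tables


def _directional_maps(tables: dict[str, pd.DataFrame], alpha: float,
                      labels: tuple[str, str], key: str) -> dict[str, dict[str, str]]:
    relabel = {"up": labels[0], "down": labels[1]}
    out = {}
    for ct, table in tables.items():
        calls = table[table["q"] < alpha]
        out[ct] = {str(r[key]): relabel[r["direction"]]
                   for _, r in calls.iterrows() if r["direction"] in relabel}
    return out


def stage_overlap(config: PipelineConfig, outdir: Path) -> None:
    diff_dir = _require(outdir / "differential", "overlap")
    over_dir = outdir / "overlap"
    over_dir.mkdir(parents=True, exist_ok=True)
    tables = _read_calls(diff_dir, "dm", "overlap")
    pool_size = len(pd.read_csv(diff_dir / f"dm_{next(iter(tables))}.tsv", sep="\t"))
    lists = _directional_maps(tables, config.alpha_disease, ("hyper", "hypo"), "probe_id")
    shared, by_direction = intersect_directional(lists) if len(lists) >= 2 else ({}, {})
    sizes = [len(v) for v in lists.values()]
    observed = len(shared)
    result = overlap_permutation_test(sizes, pool_size, observed,
                                      n_sims=config.n_sims, seed=config.seed)
    analytic = overlap_pvalue_analytic(sizes, pool_size, observed)
    payload = {"observed_overlap": observed, "list_sizes": sizes, "pool_size": pool_size,
               "n_sims": config.n_sims, "seed": config.seed,
               "p_empirical": result.p_empirical, "p_poisson": analytic,
               "shared": shared, "by_direction": by_direction}
    (over_dir / "overlap_result.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    write_results_table(result.to_frame(), over_dir / "null_histogram.tsv")


def stage_enrichment(config: PipelineConfig, outdir: Path) -> None:
    if not config.gene_sets:
        raise StageError("stage 'enrichment': no gene_sets configured")
    diff_dir = _require(outdir / "differential", "enrichment")
    enr_dir = outdir / "enrichment"
    enr_dir.mkdir(parents=True, exist_ok=True)
    sets = read_gene_sets(config.gene_sets)
    annotation = _load_annotation(config)
    universe = (sorted(set(annotation["gene_symbol"])) if annotation is not None
                else sorted({g for s in sets.values() for g in s}))

    for prefix, labels in (("dm", ("hyper", "hypo")), ("de", ("up", "down"))):
        try:
            tables = _read_calls(diff_dir, prefix, "enrichment")
        except StageError:
            continue
        maps = _directional_maps(tables, config.alpha_disease, labels,
                                 "gene_symbol" if prefix == "de" else "probe_id")
        for ct, table in tables.items():
            calls = table[table["q"] < config.alpha_disease]
            genes = sorted({g for gs in calls["gene_symbol"].astype(str)
                            for g in gs.split(";") if g})
            genes = [g for g in genes if g.upper() in {u.upper() for u in universe}]
            if not genes:
                write_results_table(pd.DataFrame(columns=["set_name", "overlap", "set_size",
                                                          "query_size", "universe_size", "p", "q"]),
                                    enr_dir / f"ora_{prefix}_{ct}.tsv")
                continue
            records = fisher_ora(genes, sets, universe)
            if prefix == "de":
                records = _attach_activation(records, sets, maps[ct])
            write_results_table(records, enr_dir / f"ora_{prefix}_{ct}.tsv")


def _attach_activation(records: pd.DataFrame, sets: dict[str, set[str]],
                       directions: dict[str, str]) -> pd.DataFrame:
    zs, states = [], []
    canon = {g.upper(): d for g, d in directions.items()}
    for name in records["set_name"]:
        members = {g.upper() for g in sets[name]}
        signs = [1 if canon[g] == "up" else -1 for g in canon if g in members]
        z, state = activation_zscore(signs) if signs else (float("nan"), "none")
        zs.append(z)
        states.append(state)
    out = records.copy()
    out["activation_z"] = zs
    out["activation_state"] = states
    return out


def stage_concordance_network(config: PipelineConfig, outdir: Path) -> None:
    if not config.network:
        raise StageError("stage 'concordance_network': no interactome configured")
    diff_dir = _require(outdir / "differential", "concordance_network")
    net_dir = outdir / "network"
    net_dir.mkdir(parents=True, exist_ok=True)
    interactome = read_network(config.network)
    dm_tables = _read_calls(diff_dir, "dm", "concordance_network")
    try:
        de_tables = _read_calls(diff_dir, "de", "concordance_network")
    except StageError:
        de_tables = {}
    annotation = _load_annotation(config)

    for ct in dm_tables:
        dm_calls = dm_tables[ct][dm_tables[ct]["q"] < config.alpha_disease]
        dm_map = _gene_direction_from_table(dm_calls, ("hyper", "hypo"))
        dm_mag = _gene_magnitude_from_table(dm_calls)
        de_map, de_mag = {}, {}
        if ct in de_tables:
            de_calls = de_tables[ct][de_tables[ct]["q"] < config.alpha_disease]
            de_map = _gene_direction_from_table(de_calls, ("up", "down"))
            de_mag = _gene_magnitude_from_table(de_calls)
        network = build_concordance_network(de_map, dm_map, interactome,
                                            de_magnitude=de_mag, dm_magnitude=dm_mag)
        write_results_table(network_to_edge_table(network), net_dir / f"concordance_edges_{ct}.tsv")
        write_results_table(network_to_node_table(network), net_dir / f"concordance_nodes_{ct}.tsv")
        summary, per_node = degree_stats(kept_subgraph(network)) if network.number_of_nodes() else ({}, None)
        (net_dir / f"degree_summary_{ct}.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))

    # hierarchical clustering of the significant cell-type probes
    union_file = diff_dir / "celltype_probes_union.txt"
    if union_file.exists():
        probes = [l.strip() for l in union_file.read_text().splitlines() if l.strip()]
        if len(probes) >= 2:
            beta = read_beta_matrix(config.beta)
            sheet = read_sample_sheet(config.methylation_sheet)
            m = _kept_samples(beta_matrix_to_m(beta, epsilon=config.epsilon), config, outdir)
            keep = sheet.frame.loc[sheet.frame["cell_type"].isin(DISEASE_CELL_TYPES), "sample_id"]
            sub = m.loc[[p for p in probes if p in m.index],
                        [c for c in m.columns if c in set(keep)]]
            result = hierarchical_cluster(sub, cluster_rows=sub.shape[0] <= 5000)
            clusters = result.cut_columns(3)
            out = pd.DataFrame({"sample_id": clusters.index, "cluster": clusters.values,
                                "order": [result.col_order.index(s) for s in clusters.index]})
            write_results_table(out, net_dir / "celltype_clustering.tsv")


def _gene_direction_from_table(calls: pd.DataFrame, labels: tuple[str, str]) -> dict[str, str]:
    relabel = {"up": labels[0], "down": labels[1]}
    per_gene: dict[str, set[str]] = {}
    for _, row in calls.iterrows():
        if row["direction"] not in relabel:
            continue
        for g in str(row["gene_symbol"]).split(";"):
            if g:
                per_gene.setdefault(g, set()).add(relabel[row["direction"]])
    return {g: next(iter(d)) for g, d in per_gene.items() if len(d) == 1}


def _gene_magnitude_from_table(calls: pd.DataFrame) -> dict[str, float]:
    mags: dict[str, float] = {}
    for _, row in calls.iterrows():
        for g in str(row["gene_symbol"]).split(";"):
            if g:
                mags[g] = max(mags.get(g, 0.0), abs(float(row["effect"])))
    return mags


def stage_ppi_enrichment(config: PipelineConfig, outdir: Path) -> None:
    if not config.network or not config.seeds:
        raise StageError("stage 'ppi_enrichment': network and seeds must be configured")
    diff_dir = _require(outdir / "differential", "ppi_enrichment")
    ppi_dir = outdir / "ppi"
    ppi_dir.mkdir(parents=True, exist_ok=True)
    interactome = read_network(config.network)
    seeds = read_gene_list(config.seeds)
    seed_net = build_seed_network(seeds, interactome)
    annotation = _load_annotation(config)
    universe_size = (len(set(annotation["gene_symbol"])) if annotation is not None
                     else interactome.number_of_nodes())

    rows = []
    for prefix in ("dm", "de"):
        try:
            tables = _read_calls(diff_dir, prefix, "ppi_enrichment")
        except StageError:
            continue
        for ct, table in tables.items():
            calls = table[table["q"] < config.alpha_disease]
            genes = sorted({g for gs in calls["gene_symbol"].astype(str)
                            for g in gs.split(";") if g})
            if not genes:
                continue
            res = ppi_enrichment_ztest(genes, seed_net, universe_size,
                                       n_binding=config.eq1_n_binding)
            rows.append({"list": prefix, "cell_type": ct, "n_query": res.n_query,
                         "O": res.O, "E": res.E, "N": res.N, "p": res.p, "q": res.q,
                         "Z": res.Z, "P_one_tailed": res.P_one_tailed,
                         "significant": res.significant})
    table = pd.DataFrame(rows, columns=["list", "cell_type", "n_query", "O", "E", "N",
                                        "p", "q", "Z", "P_one_tailed", "significant"])
    write_results_table(table, ppi_dir / "ppi_enrichment.tsv")
    (ppi_dir / "seed_network.json").write_text(json.dumps(
        {"n_nodes": seed_net.number_of_nodes(), "n_edges": seed_net.number_of_edges(),
         "n_seeds_present": int(sum(1 for _, s in seed_net.nodes(data="seed") if s))},
        indent=1, sort_keys=True))


STAGE_FUNCTIONS = {
    "qc": stage_qc,
    "differential": stage_differential,
    "overlap": stage_overlap,
    "enrichment": stage_enrichment,
    "concordance_network": stage_concordance_network,
    "ppi_enrichment": stage_ppi_enrichment,
}


def run_stage(name: str, config: PipelineConfig) -> None:
    """Run a single stage against the configured run directory."""
    if name not in STAGE_FUNCTIONS:
        raise StageError(f"unknown stage {name!r}; valid stages: {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        STAGE_FUNCTIONS[name](config, outdir)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage named
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, stages=STAGES) -> Path:
    """Run all stages in order, writing a manifest of completed stages.

    A stage failure aborts the run with a stage-named error; outputs of the
    stages that already completed are preserved, and the manifest reflects
    exactly the completed set.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest_path = outdir / "manifest.json"

    def write_manifest():
        manifest = {"package": "methconcord", "version": __version__,
                    "seed": config.seed, "config_hash": config.config_hash(),
                    "config": asdict(config), "completed_stages": completed}
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))

    for name in stages:
        try:
            run_stage(name, config)
        except StageError:
            write_manifest()
            raise
        completed.append(name)
        logger.info("completed stage %s", name)
    write_manifest()
    return outdir
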