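"""Synthetic case-control methylation/expression studies with planted truth.

The generator emulates the statistical structure of a small multi-cell-type
patient-control array study: a 27,578-probe methylation array measured in
triplicate (consecutive passages as technical replicates) on iPS cells
(with per-subject clones as biological replicates), olfactory
neurosphere-derived (ONS) cells and fibroblasts from the same subjects, plus
an embryonic stem cell comparator line used for QC only. Planted effects
comprise cell-type differences, per-cell-type disease effects, and a small
shared disease core present in all three cell types with a common direction.
A coupled expression study, a scale-free interactome with designated seed
genes, and gene-set collections complete the pipeline's inputs.

Effects are planted on the M (logit2) scale, where the downstream statistics
operate, and back-transformed so every beta value stays inside (0, 1);
effect magnitudes are configured as beta-scale differences (delta beta) for
interpretability. All randomness flows from one integer seed through
deterministic child streams, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import SampleSheet, write_gene_sets, write_matrix, write_network
from .preprocess import beta_to_m, m_to_beta

DEFAULT_DISEASE_FRACTIONS = {
    "iPS": 883 / 27578,
    "ONS": 1328 / 27578,
    "fibroblast": 952 / 27578,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the emulated design."""

    n_probes: int = 27578
    cell_types: tuple[str, ...] = ("iPS", "ONS", "fibroblast")
    include_es: bool = True            # ES comparator line (QC only, control status)
    n_patients: int = 4
    n_controls: int = 4
    ips_clones: int = 2                # iPS clones per subject (biological replicates)
    technical_replicates: int = 3      # consecutive passages measured per line
    # baseline beta mixture: hypo/mid/hyper modes so binning has mass everywhere
    baseline_weights: tuple[float, float, float] = (0.30, 0.40, 0.30)
    baseline_params: tuple[tuple[float, float], ...] = ((2.0, 8.0), (10.0, 10.0), (8.0, 2.0))
    # cell-type structure
    celltype_effect_fraction: float = 0.28
    celltype_delta_m: float = 2.0
    # disease effects
    disease_effect_fractions: dict = field(default_factory=lambda: dict(DEFAULT_DISEASE_FRACTIONS))
    shared_core_size: int = 5
    core_hypo_fraction: float = 0.8    # 4 of 5 core loci hypomethylated in patients
    disease_delta_beta: float = 0.2
    # noise on the M scale
    biological_sd_m: float = 0.30
    technical_sd_m: float = 0.15
    planted_outlier: bool = False
    outlier_shift_m: float = 3.0
    # expression coupling
    probes_per_gene: int = 1
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.5
    expr_celltype_fraction: float = 0.30
    expr_celltype_effect: float = 1.5
    coupling_fraction: float = 0.8
    concordance_prob: float = 0.9
    de_effect_log2: float = 1.0
    de_background_fraction: float = 0.01
    expr_biological_sd: float = 0.40
    expr_technical_sd: float = 0.10
    # interactome
    interactome_genes: int = 2000
    attachment_m: int = 3
    n_seed_genes: int = 20
    seed_enrichment: float = 8.0       # sampling-weight multiplier for disease genes
    # gene sets
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (20, 200)
    n_enriched_sets: int = 5
    enriched_set_disease_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [self.celltype_effect_fraction, self.coupling_fraction,
                 self.concordance_prob, self.core_hypo_fraction,
                 self.de_background_fraction, *self.disease_effect_fractions.values()]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if set(self.disease_effect_fractions) != set(self.cell_types):
            raise ValueError("disease_effect_fractions must key exactly the cell types")
        for ct, frac in self.disease_effect_fractions.items():
            if self.shared_core_size > round(frac * self.n_probes):
                raise ValueError(f"shared_core_size exceeds planted count for {ct}")
        if self.interactome_genes < self.attachment_m + 1:
            raise ValueError("interactome_genes must exceed attachment_m")
        if not 0 < self.disease_delta_beta < 0.5:
            raise ValueError("disease_delta_beta must lie in (0, 0.5)")


@dataclass
class GroundTruth:
    """Planted labels: which probes/genes carry which effects, and the seeds."""

    probe_ids: list[str]
    gene_of_probe: dict[str, str]
    celltype_probes: dict[str, dict[str, float]]      # cell type -> probe -> M offset
    disease_probes: dict[str, dict[str, str]]         # cell type -> probe -> hypo/hyper
    shared_core: dict[str, str]                       # probe -> direction (all cell types)
    de_genes: dict[str, dict[str, str]] = field(default_factory=dict)  # ct -> gene -> up/down
    seed_genes: list[str] = field(default_factory=list)

    def disease_genes(self, cell_type: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for probe, direction in self.disease_probes[cell_type].items():
            out[self.gene_of_probe[probe]] = direction
        return out

    def all_disease_genes(self) -> set[str]:
        genes: set[str] = set()
        for ct in self.disease_probes:
            genes.update(self.disease_genes(ct))
        return genes

    def to_json(self, path) -> None:
        payload = {
            "gene_of_probe": self.gene_of_probe,
            "celltype_probes": self.celltype_probes,
            "disease_probes": self.disease_probes,
            "shared_core": self.shared_core,
            "de_genes": self.de_genes,
            "seed_genes": self.seed_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def probe_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic probe -> gene table (``probes_per_gene`` probes per symbol)."""
    probe_ids = [f"cg{i:05d}" for i in range(config.n_probes)]
    genes = [f"GENE{i // config.probes_per_gene:05d}" for i in range(config.n_probes)]
    return pd.DataFrame({"probe_id": probe_ids, "gene_symbol": genes})


def simulate_methylation_study(config: SimulationConfig) -> tuple[pd.DataFrame, SampleSheet, GroundTruth]:
    """Generate the beta matrix, sample sheet and planted truth for one study."""
    rng_base, rng_ct, rng_dis, rng_noise = _child_rngs(config.seed, 4)
    n = config.n_probes
    annotation = probe_annotation(config)
    probe_ids = list(annotation["probe_id"])
    gene_of_probe = dict(zip(annotation["probe_id"], annotation["gene_symbol"]))

    # baseline methylation: mixture of hypo/mid/hyper Beta modes
    component = rng_base.choice(len(config.baseline_weights), size=n, p=config.baseline_weights)
    a = np.array([p[0] for p in config.baseline_params])[component]
    b = np.array([p[1] for p in config.baseline_params])[component]
    baseline_beta = np.clip(rng_base.beta(a, b), 0.02, 0.98)
    baseline_m = beta_to_m(baseline_beta)

    # cell-type effects: each affected probe is shifted in one cell type
    n_ct = round(config.celltype_effect_fraction * n)
    ct_probes_idx = rng_ct.choice(n, size=n_ct, replace=False)
    ct_assign = rng_ct.choice(len(config.cell_types), size=n_ct)
    ct_sign = rng_ct.choice([-1.0, 1.0], size=n_ct)
    ct_offsets = {ct: np.zeros(n) for ct in config.cell_types}
    celltype_probes: dict[str, dict[str, float]] = {ct: {} for ct in config.cell_types}
    for idx, which, sign in zip(ct_probes_idx, ct_assign, ct_sign):
        ct = config.cell_types[which]
        off = sign * config.celltype_delta_m
        ct_offsets[ct][idx] = off
        celltype_probes[ct][probe_ids[idx]] = float(off)

    # disease effects: shared core first, then per-cell-type private loci
    def delta_m_for(idx: np.ndarray, sign: np.ndarray) -> np.ndarray:
        target = np.clip(baseline_beta[idx] + sign * config.disease_delta_beta, 0.02, 0.98)
        return beta_to_m(target) - baseline_m[idx]

    core_idx = rng_dis.choice(n, size=config.shared_core_size, replace=False)
    n_core_hypo = round(config.core_hypo_fraction * config.shared_core_size)
    core_sign = np.array([-1.0] * n_core_hypo + [1.0] * (config.shared_core_size - n_core_hypo))
    disease_offsets = {ct: np.zeros(n) for ct in config.cell_types}
    disease_probes: dict[str, dict[str, str]] = {ct: {} for ct in config.cell_types}
    shared_core = {probe_ids[i]: ("hypo" if s < 0 else "hyper")
                   for i, s in zip(core_idx, core_sign)}
    core_delta = delta_m_for(core_idx, core_sign)
    rest = np.setdiff1d(np.arange(n), core_idx)
    for ct in config.cell_types:
        count = round(config.disease_effect_fractions[ct] * n)
        extra = rng_dis.choice(rest, size=count - config.shared_core_size, replace=False)
        sign = rng_dis.choice([-1.0, 1.0], size=extra.size)
        disease_offsets[ct][core_idx] = core_delta
        disease_offsets[ct][extra] = delta_m_for(extra, sign)
        for i, s in zip(core_idx, core_sign):
            disease_probes[ct][probe_ids[i]] = "hypo" if s < 0 else "hyper"
        for i, s in zip(extra, sign):
            disease_probes[ct][probe_ids[i]] = "hypo" if s < 0 else "hyper"

    # samples: subjects x cell types x clones x technical replicates
    subjects = ([(f"P{i + 1:02d}", "patient") for i in range(config.n_patients)]
                + [(f"C{i + 1:02d}", "control") for i in range(config.n_controls)])
    columns: dict[str, np.ndarray] = {}
    rows = []

    def add_line(subject, status, ct, clone, ct_offset, dis_offset):
        unit = (baseline_m + ct_offset + dis_offset
                + rng_noise.normal(0.0, config.biological_sd_m, size=n))
        for rep in range(1, config.technical_replicates + 1):
            sid = f"{subject}-{ct}-{clone}-p{rep}"
            columns[sid] = unit + rng_noise.normal(0.0, config.technical_sd_m, size=n)
            rows.append({"sample_id": sid, "subject_id": subject, "cell_type": ct,
                         "status": status, "passage": rep, "clone_id": clone,
                         "replicate_role": "technical"})

    for subject, status in subjects:
        for ct in config.cell_types:
            clones = config.ips_clones if ct == "iPS" else 1
            dis = disease_offsets[ct] if status == "patient" else 0.0
            for c in range(1, clones + 1):
                add_line(subject, status, ct, f"cl{c}", ct_offsets[ct], dis)
    if config.include_es:
        # ES comparator clusters with iPS (pluripotent); never enters contrasts
        add_line("ES01", "control", "ES", "cl1", ct_offsets["iPS"], 0.0)

    if config.planted_outlier:
        last = list(columns)[-1]
        columns[last] = columns[last] + config.outlier_shift_m

    beta = pd.DataFrame(m_to_beta(np.column_stack(list(columns.values()))),
                        index=probe_ids, columns=list(columns))
    beta.index.name = "probe_id"
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = GroundTruth(probe_ids=probe_ids, gene_of_probe=gene_of_probe,
                        celltype_probes=celltype_probes, disease_probes=disease_probes,
                        shared_core=shared_core)
    return beta, sheet, truth


def simulate_expression_study(config: SimulationConfig,
                              truth: GroundTruth) -> tuple[pd.DataFrame, SampleSheet, GroundTruth]:
    """Generate a raw fluorescence matrix coupled to the methylation truth.

    A ``coupling_fraction`` of each cell type's differentially methylated
    genes receives an expression effect whose sign is concordant
    (hypo -> up, hyper -> down) with probability ``concordance_prob``; a small
    independent background of DE genes is added on top. Truth gains the
    per-cell-type DE gene directions.
    """
    rng_struct, rng_noise = _child_rngs(config.seed + 1, 2)
    genes = sorted(set(truth.gene_of_probe.values()))
    g_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    baseline = rng_struct.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=n)

    n_ct = round(config.expr_celltype_fraction * n)
    ct_idx = rng_struct.choice(n, size=n_ct, replace=False)
    ct_assign = rng_struct.choice(len(config.cell_types), size=n_ct)
    ct_sign = rng_struct.choice([-1.0, 1.0], size=n_ct)
    ct_offsets = {ct: np.zeros(n) for ct in config.cell_types}
    for idx, which, sign in zip(ct_idx, ct_assign, ct_sign):
        ct_offsets[config.cell_types[which]][idx] = sign * config.expr_celltype_effect

    de_offsets = {ct: np.zeros(n) for ct in config.cell_types}
    de_genes: dict[str, dict[str, str]] = {}
    for ct in config.cell_types:
        dm = truth.disease_genes(ct)
        dm_list = sorted(dm)
        n_coupled = round(config.coupling_fraction * len(dm_list))
        coupled = list(rng_struct.choice(dm_list, size=n_coupled, replace=False)) if n_coupled else []
        table: dict[str, str] = {}
        for g in coupled:
            concordant = rng_struct.random() < config.concordance_prob
            up = (dm[g] == "hypo") == concordant
            table[g] = "up" if up else "down"
        free = [g for g in genes if g not in dm]
        n_bg = round(config.de_background_fraction * len(free))
        if n_bg:
            for g in rng_struct.choice(free, size=n_bg, replace=False):
                table[str(g)] = "up" if rng_struct.random() < 0.5 else "down"
        for g, d in table.items():
            de_offsets[ct][g_index[g]] = config.de_effect_log2 if d == "up" else -config.de_effect_log2
        de_genes[ct] = table
    truth.de_genes = de_genes

    columns: dict[str, np.ndarray] = {}
    meta = []
    sheet_rows = []
    for row in _expression_sample_plan(config):
        meta.append(row)
    for subject, status, ct, clone in meta:
        dis = de_offsets[ct] if (status == "patient" and ct in de_offsets) else 0.0
        ct_off = ct_offsets[ct] if ct in ct_offsets else ct_offsets["iPS"]
        unit = baseline + ct_off + dis + rng_noise.normal(0.0, config.expr_biological_sd, size=n)
        for rep in range(1, config.technical_replicates + 1):
            sid = f"{subject}-{ct}-{clone}-x{rep}"
            columns[sid] = unit + rng_noise.normal(0.0, config.expr_technical_sd, size=n)
            sheet_rows.append({"sample_id": sid, "subject_id": subject, "cell_type": ct,
                               "status": status, "passage": rep, "clone_id": clone,
                               "replicate_role": "technical"})
    raw = pd.DataFrame(np.exp2(np.column_stack(list(columns.values()))),
                       index=genes, columns=list(columns))
    raw.index.name = "probe_id"
    raw.attrs["normalization"] = "raw"
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return raw, sheet, truth


def _expression_sample_plan(config: SimulationConfig):
    subjects = ([(f"P{i + 1:02d}", "patient") for i in range(config.n_patients)]
                + [(f"C{i + 1:02d}", "control") for i in range(config.n_controls)])
    for subject, status in subjects:
        for ct in config.cell_types:
            clones = config.ips_clones if ct == "iPS" else 1
            for c in range(1, clones + 1):
                yield subject, status, ct, f"cl{c}"
    if config.include_es:
        yield "ES01", "control", "ES", "cl1"


def simulate_interactome(config: SimulationConfig,
                         truth: GroundTruth) -> tuple[nx.Graph, list[str]]:
    """Scale-free interactome over a subset of the gene universe, plus seeds.

    The topology is a preferential-attachment (Barabasi-Albert) graph whose
    nodes are relabeled with gene symbols drawn uniformly from the universe.
    Seed genes are sampled from the network's nodes with weight
    ``1 + seed_enrichment`` for disease-affected genes, so a positive
    ``seed_enrichment`` plants genuine enrichment of the disease lists in the
    seed network; ``seed_enrichment = 0`` leaves the seeds unbiased (null).
    """
    rng = _child_rngs(config.seed + 2, 1)[0]
    genes = sorted(set(truth.gene_of_probe.values()))
    n_nodes = min(config.interactome_genes, len(genes))
    labels = rng.choice(genes, size=n_nodes, replace=False)
    graph = nx.barabasi_albert_graph(n_nodes, config.attachment_m,
                                     seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: str(labels[i]) for i in range(n_nodes)})
    disease = truth.all_disease_genes()
    nodes = sorted(graph.nodes)
    weights = np.array([1.0 + config.seed_enrichment * (g in disease) for g in nodes])
    weights /= weights.sum()
    seeds = [str(s) for s in rng.choice(nodes, size=min(config.n_seed_genes, n_nodes),
                                        replace=False, p=weights)]
    truth.seed_genes = seeds
    return graph, seeds


def simulate_gene_sets(config: SimulationConfig, truth: GroundTruth) -> dict[str, set[str]]:
    """Gene-set collection with a few sets enriched for disease-affected genes."""
    rng = _child_rngs(config.seed + 3, 1)[0]
    genes = sorted(set(truth.gene_of_probe.values()))
    disease = sorted(truth.all_disease_genes())
    lo, hi = config.gene_set_size_range
    hi = min(hi, len(genes))
    collection: dict[str, set[str]] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < config.n_enriched_sets and disease:
            n_dis = min(round(config.enriched_set_disease_fraction * size), len(disease))
            members = set(rng.choice(disease, size=n_dis, replace=False))
            others = [g for g in genes if g not in members]
            members.update(rng.choice(others, size=size - len(members), replace=False))
            collection[f"SET_ENRICHED_{i:03d}"] = {str(g) for g in members}
        else:
            collection[f"SET_{i:03d}"] = {str(g) for g in rng.choice(genes, size=size, replace=False)}
    return collection


def write_fixture_dir(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate the complete input fixture for a pipeline run and write it out.

    Writes the beta matrix, raw expression matrix, both sample sheets, the
    probe annotation, GMT gene sets, interactome edge list, seed-gene list and
    the ground-truth JSON. Returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beta, sheet, truth = simulate_methylation_study(config)
    expr, expr_sheet, truth = simulate_expression_study(config, truth)
    graph, seeds = simulate_interactome(config, truth)
    sets = simulate_gene_sets(config, truth)
    paths = {
        "beta": outdir / "beta.tsv",
        "methylation_sheet": outdir / "samples_methylation.tsv",
        "expression": outdir / "expression_raw.tsv",
        "expression_sheet": outdir / "samples_expression.tsv",
        "annotation": outdir / "probe_annotation.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "network": outdir / "interactome_edges.tsv",
        "seeds": outdir / "seed_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_matrix(beta, paths["beta"])
    sheet.to_file(paths["methylation_sheet"])
    write_matrix(expr, paths["expression"], float_format="%.8g")
    expr_sheet.to_file(paths["expression_sheet"])
    probe_annotation(config).to_csv(paths["annotation"], sep="\t", index=False)
    write_gene_sets(sets, paths["gene_sets"])
    write_network(graph, paths["network"])
    paths["seeds"].write_text("\n".join(seeds) + "\n")
    truth.to_json(paths["truth"])
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=1, sort_keys=True, default=list))
    return paths
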