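"""Readers and writers for every external table the pipeline touches.

All tabular inputs are plain text: probe-major TSV matrices with a
``probe_id`` first column (CSV accepted via the delimiter argument), a
sample-sheet TSV, GMT gene-set collections and two-column edge lists.
Missing values are encoded as ``NA`` and propagated as missing, never as 0.
Every validation failure names the offending row/column so that a broken
export can be located in the source file.

Gene symbols are case-preserved on read but matched case-insensitively
across tables (methylation, expression and network files typically come
from different vendors); :func:`canonical_gene` is the single place that
rule lives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_TYPES = ("iPS", "ONS", "fibroblast", "ES")
STATUSES = ("patient", "control")
REPLICATE_ROLES = ("technical", "biological")

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "subject_id",
    "cell_type",
    "status",
    "passage",
    "clone_id",
    "replicate_role",
)


class ValidationError(ValueError):
    """An input table violated a structural invariant."""


def canonical_gene(symbol: str) -> str:
    """Canonical form used for cross-table gene matching (case-insensitive)."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Per-sample metadata: subject, cell type, disease status, passage, clone.

    Technical replicates (consecutive culture passages of the same line) share
    ``subject_id``, ``clone_id`` and ``cell_type``; distinct clones of the same
    subject are biological replicates.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in ("sample_id", "subject_id", "cell_type", "status") if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing required columns: {missing}")
        for col in ("passage", "clone_id", "replicate_role"):
            if col not in df.columns:
                df[col] = pd.NA
        if len(df) == 0:
            raise ValidationError("no samples in sample sheet")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id(s): {sorted(dup.unique())}")
        bad_ct = df.loc[~df["cell_type"].isin(CELL_TYPES), "cell_type"]
        if len(bad_ct):
            raise ValidationError(
                f"unknown cell_type token(s) {sorted(bad_ct.unique())}; expected one of {CELL_TYPES}"
            )
        bad_st = df.loc[~df["status"].isin(STATUSES), "status"]
        if len(bad_st):
            raise ValidationError(
                f"unknown status token(s) {sorted(bad_st.unique())}; expected one of {STATUSES}"
            )
        known_role = df["replicate_role"].dropna()
        bad_role = known_role[~known_role.isin(REPLICATE_ROLES)]
        if len(bad_role):
            raise ValidationError(f"unknown replicate_role token(s): {sorted(bad_role.unique())}")
        df["passage"] = pd.to_numeric(df["passage"], errors="raise").astype("Int64")
        if (df["passage"].dropna() < 0).any():
            raise ValidationError("negative passage number")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    def replicate_groups(self) -> dict[tuple, list[str]]:
        """Map (subject_id, clone_id, cell_type) -> sample_ids of the technical-replicate group."""
        df = self.frame
        key = list(zip(df["subject_id"], df["clone_id"].fillna(""), df["cell_type"]))
        groups: dict[tuple, list[str]] = {}
        for k, sid in zip(key, df["sample_id"]):
            groups.setdefault(k, []).append(sid)
        return groups

    def subset(self, sample_ids) -> "SampleSheet":
        keep = self.frame[self.frame["sample_id"].isin(list(sample_ids))]
        return SampleSheet(keep.copy())

    def to_file(self, path, delimiter: str = "\t") -> None:
        self.frame.to_csv(path, sep=delimiter, index=False, na_rep="NA")


def read_sample_sheet(path, delimiter: str = "\t") -> SampleSheet:
    """Read a sample sheet TSV into a validated :class:`SampleSheet`."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, na_values=["NA"], keep_default_na=False)
    if len(df) == 0:
        raise ValidationError(f"no samples in sample sheet {path}")
    sheet = SampleSheet(df)
    logger.info("read sample sheet %s: %d samples, %d subjects", path, len(sheet.frame), len(sheet.subjects))
    return sheet


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def _read_matrix(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    first = df.columns[0]
    if df[first].duplicated().any():
        dups = sorted(df[first][df[first].duplicated()].unique())
        raise ValidationError(f"duplicate probe_id(s) in {path}: {dups[:5]}")
    df = df.set_index(first)
    df.index.name = "probe_id"
    return df.astype(float)


def read_beta_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a probe x sample beta-value matrix.

    Beta is the methylation fraction (methylated intensity over total
    intensity), so every present value must lie in [0, 1]; out-of-range
    values raise a :class:`ValidationError` naming the probe and sample.
    Missing values ("NA") are kept as NaN.
    """
    df = _read_matrix(path, delimiter)
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        probe = df.index[bad.any(axis=1)][0]
        sample = df.columns[bad.loc[probe]][0]
        raise ValidationError(
            f"beta value out of [0,1] at probe {probe!r}, sample {sample!r}: {df.loc[probe, sample]}"
        )
    logger.info("read beta matrix %s: %d probes x %d samples", path, *df.shape)
    return df


def read_expression_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a probe x sample expression fluorescence matrix (raw values >= 0)."""
    df = _read_matrix(path, delimiter)
    bad = df < 0
    if bad.any().any():
        probe = df.index[bad.any(axis=1)][0]
        sample = df.columns[bad.loc[probe]][0]
        raise ValidationError(f"negative fluorescence at probe {probe!r}, sample {sample!r}")
    df.attrs["normalization"] = "raw"
    logger.info("read expression matrix %s: %d probes x %d samples", path, *df.shape)
    return df


def read_detection_pvalues(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a probe x sample detection p-value matrix (same dialect as beta)."""
    df = _read_matrix(path, delimiter)
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        probe = df.index[bad.any(axis=1)][0]
        raise ValidationError(f"detection p-value out of [0,1] at probe {probe!r}")
    return df


def write_matrix(df: pd.DataFrame, path, delimiter: str = "\t", float_format: str = "%.10g") -> None:
    """Write a probe x sample matrix with a probe_id first column."""
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=delimiter, na_rep="NA", float_format=float_format)


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------


def read_probe_annotation(path, delimiter: str = "\t", gene_delimiter: str = ";") -> pd.DataFrame:
    """Read a probe -> gene symbol table (columns probe_id, gene_symbol).

    A probe may map to several symbols separated by ``gene_delimiter``; the
    mapping is returned exploded to one (probe_id, gene_symbol) row per pair.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, na_values=["NA"], keep_default_na=False)
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise ValidationError(f"annotation missing column {col!r}")
    if df["probe_id"].duplicated().any():
        dups = sorted(df["probe_id"][df["probe_id"].duplicated()].unique())
        raise ValidationError(f"duplicate probe_id(s) in annotation: {dups[:5]}")
    df = df.assign(gene_symbol=df["gene_symbol"].str.split(gene_delimiter)).explode("gene_symbol")
    df["gene_symbol"] = df["gene_symbol"].str.strip()
    df = df[df["gene_symbol"].astype(bool)]
    return df.reset_index(drop=True)


def probes_to_genes(probe_ids, annotation: pd.DataFrame | None) -> list[str]:
    """Unique gene symbols mapped by ``probe_ids`` (identity mapping if no annotation)."""
    if annotation is None:
        return sorted(set(map(str, probe_ids)))
    sub = annotation[annotation["probe_id"].isin(set(map(str, probe_ids)))]
    seen: dict[str, str] = {}
    for sym in sub["gene_symbol"]:
        seen.setdefault(canonical_gene(sym), sym)
    return sorted(seen.values())


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file (set name, description, members per line) into a dict.

    Duplicate members within a line are deduplicated with a warning; a line
    with fewer than three fields raises an error with its line number.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            members = [m for m in fields[2:] if m.strip()]
            if name in collection:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not members:
                raise ValidationError(f"{path}:{lineno}: empty gene set {name!r}")
            if len(set(members)) != len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated")
            collection[name] = set(members)
    if not collection:
        raise ValidationError(f"no gene sets in {path}")
    logger.info("read %d gene sets from %s (sizes %d-%d)", len(collection), path,
                min(map(len, collection.values())), max(map(len, collection.values())))
    return collection


def write_gene_sets(collection: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            members = sorted(collection[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------


def read_network(path, delimiter: str | None = None) -> nx.Graph:
    """Read a two-column edge list into an undirected simple graph.

    Whitespace- or tab-delimited pairs; a third (interaction-type) column is
    tolerated and ignored. Self-loops are dropped with a warning; duplicate
    edges collapse.
    """
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: edge line has < 2 fields")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    if graph.number_of_nodes() == 0:
        raise ValidationError(f"no edges in network file {path}")
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-loop(s)")
    logger.info("read network %s: %d nodes, %d edges", path, graph.number_of_nodes(), graph.number_of_edges())
    return graph


def write_network(graph: nx.Graph, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}{delimiter}{b}\n")


def read_gene_list(path) -> list[str]:
    """Read a one-gene-per-line text file (blank lines and # comments skipped)."""
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    if not out:
        raise ValidationError(f"no genes in {path}")
    return out


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_results_table(records: pd.DataFrame, path, delimiter: str = "\t",
                        float_format: str = "%.6g") -> None:
    """Write a results table as TSV: header row, stable column order, fixed float precision."""
    records.to_csv(path, sep=delimiter, index=False, na_rep="NA", float_format=float_format)


def read_results_table(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, na_values=["NA"], keep_default_na=False)
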