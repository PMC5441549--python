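"""Per-probe case-control (and cell-type) differential testing.

The model is a two-group comparison per probe on the M-value (methylation) or
normalized log2 fluorescence (expression) scale. Consecutive-passage
technical replicates are collapsed to one column per biological unit
(subject, clone, cell type) before fitting; iPS clones of the same subject
remain separate biological replicates. Per-probe residual variances are
shrunk toward a common prior by empirical-Bayes moderation (moment matching
on log variances, the standard microarray practice), giving a moderated t
with augmented degrees of freedom. P-values are two-sided and adjusted by
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleSheet, probes_to_genes

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """A two-group contrast drawn from sample-sheet columns.

    ``contrast`` is the ordered pair of group labels (effect = mean(first) -
    mean(second)); ``group_column`` names the sheet column holding them
    ("status" for patient-control, "cell_type" for pairwise cell-type
    contrasts). ``technical_replicate_policy`` is "average" (collapse
    passages to their mean, the default) or "block" (keep columns; not the
    default and intended for future block-correlation modelling).
    """

    contrast: tuple[str, str]
    group_column: str = "status"
    technical_replicate_policy: str = "average"

    def __post_init__(self) -> None:
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise ValueError("contrast must be two distinct group labels")
        if self.technical_replicate_policy not in ("average", "block"):
            raise ValueError("technical_replicate_policy must be 'average' or 'block'")


def collapse_technical_replicates(matrix: pd.DataFrame, sheet: SampleSheet,
                                  policy: str = "average") -> tuple[pd.DataFrame, SampleSheet]:
    """Collapse technical-replicate columns to one per (subject, clone, cell type) unit.

    Policy "average" takes the within-group mean per probe; a group of size 1
    passes through. Returns the collapsed matrix and a unit-level sheet whose
    sample_id is the first sample of each group. Policy "block" returns the
    inputs unchanged (block structure is then the fitter's business).
    """
    if policy == "block":
        return matrix, sheet
    if policy != "average":
        raise ValueError(f"unknown replicate policy {policy!r}")
    groups = sheet.replicate_groups()
    cols = {}
    rows = []
    meta = sheet.frame.set_index("sample_id")
    for key, samples in groups.items():
        present = [s for s in samples if s in matrix.columns]
        if not present:
            continue
        unit_id = present[0]
        cols[unit_id] = matrix[present].mean(axis=1)
        row = meta.loc[present[0]].copy()
        row["sample_id"] = unit_id
        rows.append(row)
    collapsed = pd.DataFrame(cols)
    collapsed.index = matrix.index
    unit_sheet = SampleSheet(pd.DataFrame(rows).reset_index(drop=True))
    return collapsed, unit_sheet


def fit_group_model(matrix: pd.DataFrame, sheet: SampleSheet,
                    design: DesignSpec) -> pd.DataFrame:
    """Per-probe two-group fit: effect, pooled variance and residual df.

    effect = mean(group1) - mean(group2); s2 is the pooled within-group
    variance with df = n1 + n2 - 2. Requires >= 2 units per group so the
    variance is defined.
    """
    meta = sheet.frame.set_index("sample_id")
    meta = meta.loc[[s for s in matrix.columns if s in meta.index]]
    g1 = meta.index[meta[design.group_column] == design.contrast[0]]
    g2 = meta.index[meta[design.group_column] == design.contrast[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"contrast {design.contrast} needs >= 2 units per group, got {n1} and {n2}"
        )
    x1 = matrix[list(g1)].to_numpy(dtype=float)
    x2 = matrix[list(g2)].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df
    out = pd.DataFrame({"effect": m1 - m2, "s2": s2, "df": df, "n1": n1, "n2": n2},
                       index=matrix.index)
    out.index.name = "probe_id"
    return out


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-probe variances toward a common prior.

    The prior is a scaled inverse chi-square with df ``d0`` and scale ``s0^2``,
    fitted by moment matching on log variances (mean and excess variance of
    log s2 relative to the chi-square sampling noise). The posterior variance
    is the precision-weighted blend s2_post = (d0*s0^2 + df*s2) / (d0 + df).
    When the observed log-variance spread does not exceed sampling noise,
    d0 = inf and every probe is shrunk fully to s0^2 (with identical s2 this
    leaves s2 unchanged). Returns (s2_post, d0, s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need >= 10 probes for stable hyperparameter fitting")
    positive = s2[s2 > 0]
    if positive.size < 10:
        raise ValueError("need >= 10 positive variances for hyperparameter fitting")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    elif z.var(ddof=0) == 0:
        # literally identical variances: treated as exact, left unchanged
        d0 = np.inf
        s0_2 = float(np.exp(z.mean()))
        s2_post = np.full_like(s2, s0_2)
    else:
        # spread within chi-square sampling noise: fully pooled, with the
        # log-scale bias correction (geometric mean alone underestimates s0^2)
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        s2_post = np.full_like(s2, s0_2)
    return s2_post, float(d0), s0_2


def moderated_t_test(fit: pd.DataFrame, d0: float | None = None,
                     s0_2: float | None = None) -> pd.DataFrame:
    """Moderated t and two-sided p for a per-probe group fit.

    If (d0, s0^2) are not supplied they are estimated by
    :func:`moderate_variances`; d0 = 0 recovers the ordinary pooled-variance
    two-sample t-test exactly.
    """
    s2 = fit["s2"].to_numpy(dtype=float)
    df = float(fit["df"].iloc[0])
    n1, n2 = float(fit["n1"].iloc[0]), float(fit["n2"].iloc[0])
    if d0 is None:
        s2_post, d0, s0_2 = moderate_variances(s2, df)
    elif d0 == 0:
        s2_post = s2
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit["effect"].to_numpy(dtype=float) / se
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)  # zero effect over zero variance: no evidence
    t = np.where(np.isnan(t), 0.0, t)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["df_total"] = df_total
    out["p"] = np.clip(p, 0.0, 1.0)
    out.attrs["d0"] = d0
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_test(matrix: pd.DataFrame, sheet: SampleSheet, design: DesignSpec,
                      annotation: pd.DataFrame | None = None,
                      moderate: bool = True) -> pd.DataFrame:
    """Full per-probe differential pipeline for one contrast.

    Collapses technical replicates per the design policy, fits the two-group
    model, moderates variances (unless ``moderate`` is False or there are too
    few probes, in which case the ordinary t is used with a warning), and
    attaches two-sided p, BH q, direction ("up" for positive effect, "down"
    for negative) and mapped gene symbols.
    """
    collapsed, unit_sheet = collapse_technical_replicates(
        matrix, sheet, policy=design.technical_replicate_policy)
    fit = fit_group_model(collapsed, unit_sheet, design)
    if moderate and len(fit) >= 10 and (fit["s2"] > 0).sum() >= 10:
        res = moderated_t_test(fit)
    else:
        if moderate:
            warnings.warn("too few probes for variance moderation; using ordinary t")
        res = moderated_t_test(fit, d0=0.0)
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = np.where(res["effect"] > 0, "up", np.where(res["effect"] < 0, "down", "none"))
    if annotation is not None:
        gene_map = annotation.groupby("probe_id")["gene_symbol"].apply(lambda s: ";".join(s))
        res["gene_symbol"] = res.index.map(gene_map).fillna("")
    else:
        res["gene_symbol"] = res.index.astype(str)
    return res


def call_differential(results: pd.DataFrame, alpha: float = 0.05,
                      annotation: pd.DataFrame | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Probes with q < alpha, plus the unique mapped gene list.

    Direction is carried per probe; the gene list deduplicates symbols
    case-insensitively.
    """
    calls = results[results["q"] < alpha].copy()
    if annotation is None and "gene_symbol" in calls.columns:
        seen: dict[str, str] = {}
        for symbols in calls["gene_symbol"].astype(str):
            for sym in symbols.split(";"):
                if sym:
                    seen.setdefault(sym.upper(), sym)
        genes = sorted(seen.values())
    else:
        genes = probes_to_genes(calls.index, annotation)
    logger.info("called %d probes (%d genes) at q < %g", len(calls), len(genes), alpha)
    return calls, genes


def directional_gene_map(calls: pd.DataFrame, direction_labels: tuple[str, str] = ("up", "down"),
                         annotation: pd.DataFrame | None = None) -> dict[str, str]:
    """Map gene symbol -> direction from per-probe calls.

    Probe directions ("up"/"down" on the analysis scale) are relabelled with
    ``direction_labels`` — e.g. ("hyper", "hypo") for methylation. A gene
    whose probes disagree in direction is dropped (ambiguous).
    """
    relabel = {"up": direction_labels[0], "down": direction_labels[1]}
    per_gene: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for probe, row in calls.iterrows():
        if annotation is not None:
            sub = annotation[annotation["probe_id"] == str(probe)]["gene_symbol"]
            symbols = list(sub)
        else:
            symbols = [str(g) for g in str(row.get("gene_symbol", probe)).split(";") if g]
        d = relabel.get(row["direction"])
        if d is None:
            continue
        for sym in symbols:
            key = sym.strip().upper()
            per_gene.setdefault(key, set()).add(d)
            names.setdefault(key, sym.strip())
    return {names[k]: next(iter(v)) for k, v in per_gene.items() if len(v) == 1}
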