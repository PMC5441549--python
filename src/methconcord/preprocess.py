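"""Beta/M transforms, methylation-state binning, expression normalization,
replicate QC, PCA and outlier flagging.

Beta values (methylation fractions) are intuitive but heteroscedastic near 0
and 1, so all statistics downstream run on the M-value, the logit2 transform
M = log2(beta / (1 - beta)). Beta values of exactly 0 or 1 are clipped to
[epsilon, 1 - epsilon] before the transform so M stays finite.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: Methylation-state bin boundaries as fractions: >= HYPER_THRESHOLD is
#: "hyper", <= HYPO_THRESHOLD is "hypo", the open interval between is "mid".
HYPER_THRESHOLD = 0.70
HYPO_THRESHOLD = 0.30

STATE_ORDER = ("hypo", "mid", "hyper")


def _check_beta_range(beta: np.ndarray) -> None:
    finite = beta[np.isfinite(beta)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"beta outside [0,1]: range [{finite.min()}, {finite.max()}]")


def beta_to_m(beta, epsilon: float = 1e-3):
    """Convert methylation fraction(s) to M-values, M = log2(b/(1-b)).

    ``beta`` is clipped into [epsilon, 1-epsilon] first so that fully
    (un)methylated probes map to finite M. Strictly monotone in beta on the
    clipped range; ``m_to_beta`` inverts it there.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    arr = np.asarray(beta, dtype=float)
    _check_beta_range(arr)
    clipped = np.clip(arr, epsilon, 1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    # expit in base 2, written to avoid overflow for large |M|
    out = np.where(arr >= 0, 1.0 / (1.0 + np.exp2(-arr)),
                   np.exp2(np.minimum(arr, 0)) / (1.0 + np.exp2(np.minimum(arr, 0))))
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out)
    return out


def beta_matrix_to_m(beta: pd.DataFrame, epsilon: float = 1e-3) -> pd.DataFrame:
    """Apply :func:`beta_to_m` to a probe x sample beta matrix (NaN preserved)."""
    out = pd.DataFrame(beta_to_m(beta.to_numpy(), epsilon=epsilon),
                       index=beta.index, columns=beta.columns)
    out.attrs["epsilon"] = epsilon
    return out


def bin_methylation_state(beta):
    """Bin methylation fraction(s) into {hypo, mid, hyper}.

    hyper: beta >= 0.70; hypo: beta <= 0.30; mid: strictly between. The bins
    are exhaustive and exclusive on [0, 1]; boundary values belong to the
    extreme bins.
    """
    arr = np.asarray(beta, dtype=float)
    _check_beta_range(arr)
    if np.isnan(arr).any():
        raise ValueError("cannot bin missing beta values")
    states = np.where(arr >= HYPER_THRESHOLD, "hyper",
                      np.where(arr <= HYPO_THRESHOLD, "hypo", "mid"))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return str(states)
    return states


def normalize_expression(raw: pd.DataFrame, background_quantile: float | None = None,
                         floor: float = 1.0) -> pd.DataFrame:
    """Background-correct, quantile-normalize and log2 a raw fluorescence matrix.

    If ``background_quantile`` is given, that per-sample quantile is
    subtracted as a background offset; values are always floored at ``floor``
    (a small positive constant, so the log is defined). Quantile
    normalization then forces every sample onto the common distribution of
    row-wise means of the sorted columns, and values are log2-transformed.
    The matrix ``attrs`` record the processing state.
    """
    if raw.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if raw.attrs.get("normalization", "raw") != "raw":
        raise ValueError("matrix is already normalized")
    values = raw.to_numpy(dtype=float)
    if background_quantile is not None:
        values = values - np.nanquantile(values, background_quantile, axis=0)
    values = np.maximum(values, floor)
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    ncol = values.shape[1]
    for j in range(ncol):
        ranks[order[:, j], j] = np.arange(values.shape[0])
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    normalized = mean_sorted[ranks]
    out = pd.DataFrame(np.log2(normalized), index=raw.index, columns=raw.columns)
    out.attrs["normalization"] = "background+quantile+log2"
    return out


def replicate_correlation(matrix: pd.DataFrame, sheet) -> tuple[pd.DataFrame, dict]:
    """Pearson r^2 between every within-group pair of technical replicates.

    Returns a per-pair table (group key, sample pair, r2) and a summary dict
    with the mean/min/max over pairs — the QC check that consecutive passages
    of the same line agree.
    """
    rows = []
    for key, samples in sheet.replicate_groups().items():
        present = [s for s in samples if s in matrix.columns]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a = matrix[present[i]].to_numpy(dtype=float)
                b = matrix[present[j]].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                r = np.corrcoef(a[ok], b[ok])[0, 1]
                rows.append({"subject_id": key[0], "clone_id": key[1], "cell_type": key[2],
                             "sample_a": present[i], "sample_b": present[j], "r2": r * r})
    table = pd.DataFrame(rows, columns=["subject_id", "clone_id", "cell_type",
                                        "sample_a", "sample_b", "r2"])
    if len(table) == 0:
        warnings.warn("no technical-replicate groups with >= 2 samples; replicate QC is empty")
        summary = {"n_pairs": 0, "mean_r2": np.nan, "min_r2": np.nan, "max_r2": np.nan}
    else:
        summary = {"n_pairs": int(len(table)), "mean_r2": float(table["r2"].mean()),
                   "min_r2": float(table["r2"].min()), "max_r2": float(table["r2"].max())}
    return table, summary


def pca_scores(matrix: pd.DataFrame, n_components: int = 4) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores of a PCA on all probes (rows with missing values dropped).

    ``matrix`` is probe x sample; samples are the observations. Data are
    centered per probe across samples (no scaling), matching a covariance PCA
    on all detected probes. Returns (scores: sample x component DataFrame,
    variance-explained fractions).
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(matrix.shape):
        raise ValueError(f"n_components={n_components} exceeds min(matrix dims)={min(matrix.shape)}")
    clean = matrix.dropna(axis=0)
    dropped = matrix.shape[0] - clean.shape[0]
    if dropped:
        logger.info("PCA: dropped %d probes with missing values", dropped)
    X = clean.to_numpy(dtype=float).T  # samples x probes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=matrix.columns, columns=cols), pca.explained_variance_ratio_


def flag_outlier_samples(scores: pd.DataFrame, k_sd: float = 4.0,
                         components: tuple[str, str] = ("PC1", "PC2")) -> list[str]:
    """Flag samples far from the score centroid on the first two components.

    Distance is Euclidean over per-component robust z-scores (median/MAD with
    the 1.4826 normal-consistency factor). Samples with distance > ``k_sd``
    are flagged; they are never removed automatically — removal is an explicit
    caller choice. With fewer than 4 samples the flag set is empty (warned):
    a robust scale cannot be estimated.
    """
    if len(scores) < 4:
        warnings.warn("fewer than 4 samples: outlier flagging skipped")
        return []
    zs = []
    for comp in components:
        x = scores[comp].to_numpy(dtype=float)
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826
        dev = x - med
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(dev == 0, 0.0, dev / mad if mad > 0 else np.inf * np.sign(dev))
        zs.append(z)
    dist = np.sqrt(np.sum(np.square(zs), axis=0))
    flagged = scores.index[dist > k_sd]
    if len(flagged):
        logger.info("flagged %d outlier sample(s): %s", len(flagged), list(flagged))
    return list(flagged)


def detected_probes(detection_p: pd.DataFrame | None, probe_ids,
                    alpha: float = 0.01) -> pd.Index:
    """Probes detected on the array.

    A probe is detected if its detection p-value is below ``alpha`` in at
    least one sample; without a detection matrix every probe is treated as
    detected.
    """
    idx = pd.Index(probe_ids)
    if detection_p is None:
        return idx
    ok = (detection_p < alpha).any(axis=1)
    return idx.intersection(detection_p.index[ok])
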