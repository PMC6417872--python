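"""Transcriptome concordance after removal of infiltrate-driven genes.

Bulk tumor RNA mixes malignant cells with immune and stromal infiltrate;
xenografts carry essentially none of the human microenvironment. PCA on
the log-transformed matrix therefore separates tumors from PDXs along
components dominated by infiltrate genes. Removing the top 1% of genes by
absolute loading on each component strips that signal, after which
tumor-PDX Pearson correlation reflects tumor-intrinsic expression and
matched pairs should out-correlate unmatched ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from pdxfidelity.stats import rank_sum_test


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    explained_variance_ratio: np.ndarray


@dataclass
class LoadingFilter:
    per_component: dict[str, list[str]]
    removed: list[str]
    retained: list[str]


def _log_center(matrix: pd.DataFrame) -> pd.DataFrame:
    logged = np.log2(matrix + 1.0)
    return logged.sub(logged.mean(axis=1), axis=0)


def run_pca(
    matrix: pd.DataFrame,
    transform: str = "log2_center",
    n_components: int | None = None,
) -> PCAResult:
    """PCA over samples of a genes x samples matrix.

    Default transform log2(x+1) with gene centering; `transform="none"`
    uses the values as given (still gene-centered for the covariance).
    Components are deterministic up to sign; the sign is fixed by making
    each component's largest-magnitude gene loading positive.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    if transform == "log2_center":
        x = _log_center(matrix)
    elif transform == "none":
        x = matrix.sub(matrix.mean(axis=1), axis=0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    data = x.T.to_numpy(dtype=float)  # samples x genes
    if np.allclose(data, data[0]):
        raise ValueError("constant matrix: PCA undefined")
    k = n_components or (matrix.shape[1] - 1)
    k = min(k, matrix.shape[1] - 1, matrix.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(data)
    loadings = pca.components_.T  # genes x k
    for j in range(k):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def remove_top_loading_genes(
    matrix: pd.DataFrame,
    loadings: pd.DataFrame,
    fraction: float = 0.01,
) -> tuple[pd.DataFrame, LoadingFilter]:
    """Drop the top `fraction` of genes by |loading| on each component.

    Per component, the top ceil(fraction * n_genes) genes are collected;
    ties at the cutoff magnitude are all included (a deterministic
    superset); the union across components is removed from the matrix.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if not loadings.index.equals(matrix.index):
        loadings = loadings.reindex(matrix.index)
        if loadings.isna().any().any():
            raise ValueError("loadings do not cover the matrix's genes")
    n_top = math.ceil(fraction * matrix.shape[0])
    per_component: dict[str, list[str]] = {}
    removed: set[str] = set()
    for comp in loadings.columns:
        mag = loadings[comp].abs().sort_values(ascending=False, kind="mergesort")
        cutoff = mag.iloc[n_top - 1]
        top = mag[mag >= cutoff].index.tolist()
        per_component[comp] = top
        removed.update(top)
    retained = [g for g in matrix.index if g not in removed]
    if not retained:
        raise ValueError("loading filter removed every gene")
    filt = LoadingFilter(
        per_component=per_component,
        removed=sorted(removed),
        retained=retained,
    )
    return matrix.loc[retained], filt


def expression_correlation_matrix(
    matrix: pd.DataFrame,
    pair_map: dict[str, tuple[str, str]] | None = None,
    log_scale: bool = False,
) -> dict:
    """Pairwise sample Pearson correlations across retained genes.

    Defaults to the linear (FPKM-like) scale; `log_scale=True` correlates
    log2(x+1) values instead. Zero-variance samples get missing
    correlations with a warning. Matched pairs (from `pair_map`, patient
    -> (tumor, pdx)) are compared with all other off-diagonal pairs by
    the one-sided rank-sum test.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    vals = np.log2(matrix + 1.0) if log_scale else matrix
    sd = vals.std(axis=0, ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"zero-variance sample(s): {dead}; correlations set to missing")
    corr = vals.corr(method="pearson")  # pandas leaves NaN for zero variance
    corr.values[np.diag_indices_from(corr.values)] = 1.0

    matched, unmatched = [], []
    matched_pairs = set()
    if pair_map:
        for t, x in pair_map.values():
            matched_pairs.add(frozenset((t, x)))
    names = list(corr.columns)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr.iloc[i, j]
            if np.isnan(r):
                continue
            if frozenset((names[i], names[j])) in matched_pairs:
                matched.append(float(r))
            else:
                unmatched.append(float(r))
    p = rank_sum_test(np.array(matched), np.array(unmatched)) if matched and unmatched else None
    return {
        "matrix": corr,
        "matched": matched,
        "unmatched": unmatched,
        "p_value": p,
        "zero_variance_samples": dead,
    }
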