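"""Signature-based spatial deconvolution.

Signatures are per-group mean linear-scale (expm1 of log-normalised)
expression over the union of the per-group top-100 marker genes. Spot
weights are estimated by nonnegative least squares on the shared genes
and renormalised to the probability simplex; the raw weight sum and the
NNLS residual are kept for diagnostics. The upstream study used a
Poisson platform-effect model for this step; NNLS on linear means is this
package's declared solver and is pluggable via ``solver``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.optimize

from .markers import NormalizedMatrix, rank_markers, top_n_signature

__all__ = [
    "SignatureMatrix",
    "DeconvResult",
    "build_signature",
    "estimate_weights",
    "state_weights",
]

_MIN_SHARED_GENES = 10


@dataclass
class SignatureMatrix:
    """Signature genes x groups, linear-scale mean expression."""

    values: pd.DataFrame  # index: gene ids; columns: groups
    signatures: dict[str, list[str]]  # per-group top-n gene lists

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative signature values")
        if (self.values.to_numpy().max(axis=0) <= 0).any():
            raise ValueError("signature column with no positive entry")


@dataclass
class DeconvResult:
    weights: pd.DataFrame  # spots x groups, rows on the simplex
    raw_sum: pd.Series  # per-spot unnormalised NNLS weight total
    residual: pd.Series  # per-spot NNLS residual norm
    undetermined: pd.Series  # per-spot flag: all-zero raw solution


def build_signature(
    nm: NormalizedMatrix,
    groups,
    n: int = 100,
    min_pct: float = 0.25,
    logfc_min: float = 0.25,
) -> SignatureMatrix:
    """Top-``n`` marker signatures and their mean linear expression.

    Markers come from the one-vs-rest Wilcoxon screen (upregulated,
    log2FC >= ``logfc_min``, expressed in >= ``min_pct`` of in-group
    cells). A group with no passing marker raises, naming the group.
    """
    table = rank_markers(nm, groups, min_pct=min_pct, logfc_min=logfc_min, mode="marker")
    sigs = top_n_signature(table, n=n)
    group_names = [str(g) for g in pd.Series(groups).unique()]
    for g in group_names:
        if not sigs.get(g):
            raise ValueError(f"group {g!r} has no passing marker genes")
    union: list[str] = []
    seen = set()
    for g in group_names:
        for gene in sigs[g]:
            if gene not in seen:
                seen.add(gene)
                union.append(gene)
    linear = np.expm1(nm.values[nm.gene_index(union), :])
    labels = pd.Series(groups).reset_index(drop=True)
    cols = {
        g: linear[:, (labels == g).to_numpy()].mean(axis=1) for g in group_names
    }
    values = pd.DataFrame(cols, index=pd.Index(union, name="gene"))
    return SignatureMatrix(values, sigs)


def _nnls_solver(S: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    return scipy.optimize.nnls(S, x)


def estimate_weights(
    spots: NormalizedMatrix,
    S: SignatureMatrix,
    solver: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, float]] = _nnls_solver,
) -> DeconvResult:
    """Per-spot nonnegative weights over the signature groups.

    Spot expression is taken on the linear scale restricted to the genes
    shared with the signature (genes absent from the signature are
    dropped, never zero-filled). Rows whose raw solution is all zero are
    flagged undetermined and set uniform.
    """
    sig_genes = [g for g in S.values.index if g in set(spots.gene_ids)]
    if len(sig_genes) < _MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(sig_genes)} genes shared between spots and signature "
            f"(need >= {_MIN_SHARED_GENES})"
        )
    S_mat = S.values.loc[sig_genes].to_numpy()
    groups = list(S.values.columns)
    X = np.expm1(spots.values[spots.gene_index(sig_genes), :])
    n_spots = X.shape[1]
    W = np.zeros((n_spots, len(groups)))
    raw_sum = np.zeros(n_spots)
    residual = np.zeros(n_spots)
    undetermined = np.zeros(n_spots, dtype=bool)
    for j in range(n_spots):
        w, res = solver(S_mat, X[:, j])
        s = w.sum()
        raw_sum[j] = s
        residual[j] = res
        if s <= 0:
            undetermined[j] = True
            W[j] = 1.0 / len(groups)
        else:
            W[j] = w / s
    index = pd.Index(spots.column_ids, name="spot_id")
    return DeconvResult(
        weights=pd.DataFrame(W, index=index, columns=groups),
        raw_sum=pd.Series(raw_sum, index=index, name="raw_sum"),
        residual=pd.Series(residual, index=index, name="residual"),
        undetermined=pd.Series(undetermined, index=index, name="undetermined"),
    )


def state_weights(spots: NormalizedMatrix, S_states: SignatureMatrix) -> DeconvResult:
    """Deconvolution restricted to the luminal-epithelial lesion states
    (normal / hyperplasia / malignant); same contract as
    :func:`estimate_weights` with a state signature."""
    if len(S_states.values.columns) != 3:
        raise ValueError("state signature must have exactly three state columns")
    return estimate_weights(spots, S_states)
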