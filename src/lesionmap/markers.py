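"""Marker ranking, cluster annotation and control-bin module scoring.

Normalisation is the standard single-cell log transform
``ln(1 + 10,000 * count / column_total)``. Marker detection is a
one-vs-rest two-sided Wilcoxon rank-sum per gene with BH correction within
each group; log2 fold changes are computed on the linear (expm1) scale
with a 1e-9 pseudocount. Two screening modes are provided:

* ``marker`` — upregulated genes with log2FC >= 0.25 expressed in at least
  25% of the in-group cells (feeds the top-100 deconvolution signatures);
* ``state`` — the stricter lesion-state screen, p < 0.05 and log2FC > 1.5.

Module scoring follows the control-bin scheme popularised by Seurat's
AddModuleScore: genes are binned by mean expression, each set gene draws
control genes from its own bin, and the score is mean(set) - mean(control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix
from .stats import bh_adjust, rank_sum_matrix, rank_sum_test

__all__ = [
    "NormalizedMatrix",
    "normalize_counts",
    "rank_markers",
    "top_n_signature",
    "annotate_clusters",
    "module_score",
    "polarization_summary",
]

_EPS = 1e-9
_SCALE = 10_000.0


@dataclass
class NormalizedMatrix:
    """Log-normalised expression (genes x cells), dense."""

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError("shape does not match identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)


def normalize_counts(m: CountMatrix) -> NormalizedMatrix:
    """ln(1 + 10,000 * count / column_total); all-zero columns stay zero."""
    dense = m.to_dense().astype(float)
    totals = dense.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    values = np.log1p(_SCALE * dense / safe)
    return NormalizedMatrix(values, list(m.gene_ids), list(m.column_ids))


def _group_masks(column_ids, groups) -> dict[str, np.ndarray]:
    groups = pd.Series(groups)
    if len(groups) != len(column_ids):
        raise ValueError("group labels do not match column count")
    return {g: (groups == g).to_numpy() for g in groups.unique()}


def rank_markers(
    nm: NormalizedMatrix,
    groups,
    min_pct: float = 0.25,
    logfc_min: float = 0.25,
    mode: str = "marker",
    p_max: float = 0.05,
    state_logfc_min: float = 1.5,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table.

    Returns a DataFrame with columns group, gene, log2_fc, pct_in,
    pct_out, p_value, fdr_bh. In ``marker`` mode rows failing
    ``min_pct``/``logfc_min`` (upregulated only) are dropped; in ``state``
    mode the p < ``p_max`` and log2FC > ``state_logfc_min`` screen applies.
    BH adjustment is computed within each group over all genes before
    screening.
    """
    if mode not in ("marker", "state"):
        raise ValueError(f"unknown mode {mode!r}")
    masks = _group_masks(nm.column_ids, groups)
    if len(masks) < 2:
        raise ValueError("need at least two groups")
    for g, mask in masks.items():
        if mask.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 cells")
    linear = np.expm1(nm.values)
    detected = nm.values > 0
    out = []
    for g in masks:
        mask = masks[g]
        mean_in = linear[:, mask].mean(axis=1)
        mean_out = linear[:, ~mask].mean(axis=1)
        log2_fc = np.log2((mean_in + _EPS) / (mean_out + _EPS))
        pct_in = detected[:, mask].mean(axis=1)
        pct_out = detected[:, ~mask].mean(axis=1)
        p = rank_sum_matrix(nm.values, mask)
        fdr = bh_adjust(p)
        tab = pd.DataFrame(
            {
                "group": g,
                "gene": nm.gene_ids,
                "log2_fc": log2_fc,
                "pct_in": pct_in,
                "pct_out": pct_out,
                "p_value": p,
                "fdr_bh": fdr,
            }
        )
        if mode == "marker":
            tab = tab[(tab["pct_in"] >= min_pct) & (tab["log2_fc"] >= logfc_min)]
        else:
            tab = tab[(tab["p_value"] < p_max) & (tab["log2_fc"] > state_logfc_min)]
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def top_n_signature(marker_table: pd.DataFrame, n: int = 100) -> dict[str, list[str]]:
    """Per-group top-``n`` genes by descending log2FC (ties broken by
    ascending p-value, then gene id)."""
    result: dict[str, list[str]] = {}
    if marker_table.empty:
        warnings.warn("empty marker table; returning no signatures")
        return result
    for g, sub in marker_table.groupby("group", sort=False):
        ordered = sub.sort_values(
            ["log2_fc", "p_value", "gene"], ascending=[False, True, True], kind="mergesort"
        )
        genes = ordered["gene"].tolist()
        if len(genes) < n:
            warnings.warn(f"group {g!r}: only {len(genes)} genes pass filters (< {n})")
        result[str(g)] = genes[:n]
    return result


def annotate_clusters(
    nm: NormalizedMatrix,
    cluster_labels,
    marker_dict: dict[str, list[str]],
    min_markers: int = 3,
    detect_frac: float = 0.5,
    mean_min: float = 1.0,
    high_expression: bool = True,
) -> dict[str, str]:
    """Assign each cluster the cell type with >= ``min_markers`` qualifying
    markers.

    A marker qualifies when it is detected in more than ``detect_frac`` of
    the cluster's cells and its mean normalised expression is >= ``mean_min``
    (or < ``mean_min`` when ``high_expression`` is False, honouring the
    literal low-expression reading as an option). Ties on the qualifying
    count give "ambiguous"; no qualifying type gives "unassigned".
    """
    masks = _group_masks(nm.column_ids, cluster_labels)
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    assignment: dict[str, str] = {}
    for cl, mask in masks.items():
        if mask.sum() == 0:
            raise ValueError(f"cluster {cl!r} is empty")
        sub = nm.values[:, mask]
        counts: dict[str, int] = {}
        for ctype, genes in marker_dict.items():
            n_qual = 0
            for g in genes:
                if g not in gene_pos:
                    warnings.warn(f"marker {g!r} absent from matrix; skipped")
                    continue
                row = sub[gene_pos[g]]
                detected = (row > 0).mean() > detect_frac
                mean_ok = (
                    row.mean() >= mean_min if high_expression else row.mean() < mean_min
                )
                if detected and mean_ok:
                    n_qual += 1
            counts[ctype] = n_qual
        qualifying = {t: c for t, c in counts.items() if c >= min_markers}
        if not qualifying:
            assignment[str(cl)] = "unassigned"
        else:
            best = max(qualifying.values())
            winners = [t for t, c in qualifying.items() if c == best]
            assignment[str(cl)] = winners[0] if len(winners) == 1 else "ambiguous"
    return assignment


def module_score(
    nm: NormalizedMatrix,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell gene-set score: mean(set expression) - mean(control).

    Genes are ranked by mean expression across cells and split into
    ``n_bins`` equal-frequency bins; each set gene draws ``n_ctrl`` control
    genes uniformly from its bin (set genes excluded from control pools;
    sampling with replacement when the pool is smaller than ``n_ctrl``).
    """
    gene_set = [g for g in gene_set]
    present = [g for g in gene_set if g in set(nm.gene_ids)]
    if not gene_set:
        raise ValueError("empty gene set")
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if len(present) < len(gene_set):
        warnings.warn(f"{len(gene_set) - len(present)} set gene(s) absent; skipped")
    rng = np.random.default_rng(seed)
    avg = nm.values.mean(axis=1)
    order = np.argsort(avg, kind="mergesort")
    n_genes = len(avg)
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.floor(np.arange(n_genes) * n_bins / n_genes).astype(int)
    # canonical (row-index) order so the score is invariant to the order
    # in which the set lists its genes
    set_idx = np.unique(nm.gene_index(present))
    set_mask = np.zeros(n_genes, dtype=bool)
    set_mask[set_idx] = True
    ctrl_rows: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~set_mask)
        if pool.size == 0:
            continue
        replace = pool.size < n_ctrl
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=replace))
    if not ctrl_rows:
        raise ValueError("no control genes available")
    ctrl_idx = np.concatenate(ctrl_rows)
    return nm.values[set_idx].mean(axis=0) - nm.values[ctrl_idx].mean(axis=0)


def polarization_summary(
    scores_m1: np.ndarray,
    scores_m2: np.ndarray,
    groups,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group M1/M2/(M1-M2) means and pairwise Wilcoxon tests on M1-M2.

    Returns (summary table indexed by group, pairwise table with BH-adjusted
    p-values). Groups of fewer than 2 cells are rejected.
    """
    scores_m1 = np.asarray(scores_m1, dtype=float)
    scores_m2 = np.asarray(scores_m2, dtype=float)
    if scores_m1.shape != scores_m2.shape:
        raise ValueError("M1 and M2 scores are on different cell sets")
    groups = pd.Series(groups).reset_index(drop=True)
    if len(groups) != len(scores_m1):
        raise ValueError("group labels do not match score length")
    diff = scores_m1 - scores_m2
    names = list(groups.unique())
    rows = []
    for g in names:
        mask = (groups == g).to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "m1": scores_m1[mask].mean(),
                "m2": scores_m2[mask].mean(),
                "m1_minus_m2": diff[mask].mean(),
                "median_m1_minus_m2": float(np.median(diff[mask])),
            }
        )
    summary = pd.DataFrame(rows).set_index("group")
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa = diff[(groups == a).to_numpy()]
            pb = diff[(groups == b).to_numpy()]
            pairs.append({"group_a": a, "group_b": b, "p_value": rank_sum_test(pa, pb)})
    pairwise = pd.DataFrame(pairs, columns=["group_a", "group_b", "p_value"])
    if not pairwise.empty:
        pairwise["fdr_bh"] = bh_adjust(pairwise["p_value"].to_numpy())
    return summary, pairwise
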