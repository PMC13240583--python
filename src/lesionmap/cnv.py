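"""Expression-inferred copy-number analysis along ordered chromosomes.

The profile mirrors the usual expression-CNV recipe: order genes by
(chromosome, start), centre every gene on the reference-cell mean, smooth
with a moving average within each chromosome (window truncated at the
ends), and re-centre every cell by its own median smoothed value so that
genome-wide library shifts (e.g. a large amplified segment inflating the
denominator of the normalisation) do not masquerade as whole-genome loss.

Event calling is the reference Z-score rule: per gene, Z-scores of target
cells against the reference mean/SD of the smoothed values; a gene is
amplified (deleted) in a group when strictly more than half of the group's
cells have Z > +1 (Z < -1). Strict majorities make the amplified and
deleted sets provably disjoint. Shared events between two groups are the
same-direction intersection; opposite-direction double calls are flagged
discordant and count as unique to each group.

The lineage tree is Ward.D2 agglomeration (scipy's ``ward`` linkage, which
matches R ``hclust(d, "ward.D2")`` on Euclidean distances) over
per-subcluster mean profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .io_formats import GeneTable, linkage_to_newick
from .markers import NormalizedMatrix

__all__ = [
    "CnvProfile",
    "CnvCallSet",
    "SharedPartition",
    "LineageTree",
    "cnv_profile",
    "call_cnv",
    "partition_shared",
    "cnv_tree",
    "rf_distance",
]


@dataclass
class CnvProfile:
    """Smoothed, reference-centred profile: genes (genomic order) x cells."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    reference_cells: list[str]
    window: int

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise ValueError(f"cell(s) absent from profile: {missing[:5]}")
        return np.array([lookup[c] for c in cells], dtype=int)


@dataclass
class CnvCallSet:
    group: str
    amplified: set[str]
    deleted: set[str]
    fraction_above: pd.Series  # per gene, fraction of cells with Z > +1
    fraction_below: pd.Series  # per gene, fraction of cells with Z < -1


@dataclass
class SharedPartition:
    shared_amplified: set[str]
    shared_deleted: set[str]
    unique_to_a: set[str]
    unique_to_b: set[str]
    discordant: set[str] = field(default_factory=set)


@dataclass
class LineageTree:
    linkage: np.ndarray
    labels: list[str]
    newick: str
    leaf_metadata: pd.DataFrame | None = None


def _moving_average_truncated(block: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 0 with truncation at the edges:
    position i averages rows max(0, i-h)..min(n, i+h+1), h = (window-1)/2."""
    n = block.shape[0]
    h = (window - 1) // 2
    csum = np.cumsum(block, axis=0)
    csum = np.vstack([np.zeros((1, block.shape[1])), csum])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    sums = csum[hi] - csum[lo]
    return sums / (hi - lo)[:, None]


def cnv_profile(
    nm: NormalizedMatrix,
    ann: GeneTable,
    reference_cells,
    window: int = 51,
    recenter_cells: bool = True,
    min_reference: int = 20,
) -> CnvProfile:
    """Build the smoothed reference-centred CNV profile.

    Genes are re-ordered genomically regardless of input order; output
    rows follow (chromosome, start). Chromosomes shorter than ``window``
    simply truncate the window (no error).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    reference_cells = [str(c) for c in reference_cells]
    if len(reference_cells) < min_reference:
        raise ValueError(
            f"need >= {min_reference} reference cells, got {len(reference_cells)}"
        )
    ann.require(nm.gene_ids)
    order = ann.genomic_order(nm.gene_ids)
    values = nm.values[nm.gene_index(order), :]
    col_lookup = {c: i for i, c in enumerate(nm.column_ids)}
    missing = [c for c in reference_cells if c not in col_lookup]
    if missing:
        raise ValueError(f"reference cell(s) absent from matrix: {missing[:5]}")
    ref_idx = [col_lookup[c] for c in reference_cells]
    centred = values - values[:, ref_idx].mean(axis=1, keepdims=True)
    chroms = ann.df.loc[order, "chromosome"].to_numpy()
    smoothed = np.empty_like(centred)
    start = 0
    while start < len(order):
        end = start
        while end < len(order) and chroms[end] == chroms[start]:
            end += 1
        smoothed[start:end] = _moving_average_truncated(centred[start:end], window)
        start = end
    if recenter_cells:
        smoothed = smoothed - np.median(smoothed, axis=0, keepdims=True)
    return CnvProfile(smoothed, order, list(nm.column_ids), reference_cells, window)


def call_cnv(
    profile: CnvProfile,
    target_groups: dict[str, list[str]],
    z_threshold: float = 1.0,
    majority: float = 0.5,
    sd_floor: float = 0.01,
) -> dict[str, CnvCallSet]:
    """Reference Z-score event calling per target group.

    Per gene, mean and SD come from the reference cells' smoothed values
    (SD floored at ``sd_floor``); a gene is amplified in a group when the
    fraction of its cells with Z > ``z_threshold`` strictly exceeds
    ``majority`` (deleted analogously with Z < -``z_threshold``).
    """
    ref = profile.values[:, profile.cell_index(profile.reference_cells)]
    mu = ref.mean(axis=1)
    sd = np.maximum(ref.std(axis=1, ddof=1), sd_floor)
    genes = pd.Index(profile.gene_ids, name="gene")
    out: dict[str, CnvCallSet] = {}
    for name, cells in target_groups.items():
        cells = [str(c) for c in cells]
        if len(cells) == 0:
            raise ValueError(f"target group {name!r} has no cells")
        overlap = set(cells) & set(profile.reference_cells)
        if overlap:
            raise ValueError(
                f"target group {name!r} overlaps the reference ({len(overlap)} cells)"
            )
        z = (profile.values[:, profile.cell_index(cells)] - mu[:, None]) / sd[:, None]
        frac_above = pd.Series((z > z_threshold).mean(axis=1), index=genes)
        frac_below = pd.Series((z < -z_threshold).mean(axis=1), index=genes)
        amplified = set(genes[frac_above > majority])
        deleted = set(genes[frac_below > majority])
        out[name] = CnvCallSet(name, amplified, deleted, frac_above, frac_below)
    return out


def partition_shared(calls_a: CnvCallSet, calls_b: CnvCallSet) -> SharedPartition:
    """Same-direction intersection of two call sets, with symmetric
    differences as unique events; opposite-direction double calls are
    flagged discordant and kept unique to each group."""
    shared_amp = calls_a.amplified & calls_b.amplified
    shared_del = calls_a.deleted & calls_b.deleted
    discordant = (calls_a.amplified & calls_b.deleted) | (
        calls_a.deleted & calls_b.amplified
    )
    all_a = calls_a.amplified | calls_a.deleted
    all_b = calls_b.amplified | calls_b.deleted
    shared = shared_amp | shared_del
    return SharedPartition(
        shared_amplified=shared_amp,
        shared_deleted=shared_del,
        unique_to_a=all_a - shared,
        unique_to_b=all_b - shared,
        discordant=discordant,
    )


def cnv_tree(
    profile: CnvProfile,
    subcluster_labels,
    min_cells: int = 3,
    state_labels=None,
) -> LineageTree:
    """Ward.D2 dendrogram over per-subcluster mean CNV profiles.

    Subclusters with fewer than ``min_cells`` cells are pooled into a
    single "small" leaf (with a warning). ``state_labels`` (per cell)
    optionally populates the leaf-metadata table with state composition
    fractions per leaf.
    """
    labels = pd.Series([str(l) for l in subcluster_labels])
    if len(labels) != len(profile.cell_ids):
        raise ValueError("subcluster labels do not match profile cells")
    sizes = labels.value_counts()
    small = set(sizes[sizes < min_cells].index)
    if small:
        warnings.warn(f"subcluster(s) {sorted(small)} have < {min_cells} cells; pooled")
        labels = labels.where(~labels.isin(small), "small")
    leaf_names = sorted(labels.unique())
    if len(leaf_names) < 2:
        raise ValueError("need at least two subclusters")
    means = np.vstack(
        [profile.values[:, (labels == l).to_numpy()].mean(axis=1) for l in leaf_names]
    )
    Z = linkage(means, method="ward")
    nwk = linkage_to_newick(Z, leaf_names)
    meta = None
    if state_labels is not None:
        states = pd.Series([str(s) for s in state_labels])
        comp = (
            pd.crosstab(labels, states, normalize="index")
            .reindex(leaf_names)
            .fillna(0.0)
        )
        comp.index.name = "leaf"
        meta = comp
    return LineageTree(Z, leaf_names, nwk, meta)


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds distance between two Newick trees sharing
    a leaf set."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
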