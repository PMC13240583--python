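"""Synthetic single-cell and spatial datasets with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* negative-binomial UMI counts per cell, with heavy-tailed (log-normal)
  base gene means, log-normal library sizes and a fixed inverse-dispersion
  ``theta`` (variance ``m + m^2/theta``);
* cell types defined by marker programs (multiplicative fold changes on
  disjoint gene sets) and luminal-epithelial lesion states
  (normal / hyperplasia / malignant) defined by state programs;
* copy-number segments as contiguous dosage multipliers along ordered
  chromosomes, some carried by both hyperplastic and malignant cells
  (shared) and some by a single state (unique);
* mitochondrial and hemoglobin genes receiving a Beta-distributed share of
  each cell's library, so QC thresholds have known violators, plus
  explicitly planted violator cells (tiny libraries, high mito/HB shares);
* spatial spots as weighted mixtures of cell-type expression profiles,
  arranged as lesion nodules with rims, a stromal background and linear
  gradient strips ramping hyperplastic into malignant signal.

Every downstream truth (type, state, segment carriage, spot weights,
planted violations) is emitted in the truth tables; all randomness flows
from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, GeneTable, write_counts_10x, write_gene_table

__all__ = [
    "CellTypeSpec",
    "CnvSegment",
    "Nodule",
    "GradientStrip",
    "NoduleLayout",
    "SimulationConfig",
    "build_gene_table",
    "expected_relative_expression",
    "type_profiles",
    "simulate_cells",
    "simulate_spots",
    "sample_spots",
    "make_config",
    "default_fixture",
]

LE_STATES = ("normal", "hyperplasia", "malignant")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CellTypeSpec:
    name: str
    n_cells: int
    markers: dict[str, float] = field(default_factory=dict)
    state_program: dict[str, float] = field(default_factory=dict)
    state: str | None = None  # one of LE_STATES for luminal epithelium

    def __post_init__(self) -> None:
        for fold in list(self.markers.values()) + list(self.state_program.values()):
            if fold <= 0:
                raise ValueError("fold changes must be positive")


@dataclass
class CnvSegment:
    name: str
    chromosome: str
    first_index: int  # within-chromosome gene index, inclusive
    last_index: int  # inclusive
    dosage: float
    carriers: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.last_index < self.first_index:
            raise ValueError("empty gene span")
        if self.dosage == 1 or self.dosage <= 0:
            raise ValueError("dosage must be positive and != 1")
        if not self.carriers:
            raise ValueError("carriers must be nonempty")


@dataclass
class Nodule:
    center: tuple[int, int]
    radius: float
    interior: dict[str, float]
    rim: dict[str, float]
    interior_fraction: float = 0.6  # fraction of the radius that is interior


@dataclass
class GradientStrip:
    rows: tuple[int, int]  # half-open row range
    cols: tuple[int, int]  # half-open column range; ramp runs along columns
    start_mixture: dict[str, float]
    end_mixture: dict[str, float]


@dataclass
class NoduleLayout:
    grid: tuple[int, int]
    background: dict[str, float]
    nodules: list[Nodule] = field(default_factory=list)
    gradient_strips: list[GradientStrip] = field(default_factory=list)


@dataclass
class SimulationConfig:
    chromosomes: list[tuple[str, int]]
    cell_types: list[CellTypeSpec]
    cnv_segments: list[CnvSegment] = field(default_factory=list)
    spot_layout: NoduleLayout | None = None
    nb_dispersion: float = 10.0  # inverse dispersion theta
    library_size_lognormal: tuple[float, float] = (np.log(4000.0), 0.35)
    spot_library_lognormal: tuple[float, float] = (np.log(8000.0), 0.3)
    mito_fraction_beta: tuple[float, float] = (2.0, 38.0)  # mean 5%
    hb_fraction_beta: tuple[float, float] = (1.0, 99.0)  # mean 1%
    n_hb_genes: int = 8
    frac_low_library: float = 0.03
    frac_high_mito: float = 0.03
    frac_high_hb: float = 0.02
    # fixed base weights for selected genes (marker programs): markers must
    # be lowly expressed outside their own type for the detection-based
    # annotation rule to discriminate, which the heavy-tailed random base
    # means do not guarantee on a scaled-down gene universe
    base_overrides: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["chromosomes"] = [tuple(c) for c in raw["chromosomes"]]
        raw["cell_types"] = [CellTypeSpec(**c) for c in raw["cell_types"]]
        raw["cnv_segments"] = [
            CnvSegment(**{**s, "carriers": tuple(s["carriers"])})
            for s in raw["cnv_segments"]
        ]
        if raw.get("spot_layout") is not None:
            lay = raw["spot_layout"]
            raw["spot_layout"] = NoduleLayout(
                grid=tuple(lay["grid"]),
                background=lay["background"],
                nodules=[
                    Nodule(**{**n, "center": tuple(n["center"])})
                    for n in lay["nodules"]
                ],
                gradient_strips=[
                    GradientStrip(
                        rows=tuple(s["rows"]),
                        cols=tuple(s["cols"]),
                        start_mixture=s["start_mixture"],
                        end_mixture=s["end_mixture"],
                    )
                    for s in lay["gradient_strips"]
                ],
            )
        for key in ("library_size_lognormal", "spot_library_lognormal",
                    "mito_fraction_beta", "hb_fraction_beta"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

def build_gene_table(cfg: SimulationConfig) -> GeneTable:
    """Gene ids G0000... laid out sequentially along the configured
    chromosomes; chrM genes are mitochondrial, the last ``n_hb_genes``
    genes of the last autosome are hemoglobin."""
    rows = []
    gi = 0
    autosomes = [c for c, _ in cfg.chromosomes if c != "chrM"]
    last_autosome = autosomes[-1] if autosomes else None
    hb_ids: set[int] = set()
    if last_autosome is not None and cfg.n_hb_genes > 0:
        offset = 0
        for chrom, n in cfg.chromosomes:
            if chrom == last_autosome:
                hb_ids = set(range(offset + n - cfg.n_hb_genes, offset + n))
                break
            offset += n
    for chrom, n in cfg.chromosomes:
        for j in range(n):
            rows.append(
                {
                    "gene_id": f"G{gi:05d}",
                    "chromosome": chrom,
                    "start": j * 1000,
                    "end": j * 1000 + 500,
                    "is_mito": chrom == "chrM",
                    "is_hb": gi in hb_ids,
                }
            )
            gi += 1
    df = pd.DataFrame(rows).set_index("gene_id")
    order = [c for c, _ in cfg.chromosomes]
    return GeneTable(df, chrom_order=order)


def _base_means(cfg: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, 7])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    if cfg.base_overrides:
        # gene ids are positional (G00000...), so the index is the number
        for g, w in cfg.base_overrides.items():
            base[int(g[1:])] = w
    return base


def _segment_gene_ids(cfg: SimulationConfig, ann: GeneTable) -> dict[str, list[str]]:
    by_chrom: dict[str, list[str]] = {}
    for g, row in ann.df.iterrows():
        by_chrom.setdefault(row["chromosome"], []).append(g)
    out = {}
    for seg in cfg.cnv_segments:
        genes = by_chrom.get(seg.chromosome, [])
        if seg.last_index >= len(genes):
            raise ValueError(f"segment {seg.name} exceeds {seg.chromosome}")
        out[seg.name] = genes[seg.first_index : seg.last_index + 1]
    return out


def expected_relative_expression(
    cfg: SimulationConfig, spec: CellTypeSpec, ann: GeneTable
) -> np.ndarray:
    """Relative expression of one cell type before mito/HB partitioning:
    base mean x marker fold x state fold x CNV dosage, unnormalised."""
    base = _base_means(cfg).copy()
    pos = {g: i for i, g in enumerate(ann.gene_ids)}
    for g, fold in spec.markers.items():
        base[pos[g]] *= fold
    for g, fold in spec.state_program.items():
        base[pos[g]] *= fold
    seg_genes = _segment_gene_ids(cfg, ann)
    for seg in cfg.cnv_segments:
        if spec.name in seg.carriers:
            for g in seg_genes[seg.name]:
                base[pos[g]] *= seg.dosage
    return base


def _partition_masks(ann: GeneTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mito = ann.df["is_mito"].to_numpy()
    hb = ann.df["is_hb"].to_numpy()
    return ~mito & ~hb, mito, hb


def _mean_counts(
    rel: np.ndarray,
    masks: tuple[np.ndarray, np.ndarray, np.ndarray],
    library: float,
    mito_frac: float,
    hb_frac: float,
) -> np.ndarray:
    nuclear, mito, hb = masks
    mean = np.zeros_like(rel)
    for mask, share in ((nuclear, 1.0 - mito_frac - hb_frac), (mito, mito_frac), (hb, hb_frac)):
        tot = rel[mask].sum()
        if mask.any() and tot > 0:
            mean[mask] = rel[mask] / tot * share * library
    return mean


def type_profiles(cfg: SimulationConfig, ann: GeneTable) -> pd.DataFrame:
    """Noise-free per-type expected expression profiles (genes x types),
    each column summing to 1; used as the mixing basis for spots."""
    masks = _partition_masks(ann)
    m_bar = cfg.mito_fraction_beta[0] / sum(cfg.mito_fraction_beta)
    h_bar = cfg.hb_fraction_beta[0] / sum(cfg.hb_fraction_beta)
    cols = {}
    for spec in cfg.cell_types:
        rel = expected_relative_expression(cfg, spec, ann)
        cols[spec.name] = _mean_counts(rel, masks, 1.0, m_bar, h_bar)
    return pd.DataFrame(cols, index=pd.Index(ann.gene_ids, name="gene"))


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_cells(cfg: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Sample the cell count matrix and its ground-truth table."""
    if not cfg.cell_types:
        raise ValueError("cell type list is empty")
    ann = build_gene_table(cfg)
    masks = _partition_masks(ann)
    rng = np.random.default_rng([cfg.seed, 0])
    mu, sigma = cfg.library_size_lognormal
    a_m, b_m = cfg.mito_fraction_beta
    a_h, b_h = cfg.hb_fraction_beta
    seg_by_type: dict[str, list[str]] = {}
    for seg in cfg.cnv_segments:
        for t in seg.carriers:
            seg_by_type.setdefault(t, []).append(seg.name)
    columns = []
    truth_rows = []
    ci = 0
    for spec in cfg.cell_types:
        rel = expected_relative_expression(cfg, spec, ann)
        for _ in range(spec.n_cells):
            cell_id = f"C{ci:05d}"
            ci += 1
            library = rng.lognormal(mu, sigma)
            mito_frac = rng.beta(a_m, b_m)
            hb_frac = rng.beta(a_h, b_h)
            u = rng.random()
            violation = "none"
            if u < cfg.frac_low_library:
                violation = "low_library"
                library *= 0.06
            elif u < cfg.frac_low_library + cfg.frac_high_mito:
                violation = "high_mito"
                mito_frac = rng.beta(25, 75)  # mean 25%
            elif u < cfg.frac_low_library + cfg.frac_high_mito + cfg.frac_high_hb:
                violation = "high_hb"
                hb_frac = rng.beta(10, 90)  # mean 10%
            mean = _mean_counts(rel, masks, library, mito_frac, hb_frac)
            columns.append(_nb_sample(rng, mean, cfg.nb_dispersion))
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "cell_type": spec.name,
                    "state": spec.state or "none",
                    "segments": ";".join(seg_by_type.get(spec.name, [])) or "none",
                    "violation": violation,
                    "library_size": library,
                    "mito_fraction": mito_frac,
                    "hb_fraction": hb_frac,
                }
            )
    counts = sp.csr_matrix(np.column_stack(columns).astype(np.int64))
    matrix = CountMatrix(counts, ann.gene_ids, [r["cell_id"] for r in truth_rows])
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return matrix, truth


# ---------------------------------------------------------------------------
# spots
# ---------------------------------------------------------------------------

def _validate_mixture(mix: dict[str, float], types: set[str], where: str) -> None:
    if not mix:
        raise ValueError(f"{where}: empty mixture")
    unknown = set(mix) - types
    if unknown:
        raise ValueError(f"{where}: unknown cell type(s) {sorted(unknown)}")
    vals = np.array(list(mix.values()), dtype=float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-8:
        raise ValueError(f"{where}: mixture is off the probability simplex")


def layout_weights(layout: NoduleLayout, types: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a nodule layout into per-spot weights and coordinates.

    Later layers override earlier ones: background < nodule rim < nodule
    interior < gradient strip. Returns (weights spots x types, coords with
    row/col/region).
    """
    tset = set(types)
    _validate_mixture(layout.background, tset, "background")
    for i, nod in enumerate(layout.nodules):
        _validate_mixture(nod.interior, tset, f"nodule {i} interior")
        _validate_mixture(nod.rim, tset, f"nodule {i} rim")
    for i, strip in enumerate(layout.gradient_strips):
        _validate_mixture(strip.start_mixture, tset, f"strip {i} start")
        _validate_mixture(strip.end_mixture, tset, f"strip {i} end")
    n_rows, n_cols = layout.grid
    records = []
    weight_rows = []
    si = 0
    for r in range(n_rows):
        for c in range(n_cols):
            mix = dict(layout.background)
            region = "background"
            for i, nod in enumerate(layout.nodules):
                d = np.hypot(r - nod.center[0], c - nod.center[1])
                if d <= nod.radius * nod.interior_fraction:
                    mix, region = dict(nod.interior), f"nodule{i}_interior"
                elif d <= nod.radius:
                    mix, region = dict(nod.rim), f"nodule{i}_rim"
            for i, strip in enumerate(layout.gradient_strips):
                r0, r1 = strip.rows
                c0, c1 = strip.cols
                if r0 <= r < r1 and c0 <= c < c1:
                    t = (c - c0) / max(c1 - 1 - c0, 1)
                    mix = {
                        ty: (1 - t) * strip.start_mixture.get(ty, 0.0)
                        + t * strip.end_mixture.get(ty, 0.0)
                        for ty in tset
                    }
                    region = f"strip{i}"
            w = np.array([mix.get(t, 0.0) for t in types])
            weight_rows.append(w)
            records.append({"spot_id": f"S{si:05d}", "row": r, "col": c, "region": region})
            si += 1
    coords = pd.DataFrame(records).set_index("spot_id")
    weights = pd.DataFrame(weight_rows, index=coords.index, columns=types)
    return weights, coords


def sample_spots(
    profiles: pd.DataFrame,
    weights: pd.DataFrame,
    libraries: np.ndarray,
    theta: float,
    rng: np.random.Generator,
    spot_ids: list[str] | None = None,
) -> CountMatrix:
    """NB-sample spot counts: mean = library * sum_t w_t * profile_t."""
    W = weights.to_numpy(dtype=float)
    if (W < 0).any() or (np.abs(W.sum(axis=1) - 1.0) > 1e-6).any():
        raise ValueError("spot weights are off the probability simplex")
    P = profiles[weights.columns].to_numpy()
    means = (P @ W.T) * np.asarray(libraries)[None, :]
    counts = np.column_stack(
        [_nb_sample(rng, means[:, j], theta) for j in range(means.shape[1])]
    )
    ids = spot_ids if spot_ids is not None else list(weights.index)
    return CountMatrix(
        sp.csr_matrix(counts.astype(np.int64)), list(profiles.index), ids
    )


def simulate_spots(
    cfg: SimulationConfig, profiles: pd.DataFrame | None = None
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Sample the spatial count matrix, truth table and coordinates."""
    if cfg.spot_layout is None:
        raise ValueError("config has no spot layout")
    ann = build_gene_table(cfg)
    if profiles is None:
        profiles = type_profiles(cfg, ann)
    types = [s.name for s in cfg.cell_types]
    weights, coords = layout_weights(cfg.spot_layout, types)
    rng = np.random.default_rng([cfg.seed, 1])
    mu, sigma = cfg.spot_library_lognormal
    n_spots = len(weights)
    libraries = rng.lognormal(mu, sigma, size=n_spots)
    violation = np.full(n_spots, "none", dtype=object)
    u = rng.random(n_spots)
    low = u < cfg.frac_low_library
    libraries[low] *= 0.05
    violation[low] = "low_library"
    high = (~low) & (u < cfg.frac_low_library + cfg.frac_high_mito)
    violation[high] = "high_mito"
    prof = profiles.copy()
    mito_mask = ann.df["is_mito"].to_numpy()
    counts_cols = []
    for j in range(n_spots):
        p = prof.to_numpy() @ weights.to_numpy()[j]
        if violation[j] == "high_mito":
            # re-allocate a quarter of the library to mitochondrial genes
            p = p.copy()
            mito_base = p[mito_mask].sum()
            p[~mito_mask] *= 0.75 / max(1.0 - mito_base, 1e-9)
            p[mito_mask] *= 0.25 / max(mito_base, 1e-9)
        counts_cols.append(_nb_sample(rng, p * libraries[j], cfg.nb_dispersion))
    matrix = CountMatrix(
        sp.csr_matrix(np.column_stack(counts_cols).astype(np.int64)),
        list(profiles.index),
        list(weights.index),
    )
    truth = coords.join(weights)
    truth["violation"] = violation
    truth["library_size"] = libraries
    return matrix, truth, coords[["row", "col"]]


# ---------------------------------------------------------------------------
# default fixtures
# ---------------------------------------------------------------------------

def _draw_disjoint_sets(
    rng: np.random.Generator, pool: list[str], sizes: dict[str, int]
) -> dict[str, list[str]]:
    chosen = rng.choice(len(pool), size=sum(sizes.values()), replace=False)
    out = {}
    at = 0
    for name, k in sizes.items():
        out[name] = sorted(pool[i] for i in chosen[at : at + k])
        at += k
    return out


def make_config(scale: str = "desk", seed: int = 0, with_spots: bool = True) -> SimulationConfig:
    """Build the standard fixture configuration at ``tiny`` or ``desk``
    scale. The desk fixture carries two shared and two state-unique CNV
    segments; the tiny fixture is a fast smoke-scale version of the same
    design."""
    if scale == "desk":
        n_per_chrom, n_chrom = 330, 6
        seg_span, seg_lo = 80, 100
        n_marker, n_program, n_pol = 60, 30, 20
        counts = {
            "LE_normal": 400, "LE_hyperplasia": 400, "LE_malignant": 400,
            "BE": 200, "T_CD4": 200, "T_CD8": 150, "Macro_M1": 150,
            "Macro_M2": 150, "Mono": 100, "NK": 100, "B": 100, "Endo": 100,
        }
        grid, radius = (30, 30), 5.0
        lib = (float(np.log(4000.0)), 0.35)
        spot_lib = (float(np.log(8000.0)), 0.3)
        window_hint = 51  # documented default used downstream
    elif scale == "tiny":
        n_per_chrom, n_chrom = 80, 4
        seg_span, seg_lo = 20, 25
        n_marker, n_program, n_pol = 16, 12, 10
        counts = {
            "LE_normal": 50, "LE_hyperplasia": 40, "LE_malignant": 40,
            "BE": 25, "T_CD4": 25, "T_CD8": 20, "Macro_M1": 20,
            "Macro_M2": 20, "Mono": 15, "NK": 15, "B": 15, "Endo": 15,
        }
        grid, radius = (10, 10), 2.5
        lib = (float(np.log(2000.0)), 0.35)
        spot_lib = (float(np.log(4000.0)), 0.3)
        window_hint = 11
    else:
        raise ValueError(f"unknown scale {scale!r} (use 'tiny' or 'desk')")
    del window_hint
    chromosomes = [(f"chr{i + 1}", n_per_chrom) for i in range(n_chrom)] + [
        ("chrM", 12 if scale == "desk" else 8)
    ]
    n_hb = 8 if scale == "desk" else 4
    base_cfg = SimulationConfig(
        chromosomes=chromosomes,
        cell_types=[],
        n_hb_genes=n_hb,
        library_size_lognormal=lib,
        spot_library_lognormal=spot_lib,
        seed=seed,
    )
    ann = build_gene_table(base_cfg)
    eligible = [
        g
        for g, row in ann.df.iterrows()
        if not row["is_mito"] and not row["is_hb"]
    ]
    rng = np.random.default_rng([seed, 42])
    lineages = ["LE", "BE", "T_CD4", "T_CD8", "Macro", "Mono", "NK", "B", "Endo"]
    sizes = {f"markers_{l}": n_marker for l in lineages}
    sizes.update({f"state_{s}": n_program for s in LE_STATES})
    sizes.update({"M1": n_pol, "M2": n_pol})
    sets = _draw_disjoint_sets(rng, eligible, sizes)
    lineage_of = {
        "LE_normal": "LE", "LE_hyperplasia": "LE", "LE_malignant": "LE",
        "BE": "BE", "T_CD4": "T_CD4", "T_CD8": "T_CD8", "Macro_M1": "Macro",
        "Macro_M2": "Macro", "Mono": "Mono", "NK": "NK", "B": "B", "Endo": "Endo",
    }
    cell_types = []
    for name, n_cells in counts.items():
        markers = {g: 5.0 for g in sets[f"markers_{lineage_of[name]}"]}
        program: dict[str, float] = {}
        state = None
        if name.startswith("LE_"):
            state = name.split("_", 1)[1]
            program = {g: 3.0 for g in sets[f"state_{state}"]}
        elif name == "Macro_M1":
            program = {g: 2.0 for g in sets["M1"]}
        elif name == "Macro_M2":
            program = {g: 2.0 for g in sets["M2"]}
        cell_types.append(
            CellTypeSpec(name=name, n_cells=n_cells, markers=markers,
                         state_program=program, state=state)
        )
    # pin marker base weights so markers sit near 1 count-per-10k outside
    # their own type (below the annotation rule's detection and mean
    # thresholds) and 5x that inside it; E[lognormal(0,1)] = e^0.5
    n_genes = sum(n for _, n in chromosomes)
    w_marker = 1.05 * np.exp(0.5) * n_genes / 10_000.0
    base_overrides = {
        g: float(w_marker)
        for l in lineages
        for g in sets[f"markers_{l}"]
    }
    seg_hi = seg_lo + seg_span - 1
    segments = [
        CnvSegment("seg_shared_amp", "chr1", seg_lo, seg_hi, 1.5,
                   ("LE_hyperplasia", "LE_malignant")),
        CnvSegment("seg_shared_del", "chr2", seg_lo, seg_hi, 0.5,
                   ("LE_hyperplasia", "LE_malignant")),
        CnvSegment("seg_h_amp", "chr3", seg_lo, seg_hi, 1.5, ("LE_hyperplasia",)),
        CnvSegment("seg_m_del", "chr4", seg_lo, seg_hi, 0.5, ("LE_malignant",)),
    ]
    layout = None
    if with_spots:
        n_rows, n_cols = grid
        background = {
            "T_CD4": 0.25, "Macro_M1": 0.1, "Macro_M2": 0.15, "Endo": 0.2,
            "B": 0.1, "NK": 0.05, "Mono": 0.05, "LE_normal": 0.1,
        }
        rim_h = {"LE_hyperplasia": 0.45, "LE_normal": 0.15, "T_CD4": 0.2,
                 "Macro_M2": 0.1, "Endo": 0.1}
        rim_m = {"LE_malignant": 0.45, "LE_normal": 0.15, "T_CD4": 0.2,
                 "Macro_M2": 0.1, "Endo": 0.1}
        layout = NoduleLayout(
            grid=grid,
            background=background,
            nodules=[
                Nodule(center=(n_rows // 4, n_cols // 4), radius=radius,
                       interior={"LE_hyperplasia": 0.85, "BE": 0.05,
                                 "Macro_M2": 0.05, "T_CD4": 0.05},
                       rim=rim_h),
                Nodule(center=(n_rows // 4, 3 * n_cols // 4), radius=radius,
                       interior={"LE_malignant": 0.85, "BE": 0.05,
                                 "Macro_M2": 0.05, "T_CD4": 0.05},
                       rim=rim_m),
                Nodule(center=(2 * n_rows // 3, n_cols // 4), radius=radius * 0.8,
                       interior={"LE_normal": 0.9, "BE": 0.1},
                       rim={"LE_normal": 0.5, "BE": 0.1, "T_CD4": 0.2, "Endo": 0.2}),
            ],
            gradient_strips=[
                GradientStrip(
                    rows=(n_rows - 2, n_rows),
                    cols=(0, n_cols),
                    start_mixture={"LE_hyperplasia": 0.9, "T_CD4": 0.1},
                    end_mixture={"LE_malignant": 0.9, "T_CD4": 0.1},
                )
            ],
        )
    return SimulationConfig(
        chromosomes=chromosomes,
        cell_types=cell_types,
        cnv_segments=segments,
        spot_layout=layout,
        n_hb_genes=n_hb,
        library_size_lognormal=lib,
        spot_library_lognormal=spot_lib,
        base_overrides=base_overrides,
        seed=seed,
    )


def fixture_gene_sets(cfg: SimulationConfig) -> pd.DataFrame:
    """Two-column (set_name, gene_id) table of every planted gene program."""
    rows = []
    seen_markers: dict[tuple, str] = {}
    for spec in cfg.cell_types:
        if spec.name.startswith("LE_"):
            lineage = "LE"
        elif spec.name.startswith("Macro"):
            lineage = "Macro"
        else:
            lineage = spec.name
        key = tuple(sorted(spec.markers))
        label = seen_markers.get(key)
        if label is None:
            label = f"markers_{lineage}"
            seen_markers[key] = label
            rows += [{"set_name": label, "gene_id": g} for g in sorted(spec.markers)]
        if spec.state is not None:
            rows += [
                {"set_name": f"state_{spec.state}", "gene_id": g}
                for g in sorted(spec.state_program)
            ]
        elif spec.name == "Macro_M1":
            rows += [{"set_name": "M1", "gene_id": g} for g in sorted(spec.state_program)]
        elif spec.name == "Macro_M2":
            rows += [{"set_name": "M2", "gene_id": g} for g in sorted(spec.state_program)]
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


def default_fixture(out_dir: str | Path, scale: str = "tiny", seed: int = 0) -> Path:
    """Write a complete on-disk dataset (cells, spots, gene table, gene
    sets, truth tables, config) for the given scale; returns the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = make_config(scale=scale, seed=seed)
    ann = build_gene_table(cfg)
    cells, cell_truth = simulate_cells(cfg)
    spots, spot_truth, coords = simulate_spots(cfg)
    write_counts_10x(cells, out / "cells")
    write_counts_10x(spots, out / "spots")
    write_gene_table(ann, out / "genes.bed")
    cell_truth.to_csv(out / "cell_truth.tsv", sep="\t")
    spot_truth.to_csv(out / "spot_truth.tsv", sep="\t")
    coords.to_csv(out / "spot_coords.tsv", sep="\t")
    seg_genes = _segment_gene_ids(cfg, ann)
    seg_rows = []
    for seg in cfg.cnv_segments:
        for g in seg_genes[seg.name]:
            seg_rows.append(
                {
                    "segment": seg.name,
                    "gene_id": g,
                    "chromosome": seg.chromosome,
                    "dosage": seg.dosage,
                    "carriers": ";".join(seg.carriers),
                }
            )
    pd.DataFrame(seg_rows).to_csv(out / "segments.tsv", sep="\t", index=False)
    fixture_gene_sets(cfg).to_csv(out / "gene_sets.tsv", sep="\t", index=False)
    cfg.to_json(out / "config.json")
    return out
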