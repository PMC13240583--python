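"""End-to-end orchestration: simulate -> qc -> markers/scores -> cnv ->
deconv -> transformation map -> truth comparison.

A run is a pure function of (config, seed): every stage writes its
outputs under the run directory, the report records parameters, output
checksums and counts, and rerunning with the same config reproduces
identical checksums. Ground-truth comparison metrics are attached
whenever the generator's truth tables are present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import deconv as deconv_mod
from . import markers as mk
from . import qc as qc_mod
from . import synthetic, transform
from .io_formats import read_counts_10x, read_gene_table, write_counts_10x
from .qc import QcProfile, QcRule

__all__ = ["RunConfig", "run_pipeline", "compare_to_truth", "fixture_spot_profile"]

_STAGE_DEPS = {
    "simulate": (),
    "qc": ("simulate",),
    "markers": ("qc",),
    "score": ("qc",),
    "cnv": ("qc",),
    "tree": ("cnv",),
    "deconv": ("markers",),
    "map": ("deconv",),
    "compare": ("map",),
}

ALL_STAGES = tuple(_STAGE_DEPS)

# planted desk/tiny topology: the lesion states share segments, so the
# hyperplastic and malignant leaves are sisters, with normal LE and basal
# epithelium on the other side
PLANTED_TOPOLOGY = "((LE_hyperplasia,LE_malignant),(LE_normal,BE));"


@dataclass
class RunConfig:
    out_dir: str
    scale: str = "tiny"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cell_profile: str = "auto"  # auto: internal_cell at desk, scaled at tiny
    spot_profile: str = "auto"  # auto: spatial_spot at desk, scaled at tiny
    cnv_window: int = 0  # 0 -> scale default (17 desk, 11 tiny)
    n_top: int = 0  # 0 -> scale default (100 desk, 25 tiny)
    dominance: float = 0.8
    score_seed: int = 0
    render: bool = False

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def fixture_spot_profile(scale: str) -> QcProfile:
    """Spot QC profile matched to fixture scale: the full-size thresholds
    at desk scale, proportionally scaled bounds for the tiny smoke fixture
    (whose gene universe is far below the detected-gene threshold)."""
    if scale == "desk":
        return qc_mod.BUILTIN_PROFILES["spatial_spot"]
    return QcProfile(
        "tiny_spot",
        (
            QcRule("n_umi", "<", 200),
            QcRule("n_umi", ">", 50_000),
            QcRule("n_gene", "<", 50),
            QcRule("pct_mito", ">", 15),
        ),
    )


def fixture_cell_profile(scale: str) -> QcProfile:
    """Cell QC profile matched to fixture scale; the genes-per-UMI and
    detected-gene thresholds assume a transcriptome-scale gene universe,
    so the tiny smoke fixture uses proportionally scaled bounds."""
    if scale == "desk":
        return qc_mod.BUILTIN_PROFILES["internal_cell"]
    return QcProfile(
        "tiny_cell",
        (
            QcRule("n_gene", "<", 50),
            QcRule("n_umi", "<", 500),
            QcRule("log10_genes_per_umi", "<", 0.5),
            QcRule("pct_mito", ">", 10),
            QcRule("pct_hb", ">", 5),
        ),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_dir(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file() and p.suffix != ".png":
            out[str(p.relative_to(root))] = _sha256(p)
    return out


def _require(stage: str, enabled: set[str]) -> None:
    for dep in _STAGE_DEPS[stage]:
        if dep not in enabled:
            raise ValueError(f"stage {stage!r} requires stage {dep!r} to be enabled")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report
    (also written to ``<out_dir>/report.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(cfg.stages)
    for stage in enabled:
        if stage not in _STAGE_DEPS:
            raise ValueError(f"unknown stage {stage!r}")
        _require(stage, enabled)
    window = cfg.cnv_window or (17 if cfg.scale == "desk" else 11)
    n_top = cfg.n_top or (100 if cfg.scale == "desk" else 25)
    report: dict = {
        "config": dataclasses.asdict(cfg),
        "resolved": {"cnv_window": window, "n_top": n_top},
        "stages": {},
    }
    data_dir = out / "data"

    if "simulate" in enabled:
        synthetic.default_fixture(data_dir, scale=cfg.scale, seed=cfg.seed)
        report["stages"]["simulate"] = {"status": "ok", "dir": str(data_dir)}
    if not data_dir.exists():
        raise FileNotFoundError(f"stage 'qc' needs simulated data at {data_dir}")

    ann = read_gene_table(data_dir / "genes.bed")
    cells = read_counts_10x(data_dir / "cells")
    spots = read_counts_10x(data_dir / "spots")
    cell_truth = pd.read_csv(data_dir / "cell_truth.tsv", sep="\t", index_col="cell_id")
    spot_truth = pd.read_csv(data_dir / "spot_truth.tsv", sep="\t", index_col="spot_id")
    coords = pd.read_csv(data_dir / "spot_coords.tsv", sep="\t", index_col="spot_id")

    qc_dir = out / "qc"
    if "qc" in enabled:
        qc_dir.mkdir(exist_ok=True)
        cell_prof = (
            fixture_cell_profile(cfg.scale)
            if cfg.cell_profile == "auto"
            else cfg.cell_profile
        )
        cell_metrics = qc_mod.compute_qc_metrics(cells, ann)
        cells, cell_log = qc_mod.filter_cells(cells, cell_metrics, cell_prof)
        spot_prof = (
            fixture_spot_profile(cfg.scale)
            if cfg.spot_profile == "auto"
            else cfg.spot_profile
        )
        spot_metrics = qc_mod.compute_qc_metrics(spots, ann)
        spots, spot_log = qc_mod.filter_spots(spots, spot_metrics, spot_prof)
        cell_log.to_csv(qc_dir / "cell_removals.tsv", sep="\t", index=False)
        spot_log.to_csv(qc_dir / "spot_removals.tsv", sep="\t", index=False)
        write_counts_10x(cells, qc_dir / "cells")
        write_counts_10x(spots, qc_dir / "spots")
        report["stages"]["qc"] = {
            "status": "ok",
            "cells_removed": int(len(cell_log)),
            "spots_removed": int(len(spot_log)),
            "cells_surviving": cells.shape[1],
            "spots_surviving": spots.shape[1],
            "sample_mito_flag": qc_mod.sample_mito_flag(cell_metrics),
        }

    cell_truth = cell_truth.loc[cells.column_ids]
    spot_truth = spot_truth.loc[spots.column_ids]
    nm = mk.normalize_counts(cells)
    types = cell_truth["cell_type"]
    states = cell_truth["state"]
    gene_sets = pd.read_csv(data_dir / "gene_sets.tsv", sep="\t")
    set_map = {
        name: sub["gene_id"].tolist() for name, sub in gene_sets.groupby("set_name")
    }

    annotation: dict[str, str] | None = None
    if "markers" in enabled:
        mdir = out / "markers"
        mdir.mkdir(exist_ok=True)
        table = mk.rank_markers(nm, types)
        table.to_csv(mdir / "marker_table.tsv", sep="\t", index=False)
        marker_dict = {
            name.removeprefix("markers_"): genes
            for name, genes in set_map.items()
            if name.startswith("markers_")
        }
        annotation = mk.annotate_clusters(nm, types, marker_dict)
        pd.Series(annotation, name="assigned").rename_axis("cluster").to_csv(
            mdir / "annotation.tsv", sep="\t"
        )
        report["stages"]["markers"] = {
            "status": "ok",
            "n_marker_rows": int(len(table)),
            "annotation": annotation,
        }

    if "score" in enabled:
        sdir = out / "scores"
        sdir.mkdir(exist_ok=True)
        macro = types.str.startswith("Macro")
        macro_nm = mk.NormalizedMatrix(
            nm.values[:, macro.to_numpy()], nm.gene_ids,
            [c for c, m in zip(nm.column_ids, macro) if m],
        )
        m1 = mk.module_score(macro_nm, set_map["M1"], seed=cfg.score_seed)
        m2 = mk.module_score(macro_nm, set_map["M2"], seed=cfg.score_seed + 1)
        summary, pairwise = mk.polarization_summary(m1, m2, types[macro.to_numpy()])
        scores = pd.DataFrame(
            {"m1": m1, "m2": m2, "diff": m1 - m2},
            index=pd.Index(macro_nm.column_ids, name="cell_id"),
        )
        scores.to_csv(sdir / "macrophage_scores.tsv", sep="\t")
        summary.to_csv(sdir / "polarization_summary.tsv", sep="\t")
        pairwise.to_csv(sdir / "polarization_tests.tsv", sep="\t", index=False)
        report["stages"]["score"] = {
            "status": "ok",
            "groups": summary["m1_minus_m2"].to_dict(),
        }

    profile = None
    calls = None
    partition = None
    if "cnv" in enabled:
        cdir = out / "cnv"
        cdir.mkdir(exist_ok=True)
        reference = [c for c, t in types.items() if t == "LE_normal"]
        profile = cnv_mod.cnv_profile(nm, ann, reference, window=window)
        groups = {
            t: [c for c, tt in types.items() if tt == t]
            for t in ("LE_hyperplasia", "LE_malignant")
        }
        calls = cnv_mod.call_cnv(profile, groups)
        partition = cnv_mod.partition_shared(
            calls["LE_hyperplasia"], calls["LE_malignant"]
        )
        rows = []
        for gname, cs in calls.items():
            for g in sorted(cs.amplified):
                rows.append({"group": gname, "gene": g, "direction": "amplified",
                             "fraction": cs.fraction_above[g]})
            for g in sorted(cs.deleted):
                rows.append({"group": gname, "gene": g, "direction": "deleted",
                             "fraction": cs.fraction_below[g]})
        pd.DataFrame(rows, columns=["group", "gene", "direction", "fraction"]).to_csv(
            cdir / "calls.tsv", sep="\t", index=False
        )
        part_rows = [
            {"category": cat, "gene": g}
            for cat, genes in (
                ("shared_amplified", partition.shared_amplified),
                ("shared_deleted", partition.shared_deleted),
                ("unique_to_hyperplasia", partition.unique_to_a),
                ("unique_to_malignant", partition.unique_to_b),
                ("discordant", partition.discordant),
            )
            for g in sorted(genes)
        ]
        pd.DataFrame(part_rows, columns=["category", "gene"]).to_csv(
            cdir / "partition.tsv", sep="\t", index=False
        )
        report["stages"]["cnv"] = {
            "status": "ok",
            "n_amplified": {g: len(c.amplified) for g, c in calls.items()},
            "n_deleted": {g: len(c.deleted) for g, c in calls.items()},
        }

    tree = None
    if "tree" in enabled:
        subclusters = types.where(
            types.isin(["LE_normal", "LE_hyperplasia", "LE_malignant", "BE"])
        ).dropna()
        sub_profile_cells = profile.cell_index(list(subclusters.index))
        sub = cnv_mod.CnvProfile(
            profile.values[:, sub_profile_cells],
            profile.gene_ids,
            list(subclusters.index),
            profile.reference_cells,
            profile.window,
        )
        tree = cnv_mod.cnv_tree(sub, subclusters, state_labels=states[subclusters.index])
        (out / "cnv" / "tree.nwk").write_text(tree.newick + "\n")
        if tree.leaf_metadata is not None:
            tree.leaf_metadata.to_csv(out / "cnv" / "tree_leaves.tsv", sep="\t")
        report["stages"]["tree"] = {"status": "ok", "newick": tree.newick}

    weights_states = None
    if "deconv" in enabled:
        ddir = out / "deconv"
        ddir.mkdir(exist_ok=True)
        spot_nm = mk.normalize_counts(spots)
        sig_types = deconv_mod.build_signature(nm, types, n=n_top)
        res_types = deconv_mod.estimate_weights(spot_nm, sig_types)
        le_mask = types.str.startswith("LE_").to_numpy()
        le_nm = mk.NormalizedMatrix(
            nm.values[:, le_mask], nm.gene_ids,
            [c for c, m in zip(nm.column_ids, le_mask) if m],
        )
        sig_states = deconv_mod.build_signature(le_nm, states[le_mask], n=n_top)
        weights_states = deconv_mod.state_weights(spot_nm, sig_states)
        sig_types.values.to_csv(ddir / "signature_types.tsv", sep="\t")
        sig_states.values.to_csv(ddir / "signature_states.tsv", sep="\t")
        res_types.weights.to_csv(ddir / "weights_types.tsv", sep="\t")
        weights_states.weights.to_csv(ddir / "weights_states.tsv", sep="\t")
        report["stages"]["deconv"] = {
            "status": "ok",
            "n_spots": int(len(res_types.weights)),
            "n_undetermined_states": int(weights_states.undetermined.sum()),
        }

    tm = None
    if "map" in enabled:
        mdir = out / "map"
        mdir.mkdir(exist_ok=True)
        tm = transform.classify_spots(
            weights_states, dominance=cfg.dominance, coords=coords.loc[spots.column_ids]
        )
        tm.to_csv(mdir / "transformation_map.tsv", sep="\t")
        if cfg.render:
            transform.render_map(tm, mdir / "transformation_map.png")
        report["stages"]["map"] = {
            "status": "ok",
            "pathway_counts": tm["pathway"].value_counts().to_dict(),
        }

    if "compare" in enabled:
        metrics = compare_to_truth(
            out,
            annotation=annotation,
            calls=calls,
            partition=partition,
            tree=tree,
            state_weights_result=weights_states,
            tmap=tm,
            cell_truth=cell_truth,
            spot_truth=spot_truth,
            data_dir=data_dir,
        )
        metrics.to_csv(out / "truth_metrics.tsv", sep="\t", index=False)
        report["stages"]["compare"] = {
            "status": "ok",
            "metrics": dict(zip(metrics["metric"], metrics["value"])),
        }

    report["checksums"] = _checksum_dir(out)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def segment_truth_sets(seg_table: pd.DataFrame) -> dict[str, set[str]]:
    """Planted per-category gene sets from the generator's segment table."""
    out = {
        "shared_amplified": set(),
        "shared_deleted": set(),
        "unique_to_hyperplasia": set(),
        "unique_to_malignant": set(),
    }
    for _, row in seg_table.iterrows():
        carriers = set(row["carriers"].split(";"))
        direction = "amplified" if row["dosage"] > 1 else "deleted"
        if carriers == {"LE_hyperplasia", "LE_malignant"}:
            out[f"shared_{direction}"].add(row["gene_id"])
        elif carriers == {"LE_hyperplasia"}:
            out["unique_to_hyperplasia"].add(row["gene_id"])
        elif carriers == {"LE_malignant"}:
            out["unique_to_malignant"].add(row["gene_id"])
    return out


def cnv_recovery_metrics(
    calls: dict, seg_table: pd.DataFrame, all_genes: list[str]
) -> dict[str, float]:
    """Gene-level sensitivity inside planted segments and specificity
    outside, per target group, plus per-category partition Jaccard."""
    metrics: dict[str, float] = {}
    for group, cs in calls.items():
        truth_amp = set(
            seg_table[(seg_table["dosage"] > 1) & seg_table["carriers"].str.contains(group)][
                "gene_id"
            ]
        )
        truth_del = set(
            seg_table[(seg_table["dosage"] < 1) & seg_table["carriers"].str.contains(group)][
                "gene_id"
            ]
        )
        truth_all = truth_amp | truth_del
        called = cs.amplified | cs.deleted
        tp = len((cs.amplified & truth_amp) | (cs.deleted & truth_del))
        metrics[f"cnv_sensitivity_{group}"] = tp / max(len(truth_all), 1)
        outside = set(all_genes) - truth_all
        fp = len(called & outside)
        metrics[f"cnv_specificity_{group}"] = 1.0 - fp / max(len(outside), 1)
    return metrics


def compare_to_truth(
    out: Path,
    annotation,
    calls,
    partition,
    tree,
    state_weights_result,
    tmap,
    cell_truth: pd.DataFrame,
    spot_truth: pd.DataFrame,
    data_dir: Path,
) -> pd.DataFrame:
    """Ground-truth comparison metrics; missing truth inputs are skipped
    with a warning."""
    rows: list[dict] = []

    def add(metric: str, value: float) -> None:
        rows.append({"metric": metric, "value": float(value)})

    if annotation is not None:
        lineage = {
            t: ("LE" if t.startswith("LE_") else ("Macro" if t.startswith("Macro") else t))
            for t in cell_truth["cell_type"].unique()
        }
        correct = sum(annotation.get(t) == lin for t, lin in lineage.items())
        add("annotation_accuracy", correct / len(lineage))

    seg_path = data_dir / "segments.tsv"
    if calls is not None and seg_path.exists():
        seg_table = pd.read_csv(seg_path, sep="\t")
        all_genes = list(next(iter(calls.values())).fraction_above.index)
        for k, v in cnv_recovery_metrics(calls, seg_table, all_genes).items():
            add(k, v)
        truth_sets = segment_truth_sets(seg_table)
        called_sets = {
            "shared_amplified": partition.shared_amplified,
            "shared_deleted": partition.shared_deleted,
            "unique_to_hyperplasia": partition.unique_to_a,
            "unique_to_malignant": partition.unique_to_b,
        }
        for cat, truth in truth_sets.items():
            add(f"partition_jaccard_{cat}", _jaccard(called_sets[cat], truth))
    elif calls is not None:
        warnings.warn("segments.tsv missing; CNV recovery metrics skipped")

    if tree is not None:
        add("tree_rf_distance", cnv_mod.rf_distance(tree.newick, PLANTED_TOPOLOGY))

    if state_weights_result is not None:
        le_cols = ["LE_normal", "LE_hyperplasia", "LE_malignant"]
        truth_w = spot_truth[le_cols].to_numpy(dtype=float)
        sums = truth_w.sum(axis=1)
        ok = sums > 0.5  # spots dominated by LE signal have meaningful state truth
        truth_norm = truth_w[ok] / sums[ok][:, None]
        est = state_weights_result.weights[["normal", "hyperplasia", "malignant"]]
        est = est.loc[spot_truth.index[ok]].to_numpy()
        add("state_weight_mae_le_spots", np.abs(est - truth_norm).mean())

    if tmap is not None and "region" in spot_truth.columns:
        strip = spot_truth.index[spot_truth["region"].str.startswith("strip")]
        strip_map = tmap.loc[tmap.index.intersection(strip)]
        if (strip_map["stage"] != "NA").sum() >= 3:
            add(
                "strip_stage_rank_association",
                transform.stage_position_association(strip_map, strip_map["col"]),
            )
    return pd.DataFrame(rows, columns=["metric", "value"])
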