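"""Spot-level lesion transformation pathways and progression stages.

Per spot, the three luminal-epithelial state weights (normal,
hyperplasia, malignant) are reduced to a pathway and a stage:

* if the largest weight exceeds the dominance threshold (default 0.8),
  the spot is stable in that state (stage NA);
* otherwise the two largest-weight states, ordered by progression rank
  normal < hyperplasia < malignant, define the pathway (n_to_h, h_to_m or
  n_to_m), and the transformation index is
  ``w(later) / (w(earlier) + w(later))`` in [0, 1];
* stage tertiles on the index: early (< 1/3), advanced (> 2/3),
  intermediate otherwise.

The dominance threshold, the two-largest-states rule, the index formula
and the tertile cut-offs are this package's own definitions: the source
analysis reports exactly three pathways at three intensities but gives no
formula, so every knob here is configurable and documented as a choice.
An optional admissibility set (from external trajectory analyses) can
veto pathways; vetoed spots fall back to stable in their argmax state.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .deconv import DeconvResult

__all__ = [
    "STATE_ORDER",
    "PATHWAY_HUES",
    "STAGE_RANK",
    "classify_spots",
    "stage_position_association",
    "render_map",
    "read_map",
]

STAGE_RANK = {"early": 0, "intermediate": 1, "advanced": 2}

STATE_ORDER = ("normal", "hyperplasia", "malignant")

# hue legend: blue = normal->hyperplasia, orange = hyperplasia->malignant,
# green = normal->malignant
PATHWAY_HUES = {
    "n_to_h": "#1f77b4",
    "h_to_m": "#ff7f0e",
    "n_to_m": "#2ca02c",
    "stable_normal": "#bdbdbd",
    "stable_hyperplasia": "#969696",
    "stable_malignant": "#636363",
}

_STAGE_ALPHA = {"early": 0.35, "intermediate": 0.65, "advanced": 1.0, "NA": 1.0}

_PATHWAY_NAME = {
    ("normal", "hyperplasia"): "n_to_h",
    ("hyperplasia", "malignant"): "h_to_m",
    ("normal", "malignant"): "n_to_m",
}


def classify_spots(
    w: DeconvResult | pd.DataFrame,
    dominance: float = 0.8,
    coords: pd.DataFrame | None = None,
    admissible: set[str] | None = None,
    early_cut: float = 1 / 3,
    advanced_cut: float = 2 / 3,
) -> pd.DataFrame:
    """Classify each spot into a transformation pathway and stage.

    ``w`` holds per-spot state weights on the simplex over
    ``(normal, hyperplasia, malignant)``. ``coords`` (indexed by spot id,
    columns row/col) attaches grid positions when given. Returns a
    DataFrame indexed by spot id with pathway, stage, index (NaN for
    stable spots) and optional row/col.
    """
    weights = w.weights if isinstance(w, DeconvResult) else w
    missing = [s for s in STATE_ORDER if s not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing state column(s) {missing}")
    W = weights[list(STATE_ORDER)].to_numpy(dtype=float)
    if (W < -1e-6).any() or (np.abs(W.sum(axis=1) - 1.0) > 1e-6).any():
        raise ValueError("state weights are off the probability simplex")
    rows = []
    for i, spot in enumerate(weights.index):
        wv = W[i]
        top = int(np.argmax(wv))
        if wv[top] > dominance:
            pathway, stage, index = f"stable_{STATE_ORDER[top]}", "NA", np.nan
        else:
            two = np.argsort(wv)[-2:]  # indices of the two largest weights
            lo, hi = sorted(two)  # progression order: normal < hyper < malig
            pathway = _PATHWAY_NAME[(STATE_ORDER[lo], STATE_ORDER[hi])]
            if admissible is not None and pathway not in admissible:
                pathway, stage, index = f"stable_{STATE_ORDER[top]}", "NA", np.nan
            else:
                index = wv[hi] / (wv[lo] + wv[hi])
                if index < early_cut:
                    stage = "early"
                elif index > advanced_cut:
                    stage = "advanced"
                else:
                    stage = "intermediate"
        rows.append({"spot_id": spot, "pathway": pathway, "stage": stage, "index": index})
    tm = pd.DataFrame(rows).set_index("spot_id")
    if coords is not None:
        tm = tm.join(coords[["row", "col"]], how="left")
        if tm[["row", "col"]].isna().any().any():
            raise ValueError("coordinates missing for some spots")
    return tm


def stage_position_association(tm: pd.DataFrame, positions) -> float:
    """Kendall-type rank association between spatial position and stage.

    Only staged spots (stage != NA) enter. Because the stage is a
    three-level ordinal variable, the tie-corrected tau-b is bounded well
    below 1 even for a perfect early->intermediate->advanced staircase, so
    this uses the tie-ignoring Kendall variant (Goodman-Kruskal gamma):
    (concordant - discordant) / (concordant + discordant) over pairs with
    distinct stages and distinct positions. 1.0 means perfectly monotone.
    """
    positions = np.asarray(pd.Series(positions), dtype=float)
    staged = tm["stage"] != "NA"
    ranks = tm.loc[staged, "stage"].map(STAGE_RANK).to_numpy(dtype=float)
    pos = positions[staged.to_numpy()]
    if len(ranks) < 2:
        raise ValueError("need at least two staged spots")
    dr = np.sign(ranks[:, None] - ranks[None, :])
    dp = np.sign(pos[:, None] - pos[None, :])
    prod = (dr * dp)[np.triu_indices(len(ranks), k=1)]
    concordant = (prod > 0).sum()
    discordant = (prod < 0).sum()
    if concordant + discordant == 0:
        return 0.0
    return float((concordant - discordant) / (concordant + discordant))


def render_map(tm: pd.DataFrame, path: str | Path, point_size: float = 30.0) -> Path:
    """Render the transformation map (hue = pathway, intensity = stage)
    and write a TSV sidecar with all per-spot fields.

    Returns the sidecar path; the figure is written to ``path``.
    """
    if "row" not in tm.columns or "col" not in tm.columns:
        raise ValueError("transformation map has no coordinates")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    for pathway, sub in tm.groupby("pathway"):
        color = PATHWAY_HUES.get(pathway, "#000000")
        for stage, ss in sub.groupby("stage"):
            ax.scatter(
                ss["col"],
                -ss["row"],
                s=point_size,
                c=color,
                alpha=_STAGE_ALPHA.get(stage, 1.0),
                label=f"{pathway} ({stage})" if stage != "NA" else pathway,
                linewidths=0,
            )
    ax.set_aspect("equal")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.legend(fontsize=6, loc="upper left", bbox_to_anchor=(1.01, 1.0))
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    sidecar = path.with_suffix(".tsv")
    tm.to_csv(sidecar, sep="\t")
    return sidecar


def read_map(path: str | Path) -> pd.DataFrame:
    """Read a transformation-map TSV sidecar back into memory."""
    tm = pd.read_csv(path, sep="\t", index_col="spot_id", keep_default_na=False)
    tm["index"] = pd.to_numeric(tm["index"], errors="coerce")
    return tm
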