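"""Threshold-based quality control for cells and spatial spots.

Three built-in threshold profiles are provided:

* ``internal_cell`` — remove cells with n_gene < 200, n_umi < 1000,
  log10 genes-per-UMI < 0.7, mitochondrial percentage > 10, or
  hemoglobin percentage > 5;
* ``spatial_spot`` — keep spots with 1000 <= n_umi <= 50,000,
  n_gene >= 500 and mito percentage <= 15;
* ``geo_cell`` — remove cells with n_gene <= 200, n_gene >= 6000,
  n_umi >= 50,000 or mito percentage > 15 (the <=200 boundary reading is
  a documented choice; the source criteria are ambiguous there).

Comparison strictness follows the printed inequalities verbatim. A rule
fires when its comparison holds, and every fired rule is recorded in the
removal log, so survivor + removed partitions the input columns.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneTable

__all__ = [
    "QcRule",
    "QcProfile",
    "BUILTIN_PROFILES",
    "compute_qc_metrics",
    "filter_cells",
    "filter_spots",
    "filter_columns",
    "sample_mito_flag",
]

_OPS = {"<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge}

METRIC_COLUMNS = ["n_umi", "n_gene", "log10_genes_per_umi", "pct_mito", "pct_hb"]


@dataclass(frozen=True)
class QcRule:
    """A single removal rule: column removed when ``metric op threshold``."""

    metric: str
    op: str
    threshold: float

    @property
    def name(self) -> str:
        return f"{self.metric}{self.op}{self.threshold:g}"

    def fires(self, metrics: pd.DataFrame) -> np.ndarray:
        return _OPS[self.op](metrics[self.metric].to_numpy(), self.threshold)


@dataclass(frozen=True)
class QcProfile:
    name: str
    rules: tuple[QcRule, ...] = field(default_factory=tuple)


BUILTIN_PROFILES: dict[str, QcProfile] = {
    "internal_cell": QcProfile(
        "internal_cell",
        (
            QcRule("n_gene", "<", 200),
            QcRule("n_umi", "<", 1000),
            QcRule("log10_genes_per_umi", "<", 0.7),
            QcRule("pct_mito", ">", 10),
            QcRule("pct_hb", ">", 5),
        ),
    ),
    "spatial_spot": QcProfile(
        "spatial_spot",
        (
            QcRule("n_umi", "<", 1000),
            QcRule("n_umi", ">", 50_000),
            QcRule("n_gene", "<", 500),
            QcRule("pct_mito", ">", 15),
        ),
    ),
    "geo_cell": QcProfile(
        "geo_cell",
        (
            QcRule("n_gene", "<=", 200),
            QcRule("n_gene", ">=", 6000),
            QcRule("n_umi", ">=", 50_000),
            QcRule("pct_mito", ">", 15),
        ),
    ),
}


def compute_qc_metrics(m: CountMatrix, ann: GeneTable) -> pd.DataFrame:
    """Per-column QC metrics, indexed by column id.

    ``log10_genes_per_umi`` is log10(n_gene)/log10(n_umi), defined as 0
    when n_umi <= 1 (all-zero columns are then caught by the count rules).
    Percentages are on a 0-100 scale.
    """
    ann.require(m.gene_ids)
    csc = m.values.tocsc()
    n_umi = np.asarray(csc.sum(axis=0)).ravel().astype(np.int64)
    n_gene = np.asarray((csc > 0).sum(axis=0)).ravel().astype(np.int64)
    flags = ann.df.loc[m.gene_ids]
    mito_mask = flags["is_mito"].to_numpy()
    hb_mask = flags["is_hb"].to_numpy()
    mito_umi = np.asarray(csc[mito_mask, :].sum(axis=0)).ravel()
    hb_umi = np.asarray(csc[hb_mask, :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        lgpu = np.where(
            n_umi > 1, np.log10(np.maximum(n_gene, 1)) / np.log10(np.maximum(n_umi, 2)), 0.0
        )
        pct_mito = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
        pct_hb = np.where(n_umi > 0, 100.0 * hb_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_umi": n_umi,
            "n_gene": n_gene,
            "log10_genes_per_umi": lgpu,
            "pct_mito": pct_mito,
            "pct_hb": pct_hb,
        },
        index=pd.Index(m.column_ids, name="column_id"),
    )


def _resolve_profile(profile: str | QcProfile) -> QcProfile:
    if isinstance(profile, QcProfile):
        return profile
    try:
        return BUILTIN_PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown QC profile {profile!r}; built-ins: {sorted(BUILTIN_PROFILES)}"
        ) from None


def filter_columns(
    m: CountMatrix, metrics: pd.DataFrame, profile: str | QcProfile
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove columns for which any profile rule fires.

    Returns the surviving matrix and a removal log with one row per removed
    column listing every rule that fired (comma-separated).
    """
    prof = _resolve_profile(profile)
    if list(metrics.index) != list(m.column_ids):
        raise ValueError("metrics index does not match matrix columns")
    fired = {rule.name: rule.fires(metrics) for rule in prof.rules}
    any_fired = np.zeros(m.shape[1], dtype=bool)
    for mask in fired.values():
        any_fired |= mask
    reasons = []
    for i in np.flatnonzero(any_fired):
        reasons.append(
            {
                "column_id": m.column_ids[i],
                "rules": ",".join(n for n, mask in fired.items() if mask[i]),
            }
        )
    log = pd.DataFrame(reasons, columns=["column_id", "rules"])
    survivors = m.subset_columns(np.flatnonzero(~any_fired))
    return survivors, log


def filter_cells(
    m: CountMatrix, metrics: pd.DataFrame, profile: str | QcProfile = "internal_cell"
) -> tuple[CountMatrix, pd.DataFrame]:
    return filter_columns(m, metrics, profile)


def filter_spots(
    m: CountMatrix, metrics: pd.DataFrame, profile: str | QcProfile = "spatial_spot"
) -> tuple[CountMatrix, pd.DataFrame]:
    return filter_columns(m, metrics, profile)


def sample_mito_flag(metrics: pd.DataFrame, threshold: float = 25.0) -> bool:
    """Whole-sample mito check: True (flag the sample) when total
    mitochondrial UMI exceeds ``threshold`` percent of all UMI."""
    total = metrics["n_umi"].sum()
    if total == 0:
        return False
    mito = (metrics["pct_mito"] * metrics["n_umi"]).sum() / 100.0
    return bool(100.0 * mito / total > threshold)
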