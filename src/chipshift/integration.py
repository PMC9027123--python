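"""Expression filtering and ChIP/RNA integration.

Differential-expression tables are DESeq2-style
(``gene_id, log2FC, padj``).  A gene is significant when
``padj < alpha`` and ``|log2FC| > lfc_min`` — both strict — with
defaults alpha = 0.05 and lfc_min = 0.58 (about 1.5-fold).  "Repressed"
genes are those *up*-regulated after knocking the factor down,
"activated" genes those downregulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DEFilterResult",
    "filter_de",
    "merge_expression_binding",
    "six_way_categories",
    "heatmap_matrix",
    "SIX_WAY_LABELS",
]

REQUIRED_COLUMNS = ("gene_id", "log2FC", "padj")

SIX_WAY_LABELS = (
    "core-esBAF-repressed",
    "core-esBAF-activated",
    "B1-repressed-not-A4",
    "B1-activated-not-A4",
    "A4-repressed-not-B1",
    "A4-activated-not-B1",
)


def _validate_de(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    bad = table.index[pd.to_numeric(table["log2FC"], errors="coerce").isna()
                      & table["log2FC"].notna()]
    if len(bad):
        raise ValueError(f"malformed log2FC at row {bad[0]}")
    return table


@dataclass
class DEFilterResult:
    """Partition of a DE table into up / down / excluded."""

    up: pd.DataFrame
    down: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        return pd.concat([self.up, self.down]).sort_index()


def filter_de(
    table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.58
) -> DEFilterResult:
    """Split a DE table by the significance filter.

    up: ``padj < alpha`` and ``log2FC > lfc_min``;
    down: ``padj < alpha`` and ``log2FC < -lfc_min``.
    Rows with missing padj are never significant.  Inequalities are
    strict, so padj exactly at alpha is excluded.
    """
    table = _validate_de(table)
    padj = pd.to_numeric(table["padj"], errors="coerce")
    lfc = pd.to_numeric(table["log2FC"], errors="coerce")
    sig = padj.notna() & (padj < alpha)
    up_mask = sig & (lfc > lfc_min)
    down_mask = sig & (lfc < -lfc_min)
    return DEFilterResult(
        up=table[up_mask],
        down=table[down_mask],
        excluded=table[~(up_mask | down_mask)],
    )


def merge_expression_binding(
    de: pd.DataFrame,
    membership: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.58,
) -> pd.DataFrame:
    """Per-gene binding profile: expression direction + class memberships.

    ``membership`` is the annotation table
    (gene_id, antibody, peak_class, n_peaks).  The result has one row
    per gene in the DE table with columns ``gene_id, log2FC, padj,
    direction`` (up/down/ns) and, per antibody, the comma-joined sorted
    set of peak classes (empty string = no surviving peak, flagged by
    ``has_binding``).  Duplicate gene ids in the DE table are an error.
    """
    de = _validate_de(de)
    if de["gene_id"].duplicated().any():
        dupe = de["gene_id"][de["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id in DE table: {dupe!r}")
    res = filter_de(de, alpha=alpha, lfc_min=lfc_min)
    direction = pd.Series("ns", index=de["gene_id"])
    direction.loc[res.up["gene_id"]] = "up"
    direction.loc[res.down["gene_id"]] = "down"

    profiles = de[["gene_id", "log2FC", "padj"]].copy()
    profiles["direction"] = direction.values

    antibodies = sorted(membership["antibody"].unique()) if len(membership) else []
    for ab in antibodies:
        sub = membership[membership["antibody"] == ab]
        classes = sub.groupby("gene_id")["peak_class"].apply(
            lambda s: ",".join(sorted(set(s)))
        )
        profiles[ab] = profiles["gene_id"].map(classes).fillna("")
    profiles["has_binding"] = (
        profiles[antibodies].ne("").any(axis=1) if antibodies else False
    )
    return profiles.reset_index(drop=True)


def _side_flags(
    table: pd.DataFrame, p_max: float, lfc_min: float
) -> pd.DataFrame:
    """Per gene: significant-up ('repressed') and significant-down
    ('activated') flags for one knockdown dataset."""
    t = _validate_de(table)
    padj = pd.to_numeric(t["padj"], errors="coerce")
    lfc = pd.to_numeric(t["log2FC"], errors="coerce")
    sig = padj.notna() & (padj < p_max)
    return pd.DataFrame(
        {
            "gene_id": t["gene_id"].values,
            "repressed": (sig & (lfc > lfc_min)).values,
            "activated": (sig & (lfc < -lfc_min)).values,
        }
    ).set_index("gene_id")


def six_way_categories(
    b1_de: pd.DataFrame,
    a4_de: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 0.58,
    lfc_min_a4: Optional[float] = None,
) -> pd.DataFrame:
    """Compare two knockdown DE tables gene by gene.

    Core categories need a concordant significant change in both tables;
    the "X-not-Y" categories need significance in X and absence of a
    significant change *in that direction* in Y.  Genes significant in
    opposite directions satisfy both "not" sides; the single-label
    ``category`` column marks them ``discordant`` while the boolean
    per-label columns keep both memberships.

    Returns a DataFrame indexed by gene_id with one boolean column per
    label plus ``category``.
    """
    if lfc_min_a4 is None:
        lfc_min_a4 = lfc_min
    b1 = _side_flags(b1_de, p_max, lfc_min)
    a4 = _side_flags(a4_de, p_max, lfc_min_a4)
    genes = sorted(set(b1.index) | set(a4.index))
    b1 = b1.reindex(genes, fill_value=False)
    a4 = a4.reindex(genes, fill_value=False)

    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["core-esBAF-repressed"] = b1["repressed"] & a4["repressed"]
    out["core-esBAF-activated"] = b1["activated"] & a4["activated"]
    out["B1-repressed-not-A4"] = b1["repressed"] & ~a4["repressed"]
    out["B1-activated-not-A4"] = b1["activated"] & ~a4["activated"]
    out["A4-repressed-not-B1"] = a4["repressed"] & ~b1["repressed"]
    out["A4-activated-not-B1"] = a4["activated"] & ~b1["activated"]

    discordant = (b1["repressed"] & a4["activated"]) | (
        b1["activated"] & a4["repressed"]
    )

    def _label(g: str) -> str:
        if discordant[g]:
            return "discordant"
        for lab in SIX_WAY_LABELS:
            if out.at[g, lab]:
                return lab
        return "none"

    out["category"] = [_label(g) for g in genes]
    return out


def heatmap_matrix(
    b1_de: pd.DataFrame,
    a4_de: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 0.58,
) -> pd.DataFrame:
    """Gene x 2 log2FC matrix with zero substitution.

    Included genes have padj < ``p_max`` in at least one table.  A cell
    keeps its table's log2FC unless padj > ``p_max`` or
    |log2FC| < ``lfc_min`` there, in which case it becomes 0.  Rows are
    ordered by descending first-column value, then descending second
    column, then gene id — deterministic, no clustering.
    """
    b1 = _validate_de(b1_de).set_index("gene_id")
    a4 = _validate_de(a4_de).set_index("gene_id")

    def _cell(table: pd.DataFrame, gene: str) -> float:
        if gene not in table.index:
            return 0.0
        padj = table.at[gene, "padj"]
        lfc = float(table.at[gene, "log2FC"])
        if pd.isna(padj) or float(padj) > p_max or abs(lfc) < lfc_min:
            return 0.0
        return lfc

    def _sig_genes(table: pd.DataFrame) -> set[str]:
        padj = pd.to_numeric(table["padj"], errors="coerce")
        return set(table.index[padj.notna() & (padj < p_max)])

    genes = sorted(_sig_genes(b1) | _sig_genes(a4))
    mat = pd.DataFrame(
        {
            "smarcb1_kd_log2FC": [_cell(b1, g) for g in genes],
            "smarca4_kd_log2FC": [_cell(a4, g) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return mat.sort_values(
        ["smarcb1_kd_log2FC", "smarca4_kd_log2FC", "gene_id"],
        ascending=[False, False, True],
    )
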