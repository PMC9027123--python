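"""Enhancer extension, binding fractions and nearest-gene linkage.

Enhancer catalogues arrive as 1 bp anchor points (wider intervals are
collapsed to their centre first).  Each anchor is extended to a 3001 bp
interval centred on it, overlapped with the classified Smarca4 peak
sets, linked to its nearest gene within a 100 kb cap, and summarised:
per differential class at the enhancer, what fraction of the linked,
significantly changed genes goes up versus down — side by side with the
same summary over gene-region memberships.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation import GeneModel
from .intervals import GenomicInterval, IntervalSet, nearest, overlap
from .peaks import ClassifiedPeakSet

__all__ = [
    "EnhancerRecord",
    "extend_enhancers",
    "binding_fractions",
    "link_and_summarise",
]

DEFAULT_EXTENSION = 3001
DEFAULT_CAP = 100_000


@dataclass
class EnhancerRecord:
    """One enhancer after extension, classification and linkage."""

    enhancer_id: str
    anchor: GenomicInterval          # the original 1 bp point
    extended: GenomicInterval        # 3001 bp centred interval
    clipped: bool
    nearest_gene: Optional[str] = None
    distance: Optional[int] = None
    bound_ctrl: bool = False
    bound_kd: bool = False
    smarca4_class: Optional[str] = None  # DECREASE | INCREASE | None


def _collapse_to_anchor(iv: GenomicInterval) -> GenomicInterval:
    """Centre-collapse a wider interval to its 1 bp midpoint."""
    if len(iv) == 1:
        return iv
    mid = (iv.start + iv.end - 1) // 2
    return GenomicInterval(iv.chrom, mid, mid + 1, name=iv.name)


def extend_enhancers(
    anchors: IntervalSet,
    length: int = DEFAULT_EXTENSION,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> list[EnhancerRecord]:
    """Extend each anchor to an odd ``length`` centred on it.

    An anchor at 0-based position c becomes [c - length//2,
    c + length//2 + 1).  Intervals truncated at a chromosome edge are
    flagged ``clipped``.  Anchors wider than 1 bp are centre-collapsed
    first.  An even length has no centre and is rejected.
    """
    if length < 1 or length % 2 == 0:
        raise ValueError("extension length must be odd and >= 1")
    half = length // 2
    records = []
    for i, iv in enumerate(anchors, 1):
        anchor = _collapse_to_anchor(iv)
        c = anchor.start
        start, end = c - half, c + half + 1
        clipped = start < 0
        start = max(0, start)
        if chrom_lengths is not None and end > chrom_lengths[anchor.chrom]:
            end = chrom_lengths[anchor.chrom]
            clipped = True
        eid = anchor.name or f"enh{i:03d}"
        records.append(
            EnhancerRecord(
                eid,
                anchor,
                GenomicInterval(anchor.chrom, start, end, name=eid),
                clipped,
            )
        )
    return records


def binding_fractions(
    enhancers: Sequence[EnhancerRecord],
    peak_sets: Mapping[str, IntervalSet],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Fraction of enhancers overlapped by each peak set.

    ``peak_sets`` maps a label (condition or class) to the intervals of
    the corresponding Smarca4 peaks.  Returns one row per label with
    the bound count, total and fraction (the exact ratio is recoverable
    from the integer columns).
    """
    if not enhancers:
        raise ValueError("binding_fractions needs >= 1 enhancer")
    ext = IntervalSet(e.extended for e in enhancers)
    rows = []
    for label in sorted(peak_sets):
        hits = {p.a.name for p in overlap(ext, peak_sets[label], min_overlap)}
        rows.append(
            {
                "peak_set": label,
                "bound": len(hits),
                "total": len(enhancers),
                "fraction": len(hits) / len(enhancers),
            }
        )
    return pd.DataFrame(rows, columns=["peak_set", "bound", "total", "fraction"])


def _classify_enhancer(
    record: EnhancerRecord, classified: ClassifiedPeakSet, min_overlap: int
) -> Optional[str]:
    """Differential class at the enhancer by larger bp overlap; exact
    ties stay unclassified."""
    best = {}
    for label in ("DECREASE", "INCREASE"):
        ivs = classified.class_intervals(label)
        best[label] = max(
            (record.extended.intersection_length(iv) for iv in ivs.on(record.extended.chrom)),
            default=0,
        )
    dec, inc = best["DECREASE"], best["INCREASE"]
    if max(dec, inc) < min_overlap or dec == inc:
        return None
    return "DECREASE" if dec > inc else "INCREASE"


def link_and_summarise(
    enhancers: Sequence[EnhancerRecord],
    genes: Sequence[GeneModel],
    de_table: pd.DataFrame,
    classified_smarca4: ClassifiedPeakSet,
    gene_membership: Optional[pd.DataFrame] = None,
    cap: int = DEFAULT_CAP,
    alpha: float = 0.05,
    lfc_min: float = 0.58,
    min_overlap: int = 1,
) -> tuple[list[EnhancerRecord], pd.DataFrame]:
    """Link enhancers to their nearest gene and summarise expression.

    Mutates and returns the enhancer records (class, binding flags,
    linkage) plus a summary table: per region type (enhancer, and gene
    if ``gene_membership`` is given) and differential Smarca4 class,
    the up/down fractions of linked significantly changed genes.
    Classes with no linked significant gene are reported with zero
    counts and absent (NA) fractions.
    """
    from .integration import filter_de

    ext = IntervalSet(e.extended for e in enhancers)
    gene_ivs = IntervalSet(g.interval for g in genes)
    hits = {h.query.name: h for h in nearest(ext, gene_ivs, cap)}

    ctrl_ivs = classified_smarca4.class_intervals("ctrl")
    kd_ivs = classified_smarca4.class_intervals("kd")
    bound_ctrl = {p.a.name for p in overlap(ext, ctrl_ivs, min_overlap)}
    bound_kd = {p.a.name for p in overlap(ext, kd_ivs, min_overlap)}

    for e in enhancers:
        h = hits.get(e.enhancer_id)
        if h is not None and h.subject is not None:
            e.nearest_gene, e.distance = h.subject.name, h.distance
        e.bound_ctrl = e.enhancer_id in bound_ctrl
        e.bound_kd = e.enhancer_id in bound_kd
        e.smarca4_class = _classify_enhancer(e, classified_smarca4, min_overlap)

    res = filter_de(de_table, alpha=alpha, lfc_min=lfc_min)
    up = set(res.up["gene_id"])
    down = set(res.down["gene_id"])

    rows = []
    for klass in ("DECREASE", "INCREASE"):
        linked = [
            e.nearest_gene
            for e in enhancers
            if e.smarca4_class == klass and e.nearest_gene is not None
        ]
        n_up = sum(g in up for g in linked)
        n_down = sum(g in down for g in linked)
        n_sig = n_up + n_down
        rows.append(
            {
                "region": "enhancer",
                "smarca4_class": klass,
                "n_linked": len(linked),
                "n_up": n_up,
                "n_down": n_down,
                "frac_up": n_up / n_sig if n_sig else float("nan"),
                "frac_down": n_down / n_sig if n_sig else float("nan"),
            }
        )

    if gene_membership is not None:
        sub = gene_membership[gene_membership["antibody"] == "Smarca4"]
        for klass in ("DECREASE", "INCREASE"):
            member = set(sub[sub["peak_class"] == klass]["gene_id"])
            n_up = len(member & up)
            n_down = len(member & down)
            n_sig = n_up + n_down
            rows.append(
                {
                    "region": "gene",
                    "smarca4_class": klass,
                    "n_linked": len(member),
                    "n_up": n_up,
                    "n_down": n_down,
                    "frac_up": n_up / n_sig if n_sig else float("nan"),
                    "frac_down": n_down / n_sig if n_sig else float("nan"),
                }
            )
    summary = pd.DataFrame(
        rows,
        columns=[
            "region", "smarca4_class", "n_linked", "n_up", "n_down",
            "frac_up", "frac_down",
        ],
    )
    return list(enhancers), summary
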