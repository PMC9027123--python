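"""Strand-aware gene/TSS regions and peak-to-gene assignment.

A *gene region* runs from 1 kb upstream of the transcription start site
(TSS) to the transcription end site (TES); a *TSS region* is the TSS
+/- 1 kb.  Classified peaks are assigned to every gene whose gene or
TSS region they overlap; peaks hitting neither are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap

__all__ = [
    "GeneModel",
    "AnnotationConfig",
    "gene_regions",
    "tss_regions",
    "assign_peaks",
    "read_genes_bed",
    "write_genes_bed",
]

#: peak classes that can appear in a membership table
PEAK_CLASSES = ("ctrl", "kd", "COMMON", "INCREASE", "DECREASE")


@dataclass(frozen=True)
class GeneModel:
    """One gene: a stranded interval with derived TSS and TES.

    On the + strand the TSS is ``start`` and the TES is ``end``; on the
    - strand the TSS is ``end`` and the TES is ``start``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, strand=self.strand, name=self.gene_id
        )


@dataclass(frozen=True)
class AnnotationConfig:
    upstream_pad: int = 1000  # bp added upstream of the TSS to the gene region
    tss_flank: int = 1000     # half-width of the TSS window

    def __post_init__(self) -> None:
        if self.upstream_pad < 0 or self.tss_flank < 0:
            raise ValueError("pads must be >= 0")


def gene_regions(
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> IntervalSet:
    """Gene body extended ``upstream_pad`` bp upstream of the TSS,
    clipped at chromosome bounds."""
    out = []
    for g in genes:
        if g.strand == "+":
            start, end = g.start - cfg.upstream_pad, g.end
        else:
            start, end = g.start, g.end + cfg.upstream_pad
        start = max(0, start)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        out.append(
            GenomicInterval(g.chrom, start, end, strand=g.strand, name=g.gene_id)
        )
    return IntervalSet(out)


def tss_regions(
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> IntervalSet:
    """Window [TSS - flank, TSS + flank) per gene, clipped."""
    out = []
    for g in genes:
        start = max(0, g.tss - cfg.tss_flank)
        end = g.tss + cfg.tss_flank
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if start >= end:  # degenerate after clipping
            continue
        out.append(
            GenomicInterval(g.chrom, start, end, strand=g.strand, name=g.gene_id)
        )
    return IntervalSet(out)


def assign_peaks(
    classified: Mapping[str, "object"],
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    chrom_lengths: Optional[Mapping[str, int]] = None,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Build the gene x antibody x class membership table.

    ``classified`` maps antibody name -> ClassifiedPeakSet (from
    :mod:`chipshift.peaks`).  A peak overlapping the gene region or the
    TSS window of several genes is credited to each of them; a peak
    overlapping neither region of any gene is dropped.  Gene-region and
    TSS hits are not distinguished in the class column; ``via`` records
    which rule(s) fired.

    Returns a DataFrame with columns
    ``gene_id, antibody, peak_class, n_peaks, via``.
    """
    gene_ivs = gene_regions(genes, cfg, chrom_lengths)
    tss_ivs = tss_regions(genes, cfg, chrom_lengths)
    rows: dict[tuple[str, str, str], dict] = {}

    def _credit(antibody: str, peak_class: str, peak_set, via: str) -> None:
        peak_intervals = IntervalSet(p.interval for p in peak_set)
        target = gene_ivs if via == "gene" else tss_ivs
        for pair in overlap(peak_intervals, target, min_overlap=min_overlap):
            key = (pair.b.name, antibody, peak_class)
            row = rows.setdefault(
                key, {"peaks": set(), "via": set()}
            )
            row["peaks"].add((pair.a.chrom, pair.a.start, pair.a.end))
            row["via"].add(via)

    for antibody, cps in classified.items():
        for peak_class, peak_set in (
            ("ctrl", cps.ctrl),
            ("kd", cps.kd),
            ("COMMON", cps.common),
            ("INCREASE", cps.increase),
            ("DECREASE", cps.decrease),
        ):
            _credit(antibody, peak_class, peak_set, "gene")
            _credit(antibody, peak_class, peak_set, "tss")

    records = [
        {
            "gene_id": gene_id,
            "antibody": antibody,
            "peak_class": peak_class,
            "n_peaks": len(row["peaks"]),
            "via": ",".join(sorted(row["via"])),
        }
        for (gene_id, antibody, peak_class), row in rows.items()
    ]
    df = pd.DataFrame(
        records, columns=["gene_id", "antibody", "peak_class", "n_peaks", "via"]
    )
    return df.sort_values(["gene_id", "antibody", "peak_class"]).reset_index(drop=True)


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (name = gene id, strand required)."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{line_no}: gene BED needs 6 columns")
            genes.append(GeneModel(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return genes


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Read ``gene`` features from a minimal GTF.

    GTF coordinates are 1-based closed; they convert to 0-based
    half-open on read.  The gene id is taken from the ``gene_id``
    attribute.
    """
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{line_no}: GTF needs 9 columns")
            if f[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{line_no}: gene feature lacks gene_id")
            genes.append(GeneModel(gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
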