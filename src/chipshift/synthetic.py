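"""Synthetic multi-chromosome genomes with planted, exported ground truth.

The generator builds everything the downstream pipeline consumes — a
gene annotation, enhancer anchors, per-condition ChIP tag sets and a
differential-expression table — from a seeded random stream, and writes
out the planted truth so recovery can be checked exactly:

* per gene and antibody an occupancy class (``none`` / ``stable`` /
  ``gained`` = present only after knockdown / ``lost`` = present only in
  control),
* per gene an expression direction (``up`` / ``down`` / ``null``),
* per enhancer a bound-in status (``control`` / ``kd`` / ``both`` /
  ``neither``) and the gene it is constructed to be nearest to.

Tags are 1 bp positions drawn from a uniform Poisson background plus a
fold-elevated rate over a fixed-width window centred on the TSS (genes)
or anchor (enhancers) of every region flagged occupied for that
antibody and condition.  The input control carries background only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "PlantedTruth",
    "TagSet",
    "PlacementError",
    "EmptyTagSetError",
    "ANTIBODIES",
    "simulate_genome",
    "plant_truth",
    "simulate_chip_tags",
    "simulate_de_table",
    "write_tags_bed",
    "read_tags_bed",
]

#: the five ChIP targets profiled around the knockdown
ANTIBODIES = ("Smarca4", "Ezh2", "H3K27me3", "H3K27ac", "H3K4me3")

OCCUPANCY_CLASSES = ("none", "stable", "gained", "lost")


class PlacementError(ValueError):
    """Genes/enhancers cannot be placed under the spacing constraints."""


class EmptyTagSetError(ValueError):
    """A simulated tag set came out empty."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of the toy genome.

    ``min_gene_spacing`` keeps neighbouring genes far enough apart that
    their TSS-centred enrichment windows can never be joined into one
    island by a broad-mode caller (window 200 / gap 600), so planted
    classes stay separable.  ``enhancer_margin`` keeps anchors away from
    chromosome ends so the 3001 bp extension is never clipped.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chrA": 1_600_000, "chrB": 1_600_000}
    )
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1500, 3000)
    n_enhancers: int = 40
    seed: int = 0
    min_gene_spacing: int = 12_000
    end_margin: int = 2000
    enhancer_margin: int = 2000

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chrom_lengths must be positive")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must satisfy 0 < lo <= hi")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_enhancers < 0:
            raise ValueError("n_enhancers must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth exported by the generator, keyed by gene/enhancer id."""

    occupancy: dict[str, dict[str, str]]   # antibody -> gene_id -> class
    expression: dict[str, str]             # gene_id -> up | down | null
    enhancer_binding: dict[str, str]       # enhancer_id -> control|kd|both|neither
    enhancer_target: dict[str, str]        # enhancer_id -> nearest gene id

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        occ = pd.DataFrame(
            [
                {"gene_id": g, "antibody": ab, "occupancy": c}
                for ab, per_gene in sorted(self.occupancy.items())
                for g, c in sorted(per_gene.items())
            ]
        )
        expr_rows = []
        for g, d in sorted(self.expression.items()):
            expr_rows.append({"id": g, "kind": "gene", "value": d, "target": ""})
        for e, b in sorted(self.enhancer_binding.items()):
            expr_rows.append(
                {
                    "id": e,
                    "kind": "enhancer",
                    "value": b,
                    "target": self.enhancer_target.get(e, ""),
                }
            )
        return occ, pd.DataFrame(expr_rows)


@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    genes: list[GeneModel]
    enhancers: IntervalSet  # 1 bp anchors, names = enhancer ids
    truth: PlantedTruth     # skeleton until plant_truth fills it in


@dataclass
class TagSet:
    """1 bp sequencing-tag positions for one antibody x condition."""

    antibody: str
    condition: str  # control | kd | input
    positions: dict[str, np.ndarray]  # chrom -> sorted int positions

    def __post_init__(self) -> None:
        if self.condition not in ("control", "kd", "input"):
            raise ValueError(f"bad condition {self.condition!r}")

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def on(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))


def _place_on_chrom(
    rng: np.random.Generator,
    length: int,
    lengths: np.ndarray,
    spacing: int,
    margin: int,
) -> np.ndarray:
    """Starts for non-overlapping genes with pairwise gaps >= spacing."""
    n = len(lengths)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    free = length - 2 * margin - int(lengths.sum()) - (n - 1) * spacing
    if free < 0:
        raise PlacementError(
            f"cannot fit {n} genes (total {lengths.sum()} bp, spacing {spacing}) "
            f"on a {length} bp chromosome"
        )
    # split the leftover space over n+1 slack slots
    w = rng.random(n + 1)
    slack = np.floor(free * np.cumsum(w) / w.sum()).astype(np.int64)
    starts = np.empty(n, dtype=np.int64)
    pos = margin
    for i in range(n):
        pos += slack[i] - (slack[i - 1] if i else 0)
        starts[i] = pos
        pos += int(lengths[i]) + spacing
    return starts


def simulate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Place genes and enhancer anchors; return a truth skeleton.

    Genes are laid out constructively with guaranteed spacing, so the
    only failure mode is a genome too small for the request.  Each
    enhancer anchor is placed 3–5.5 kb to the left of a dedicated gene's
    padded region, which (under the spacing constraint) makes that gene
    its unique nearest gene well inside the 100 kb linkage cap.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(spec.chrom_lengths)
    total_len = sum(spec.chrom_lengths.values())
    # apportion genes to chromosomes proportionally to length
    counts = {
        c: int(round(spec.n_genes * spec.chrom_lengths[c] / total_len)) for c in chroms
    }
    drift = spec.n_genes - sum(counts.values())
    counts[chroms[0]] += drift

    lo, hi = spec.gene_length_range
    genes: list[GeneModel] = []
    idx = 1
    for chrom in chroms:
        n = counts[chrom]
        lengths = rng.integers(lo, hi + 1, size=n)
        starts = _place_on_chrom(
            rng, spec.chrom_lengths[chrom], lengths, spec.min_gene_spacing,
            spec.end_margin,
        )
        strands = rng.choice(["+", "-"], size=n)
        for s, ln, st in zip(starts, lengths, strands):
            genes.append(GeneModel(f"gene{idx:04d}", chrom, int(s), int(s + ln), st))
            idx += 1

    enhancers = _place_enhancers(rng, spec, genes)

    skeleton = PlantedTruth(
        occupancy={ab: {g.gene_id: "none" for g in genes} for ab in ANTIBODIES},
        expression={g.gene_id: "null" for g in genes},
        enhancer_binding={iv.name: "neither" for iv in enhancers},
        # nearest gene per anchor, fixed at construction time
        enhancer_target=dict(getattr(enhancers, "_targets", {})),
    )
    return SyntheticGenome(spec, genes, enhancers, skeleton)


def _place_enhancers(
    rng: np.random.Generator, spec: SyntheticGenomeSpec, genes: Sequence[GeneModel]
) -> IntervalSet:
    if spec.n_enhancers == 0:
        s = IntervalSet([])
        s._targets = {}  # type: ignore[attr-defined]
        return s
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.start)
    # candidates: genes whose left flank can host an anchor at 3-5.5 kb
    # from the padded gene region while staying strictly nearer to the
    # target's gene body than to the previous gene's body
    candidates: list[tuple[GeneModel, int]] = []
    for chrom, gs in sorted(by_chrom.items()):
        for i, g in enumerate(gs):
            left_body = gs[i - 1].end if i else 0
            gap = g.start - left_body
            # anchor at g.start - 1000 - d: target distance ~ 1000 + d,
            # previous-gene distance = gap - 1000 - d; the 1200 bp slack
            # keeps the target strictly nearest and the 3001 bp
            # extension clear of both padded gene regions
            d_max = min(5500, gap // 2 - 1200)
            if d_max < 3000:
                continue
            if g.start - 1000 - d_max - 1501 < spec.enhancer_margin and i == 0:
                continue
            candidates.append((g, d_max))
    if len(candidates) < spec.n_enhancers:
        raise PlacementError(
            f"only {len(candidates)} genes can host an enhancer; "
            f"{spec.n_enhancers} requested"
        )
    chosen_idx = rng.choice(len(candidates), size=spec.n_enhancers, replace=False)
    anchors = []
    targets: dict[str, str] = {}
    for j, ci in enumerate(sorted(chosen_idx), 1):
        g, d_max = candidates[ci]
        d = int(rng.integers(3000, d_max + 1))
        pos = g.start - 1000 - d
        eid = f"enh{j:03d}"
        anchors.append(GenomicInterval(g.chrom, pos, pos + 1, name=eid))
        targets[eid] = g.gene_id
    s = IntervalSet(anchors)
    s._targets = targets  # type: ignore[attr-defined]
    return s


# ---------------------------------------------------------------------------
# planted truth

#: default occupancy mix for the Smarca4 track
SMARCA4_CLASS_P = {"none": 0.45, "stable": 0.25, "gained": 0.15, "lost": 0.15}


def plant_truth(
    genome: SyntheticGenome,
    seed: int,
    smarca4_class_p: Mapping[str, float] = SMARCA4_CLASS_P,
    p_up_given_gained: float = 0.7,
    p_direction_background: float = 0.05,
) -> PlantedTruth:
    """Fill the truth skeleton with correlated occupancy and expression.

    The planted structure mirrors the biology the pipeline is meant to
    resolve: genes losing Smarca4 after knockdown are downregulated;
    genes gaining Smarca4 are mostly upregulated, with a minority
    downregulated (the "unexpectedly repressed despite more BAF
    binding" group).  Activating marks (H3K27ac, H3K4me3) follow the
    expression direction, repressive ones (Ezh2, H3K27me3) oppose it.
    Enhancer binding is derived from the target gene's direction: a
    downregulated target gets a control-only (lost) enhancer, an
    upregulated one a kd-only (gained) enhancer.
    """
    rng = np.random.default_rng(seed)
    truth = genome.truth
    gene_ids = [g.gene_id for g in genome.genes]

    classes = list(smarca4_class_p)
    probs = np.array([smarca4_class_p[c] for c in classes], dtype=float)
    probs /= probs.sum()
    a4 = rng.choice(classes, size=len(gene_ids), p=probs)
    for g, c in zip(gene_ids, a4):
        truth.occupancy["Smarca4"][g] = str(c)

    for g, c in zip(gene_ids, a4):
        if c == "lost":
            truth.expression[g] = "down"
        elif c == "gained":
            truth.expression[g] = (
                "up" if rng.random() < p_up_given_gained else "down"
            )
        else:
            r = rng.random()
            if r < p_direction_background:
                truth.expression[g] = "up"
            elif r < 2 * p_direction_background:
                truth.expression[g] = "down"
            else:
                truth.expression[g] = "null"

    act = {"up": "gained", "down": "lost", "null": None}
    rep = {"up": "lost", "down": "gained", "null": None}
    flip = {"gained": "lost", "lost": "gained"}
    for ab, rule in (
        ("H3K27ac", act), ("H3K4me3", act), ("Ezh2", rep), ("H3K27me3", rep)
    ):
        for g, a4_class in zip(gene_ids, a4):
            direction = truth.expression[g]
            planted = rule[direction]
            # the retargeted-complex group: genes downregulated despite
            # *more* Smarca4 binding carry the opposite histone/PRC2
            # pattern to canonically silenced genes
            if direction == "down" and a4_class == "gained" and planted:
                planted = flip[planted]
            if planted is not None and rng.random() < 0.6:
                truth.occupancy[ab][g] = planted
            elif rng.random() < 0.3:
                truth.occupancy[ab][g] = "stable"
            # else: none

    for eid, target in truth.enhancer_target.items():
        direction = truth.expression[target]
        if direction == "down":
            truth.enhancer_binding[eid] = (
                "control" if rng.random() < 0.8 else "both"
            )
        elif direction == "up":
            truth.enhancer_binding[eid] = "kd" if rng.random() < 0.8 else "both"
        else:
            truth.enhancer_binding[eid] = (
                "both" if rng.random() < 0.4 else "neither"
            )
    return truth


# ---------------------------------------------------------------------------
# tag simulation

_GENE_OCC_BY_CONDITION = {
    "control": ("stable", "lost"),
    "kd": ("stable", "gained"),
}
_ENH_OCC_BY_CONDITION = {
    "control": ("both", "control"),
    "kd": ("both", "kd"),
}


def _draw_background(
    rng: np.random.Generator, chrom_lengths: Mapping[str, int], rate: float
) -> dict[str, np.ndarray]:
    out = {}
    for chrom in sorted(chrom_lengths):
        n = rng.poisson(rate * chrom_lengths[chrom])
        out[chrom] = np.sort(rng.integers(0, chrom_lengths[chrom], size=n))
    return out


def simulate_chip_tags(
    genome: SyntheticGenome,
    truth: PlantedTruth,
    antibody: str,
    condition: str,
    seed: int,
    background_rate: float = 0.008,
    enrichment_fold: float = 50.0,
    peak_width: int = 1000,
) -> TagSet:
    """Draw tags for one antibody x condition.

    Background is a homogeneous Poisson process at ``background_rate``
    tags/bp; every occupied window (TSS- or anchor-centred,
    ``peak_width`` bp) receives additional tags at
    ``background_rate * (enrichment_fold - 1)`` tags/bp so its total
    density is ``enrichment_fold``-fold the background.  Enhancer-anchor
    enrichment applies to the Smarca4 track only.  ``condition='input'``
    yields background alone.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    if background_rate <= 0:
        raise ValueError("background_rate must be > 0")
    rng = np.random.default_rng(seed)
    chrom_lengths = genome.spec.chrom_lengths
    positions = _draw_background(rng, chrom_lengths, background_rate)

    if condition != "input":
        centres: list[tuple[str, int]] = []
        wanted = _GENE_OCC_BY_CONDITION[condition]
        for g in genome.genes:
            if truth.occupancy[antibody][g.gene_id] in wanted:
                centres.append((g.chrom, g.tss))
        if antibody == "Smarca4":
            e_wanted = _ENH_OCC_BY_CONDITION[condition]
            for iv in genome.enhancers:
                if truth.enhancer_binding[iv.name] in e_wanted:
                    centres.append((iv.chrom, iv.start))
        extra_rate = background_rate * (enrichment_fold - 1.0)
        half = peak_width // 2
        extra: dict[str, list[np.ndarray]] = {}
        for chrom, c in centres:
            n = rng.poisson(extra_rate * peak_width)
            lo = max(0, c - half)
            hi = min(chrom_lengths[chrom], c - half + peak_width)
            extra.setdefault(chrom, []).append(rng.integers(lo, hi, size=n))
        for chrom, chunks in extra.items():
            positions[chrom] = np.sort(
                np.concatenate([positions[chrom], *chunks])
            )

    ts = TagSet(antibody if condition != "input" else "input", condition, positions)
    if ts.total == 0:
        raise EmptyTagSetError(
            f"no tags drawn for {antibody}/{condition}; raise background_rate"
        )
    return ts


def simulate_de_table(
    truth: PlantedTruth,
    seed: int,
    effect_size_log2: float = 2.0,
    null_sd: float = 0.2,
) -> pd.DataFrame:
    """DESeq2-style table (gene_id, log2FC, padj) from planted directions.

    Planted up/down genes get log2FC = +/-effect + Normal(0, null_sd)
    noise and an adjusted p drawn uniformly below 0.05; null genes get
    log2FC ~ Normal(0, null_sd) and padj uniform on [0.05, 1].  Only the
    filter semantics matter downstream, so p-values are assigned by
    class rather than fitted from counts.
    """
    if effect_size_log2 <= 0:
        raise ValueError("effect_size_log2 must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id in sorted(truth.expression):
        direction = truth.expression[gene_id]
        noise = rng.normal(0.0, null_sd)
        if direction == "up":
            lfc = effect_size_log2 + noise
            padj = rng.uniform(1e-8, 0.05)
        elif direction == "down":
            lfc = -effect_size_log2 + noise
            padj = rng.uniform(1e-8, 0.05)
        else:
            lfc = noise
            padj = rng.uniform(0.05, 1.0)
        rows.append({"gene_id": gene_id, "log2FC": lfc, "padj": padj})
    return pd.DataFrame(rows, columns=["gene_id", "log2FC", "padj"])


# ---------------------------------------------------------------------------
# tag I/O (BED3; one 1 bp interval per tag)


def write_tags_bed(tags: TagSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tags.positions):
            for p in tags.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


def read_tags_bed(path: str | Path, antibody: str, condition: str) -> TagSet:
    per_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            per_chrom.setdefault(f[0], []).append(int(f[1]))
    positions = {
        c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in sorted(per_chrom.items())
    }
    return TagSet(antibody, condition, positions)
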