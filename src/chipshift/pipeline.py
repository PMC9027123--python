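"""End-to-end orchestration: simulate -> call -> classify -> annotate ->
integrate -> permutation-test -> enhancers -> profiles.

A run is fully determined by its :class:`RunConfig`; a single global
seed deterministically derives one sub-seed per stochastic stage, so
rerunning the same config reproduces every output byte for byte.  Each
stage writes plain-text outputs into the run directory plus a manifest
recording parameters and derived seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation, enhancer, integration, peaks, permutation, profiles
from .intervals import IntervalSet, write_bed
from .synthetic import (
    ANTIBODIES,
    SyntheticGenome,
    SyntheticGenomeSpec,
    TagSet,
    plant_truth,
    simulate_chip_tags,
    simulate_de_table,
    simulate_genome,
    write_tags_bed,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "evaluate_recovery"]

#: island-level cutoffs and caller modes per antibody: narrow for the
#: factors, broad for the histone marks, with the laxer cutoff for the
#: H3K27ac-like broad mark
DEFAULT_ANTIBODY_MODES: dict[str, tuple[str, float]] = {
    "Smarca4": ("narrow", 1e-5),
    "Ezh2": ("narrow", 1e-5),
    "H3K27me3": ("broad", 1e-10),
    "H3K27ac": ("broad", 1e-5),
    "H3K4me3": ("broad", 1e-10),
}


@dataclass
class RunConfig:
    """Flat, YAML-serialisable configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "chipshift_run"
    # synthetic genome
    chrom_lengths: dict = field(
        default_factory=lambda: {"chrA": 1_600_000, "chrB": 1_600_000}
    )
    n_genes: int = 200
    gene_length_range: tuple = (1500, 3000)
    n_enhancers: int = 40
    # tag simulation
    background_rate: float = 0.008
    enrichment_fold: float = 50.0
    peak_width: int = 1000
    # expression simulation
    effect_size_log2: float = 2.0
    null_sd: float = 0.2
    # analysis thresholds
    antibodies: tuple = ANTIBODIES
    de_alpha: float = 0.05
    de_lfc_min: float = 0.58
    n_permutations: int = 100_000
    tail_alpha: float = 0.025
    enhancer_extension: int = 3001
    enhancer_cap: int = 100_000
    profile_halfwidth: int = 2500
    loess_span: float = 0.3
    write_tags: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gene_length_range" in data:
            data["gene_length_range"] = tuple(data["gene_length_range"])
        if "antibodies" in data:
            data["antibodies"] = tuple(data["antibodies"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["gene_length_range"] = list(self.gene_length_range)
        data["antibodies"] = list(self.antibodies)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: RunConfig
    genome: SyntheticGenome
    tags: dict[tuple[str, str], TagSet]
    input_tags: TagSet
    de_table: pd.DataFrame
    classified: dict[str, peaks.ClassifiedPeakSet]
    membership: pd.DataFrame
    de_filter: integration.DEFilterResult
    profiles_merged: pd.DataFrame
    permutation_results: list[permutation.PermutationResult]
    enhancer_records: list[enhancer.EnhancerRecord]
    enhancer_summary: pd.DataFrame
    binding_fractions: pd.DataFrame
    summary: dict


def _stage_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds, each < 2**31."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _caller_config(antibody: str) -> peaks.PeakCallingConfig:
    mode, cutoff = DEFAULT_ANTIBODY_MODES.get(antibody, ("broad", 1e-10))
    if mode == "narrow":
        return peaks.PeakCallingConfig.narrow(p_cutoff=cutoff)
    return peaks.PeakCallingConfig.broad(p_cutoff=cutoff)


def run_pipeline(cfg: RunConfig, outdir: Optional[str | Path] = None) -> PipelineResult:
    """Execute every stage and write all outputs under ``outdir``."""
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    n_tag_seeds = 2 * len(cfg.antibodies) + 1
    seeds = _stage_seeds(cfg.seed, 3 + n_tag_seeds + 1)
    genome_seed, truth_seed, de_seed = seeds[0], seeds[1], seeds[2]
    tag_seeds = seeds[3 : 3 + n_tag_seeds]
    perm_seed = seeds[3 + n_tag_seeds]

    # --- simulate -----------------------------------------------------
    spec = SyntheticGenomeSpec(
        chrom_lengths=dict(cfg.chrom_lengths),
        n_genes=cfg.n_genes,
        gene_length_range=tuple(cfg.gene_length_range),
        n_enhancers=cfg.n_enhancers,
        seed=genome_seed,
    )
    genome = simulate_genome(spec)
    truth = plant_truth(genome, seed=truth_seed)
    chrom_lengths = dict(spec.chrom_lengths)

    tags: dict[tuple[str, str], TagSet] = {}
    si = 0
    for ab in cfg.antibodies:
        for cond in ("control", "kd"):
            tags[(ab, cond)] = simulate_chip_tags(
                genome, truth, ab, cond, seed=tag_seeds[si],
                background_rate=cfg.background_rate,
                enrichment_fold=cfg.enrichment_fold,
                peak_width=cfg.peak_width,
            )
            si += 1
    input_tags = simulate_chip_tags(
        genome, truth, "input", "input", seed=tag_seeds[si],
        background_rate=cfg.background_rate,
        enrichment_fold=cfg.enrichment_fold,
        peak_width=cfg.peak_width,
    )
    de_table = simulate_de_table(
        truth, seed=de_seed,
        effect_size_log2=cfg.effect_size_log2, null_sd=cfg.null_sd,
    )

    annotation.write_genes_bed(genome.genes, out / "genes.bed")
    write_bed(genome.enhancers, out / "enhancer_anchors.bed")
    de_table.to_csv(out / "de_table.tsv", sep="\t", index=False, float_format="%.6g")
    occ, other = truth.to_frames()
    occ.to_csv(out / "truth_occupancy.tsv", sep="\t", index=False)
    other.to_csv(out / "truth_expression_enhancers.tsv", sep="\t", index=False)
    if cfg.write_tags:
        for (ab, cond), ts in tags.items():
            write_tags_bed(ts, out / f"tags_{ab}_{cond}.bed")
        write_tags_bed(input_tags, out / "tags_input.bed")

    # --- peak calling + classification --------------------------------
    classified: dict[str, peaks.ClassifiedPeakSet] = {}
    for ab in cfg.antibodies:
        ccfg = _caller_config(ab)
        ctrl = peaks.call_islands(tags[(ab, "control")], input_tags, ccfg, chrom_lengths)
        kd = peaks.call_islands(tags[(ab, "kd")], input_tags, ccfg, chrom_lengths)
        dec = peaks.call_differential(
            tags[(ab, "control")], tags[(ab, "kd")], ccfg, chrom_lengths
        )
        inc = peaks.call_differential(
            tags[(ab, "kd")], tags[(ab, "control")], ccfg, chrom_lengths
        )
        classified[ab] = peaks.classify(ab, ctrl, kd, dec, inc)
        for label, recs in (
            ("ctrl", ctrl), ("kd", kd),
            ("COMMON", classified[ab].common),
            ("DECREASE", classified[ab].decrease),
            ("INCREASE", classified[ab].increase),
        ):
            peaks.write_peaks_bed(recs, out / f"peaks_{ab}_{label}.bed", label)

    # --- annotation + integration --------------------------------------
    membership = annotation.assign_peaks(
        classified, genome.genes, chrom_lengths=chrom_lengths
    )
    membership.to_csv(out / "membership.tsv", sep="\t", index=False)
    de_filter = integration.filter_de(de_table, cfg.de_alpha, cfg.de_lfc_min)
    merged = integration.merge_expression_binding(
        de_table, membership, cfg.de_alpha, cfg.de_lfc_min
    )
    merged.to_csv(out / "gene_binding_profiles.tsv", sep="\t", index=False,
                  float_format="%.6g")

    # --- permutation tests ---------------------------------------------
    perm_cfg = permutation.PermutationConfig(
        n_permutations=cfg.n_permutations, tail_alpha=cfg.tail_alpha,
        seed=perm_seed,
    )
    other_abs = [ab for ab in cfg.antibodies if ab != "Smarca4"]
    try:
        d_group, i_group = permutation.build_basic_set(
            de_filter.down["gene_id"],
            membership[membership["antibody"] == "Smarca4"],
        )
        perm_results = permutation.run_permutation_suite(
            d_group, i_group, membership, other_abs, perm_cfg
        )
    except permutation.EmptyBasicSetError:
        d_group, i_group, perm_results = [], [], []
    permutation.results_frame(perm_results).to_csv(
        out / "permutation_results.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # --- enhancers -------------------------------------------------------
    enh_records = enhancer.extend_enhancers(
        genome.enhancers, cfg.enhancer_extension, chrom_lengths
    )
    a4 = classified.get("Smarca4")
    if a4 is not None and enh_records:
        fractions = enhancer.binding_fractions(
            enh_records,
            {
                "control": a4.class_intervals("ctrl"),
                "kd": a4.class_intervals("kd"),
                "DECREASE": a4.class_intervals("DECREASE"),
                "INCREASE": a4.class_intervals("INCREASE"),
            },
        )
        enh_records, enh_summary = enhancer.link_and_summarise(
            enh_records, genome.genes, de_table, a4,
            gene_membership=membership, cap=cfg.enhancer_cap,
            alpha=cfg.de_alpha, lfc_min=cfg.de_lfc_min,
        )
    else:
        fractions = pd.DataFrame(
            columns=["peak_set", "bound", "total", "fraction"]
        )
        enh_summary = pd.DataFrame()
    fractions.to_csv(out / "enhancer_binding_fractions.tsv", sep="\t", index=False,
                     float_format="%.6g")
    enh_summary.to_csv(out / "enhancer_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")

    # --- profiles --------------------------------------------------------
    for ab in cfg.antibodies:
        recs = classified[ab].ctrl
        if not recs:
            continue
        centres = profiles.peak_centres([p.interval for p in recs])
        mat = profiles.coverage_matrix(
            tags[(ab, "control")], centres, cfg.profile_halfwidth
        )
        prof = profiles.average_and_smooth(mat, span=cfg.loess_span)
        prof.to_tsv(out / f"profile_{ab}_control.tsv")

    # --- summary + manifest ----------------------------------------------
    summary = {
        "n_genes": len(genome.genes),
        "n_enhancers": len(genome.enhancers),
        "de_up": int(len(de_filter.up)),
        "de_down": int(len(de_filter.down)),
        "peaks": {
            ab: {
                "ctrl": len(classified[ab].ctrl),
                "kd": len(classified[ab].kd),
                "COMMON": len(classified[ab].common),
                "INCREASE": len(classified[ab].increase),
                "DECREASE": len(classified[ab].decrease),
            }
            for ab in cfg.antibodies
        },
        "basic_set": {"DECREASE": len(d_group), "INCREASE": len(i_group)},
        "n_permutation_tests": len(perm_results),
        "n_significant": sum(r.tier != "none" for r in perm_results),
        "n_highly_significant": sum(
            r.tier == "highly-significant" for r in perm_results
        ),
        "enhancer_fraction_bound": {
            str(row.peak_set): round(float(row.fraction), 6)
            for row in fractions.itertuples()
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "config": {**asdict(cfg),
                   "gene_length_range": list(cfg.gene_length_range),
                   "antibodies": list(cfg.antibodies)},
        "derived_seeds": {
            "genome": genome_seed, "truth": truth_seed, "de": de_seed,
            "tags": tag_seeds, "permutation": perm_seed,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        config=cfg, genome=genome, tags=tags, input_tags=input_tags,
        de_table=de_table, classified=classified, membership=membership,
        de_filter=de_filter, profiles_merged=merged,
        permutation_results=perm_results, enhancer_records=enh_records,
        enhancer_summary=enh_summary, binding_fractions=fractions,
        summary=summary,
    )


_EXPECTED_CLASS = {"stable": "COMMON", "gained": "INCREASE", "lost": "DECREASE"}


def evaluate_recovery(result: PipelineResult) -> dict:
    """Compare recovered classifications against the planted truth.

    For every gene x antibody the recovered differential-class set
    ({COMMON, INCREASE, DECREASE} memberships) must equal the planted
    class; DE directions must match planted directions after filtering;
    every enhancer must link to its construction-time nearest gene with
    the correct binding flags and differential class.  Returns per-
    aspect match counts and overall precision/recall of planted
    (non-none) occupancy classes.
    """
    genome = result.genome
    truth = genome.truth
    membership = result.membership

    by_gene_ab: dict[tuple[str, str], set[str]] = {}
    for row in membership.itertuples():
        if row.peak_class in ("COMMON", "INCREASE", "DECREASE"):
            by_gene_ab.setdefault((row.gene_id, row.antibody), set()).add(
                row.peak_class
            )

    occ_total = occ_match = 0
    tp = fp = fn = 0
    for ab, per_gene in truth.occupancy.items():
        if ab not in result.classified:
            continue
        for gene_id, planted in per_gene.items():
            recovered = by_gene_ab.get((gene_id, ab), set())
            expected = (
                {_EXPECTED_CLASS[planted]} if planted != "none" else set()
            )
            occ_total += 1
            if recovered == expected:
                occ_match += 1
            if planted != "none":
                if recovered == expected:
                    tp += 1
                else:
                    fn += 1
            elif recovered:
                fp += 1

    de_truth_up = {g for g, d in truth.expression.items() if d == "up"}
    de_truth_down = {g for g, d in truth.expression.items() if d == "down"}
    de_up = set(result.de_filter.up["gene_id"])
    de_down = set(result.de_filter.down["gene_id"])

    enh_ok = 0
    for e in result.enhancer_records:
        planted = truth.enhancer_binding[e.enhancer_id]
        target = truth.enhancer_target[e.enhancer_id]
        want_ctrl = planted in ("control", "both")
        want_kd = planted in ("kd", "both")
        want_class = {"control": "DECREASE", "kd": "INCREASE"}.get(planted)
        if (
            e.nearest_gene == target
            and e.bound_ctrl == want_ctrl
            and e.bound_kd == want_kd
            and e.smarca4_class == want_class
        ):
            enh_ok += 1

    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return {
        "occupancy_pairs": occ_total,
        "occupancy_matched": occ_match,
        "occupancy_precision": precision,
        "occupancy_recall": recall,
        "de_up_match": de_up == de_truth_up,
        "de_down_match": de_down == de_truth_down,
        "enhancers_total": len(result.enhancer_records),
        "enhancers_matched": enh_ok,
    }
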