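"""Window/gap island peak calling with Poisson enrichment.

One generic two-stage caller covers both use cases:

* *standard* peaks — a condition's tags against its input control;
* *differential* peaks — one condition's tags against the other
  condition standing in as the control.

The genome is tiled in fixed windows; a window is *eligible* when its
tag count is Poisson-improbable given the library-size-scaled control
expectation; eligible windows joined across gaps up to ``gap`` bp form
islands; each island is then scored as a whole and kept only if its
Poisson upper-tail p-value beats the island-level cutoff.  Regions are
finally classified as COMMON (standard peaks in both conditions),
DECREASE (control standard peak + control-over-kd differential peak) or
INCREASE (kd standard peak + kd-over-control differential peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalSet
from .synthetic import TagSet

__all__ = [
    "PeakCallingConfig",
    "PeakRecord",
    "ClassifiedPeakSet",
    "poisson_upper_tail",
    "bin_tags",
    "call_islands",
    "call_differential",
    "classify",
    "write_peaks_bed",
]


@dataclass(frozen=True)
class PeakCallingConfig:
    """Caller parameters.

    ``broad`` mode (window 200 bp, gap 600 bp) suits histone marks;
    ``narrow`` mode (window 50 bp, gap 0) suits transcription factors.
    ``p_cutoff`` is the island-level threshold: 1e-5 for H3K27ac-like
    broad marks and narrow-mode factors, 1e-10 for the remaining broad
    histone marks.  ``eligibility_p`` gates single windows before island
    aggregation; ``pseudocount`` (tags/window, control side) keeps the
    Poisson rate positive for empty control windows.
    """

    window: int = 200
    gap: int = 600
    p_cutoff: float = 1e-10
    mode: str = "broad"
    pseudocount: float = 0.25
    eligibility_p: float = 0.01
    #: span (bp) of the local background estimate: the control rate per
    #: window is max(own count, local mean) so a downward-fluctuating
    #: control window cannot fake an enrichment — the usual local-lambda
    #: guard of two-sample peak comparisons
    local_background_bp: int = 1000
    #: minimum number of eligible windows per island; differential
    #: (two-sample) calls require 2 because a single window is pure
    #: shot noise while any real occupancy change spans at least a
    #: fragment length
    min_eligible_windows: int = 1
    min_eligible_windows_diff: int = 2

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not (0 < self.p_cutoff < 1):
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.mode not in ("broad", "narrow"):
            raise ValueError("mode must be 'broad' or 'narrow'")

    @classmethod
    def broad(cls, p_cutoff: float = 1e-10) -> "PeakCallingConfig":
        return cls(window=200, gap=600, p_cutoff=p_cutoff, mode="broad")

    @classmethod
    def narrow(cls, p_cutoff: float = 1e-5) -> "PeakCallingConfig":
        return cls(window=50, gap=0, p_cutoff=p_cutoff, mode="narrow")


@dataclass(frozen=True)
class PeakRecord:
    """A called island: interval, tag count, control expectation, p."""

    interval: GenomicInterval
    count: int
    expected: float
    pvalue: float


@dataclass
class ClassifiedPeakSet:
    """Per-antibody standard peaks plus the derived differential classes."""

    antibody: str
    ctrl: list[PeakRecord]
    kd: list[PeakRecord]
    common: list[PeakRecord] = field(default_factory=list)
    increase: list[PeakRecord] = field(default_factory=list)
    decrease: list[PeakRecord] = field(default_factory=list)
    #: regions qualifying for both classes with tied overlap, dropped
    conflicts: list[PeakRecord] = field(default_factory=list)

    def class_intervals(self, peak_class: str) -> IntervalSet:
        attr = {
            "ctrl": "ctrl", "kd": "kd", "COMMON": "common",
            "INCREASE": "increase", "DECREASE": "decrease",
        }[peak_class]
        return IntervalSet(p.interval for p in getattr(self, attr))


def poisson_upper_tail(count: int | np.ndarray, lam: float | np.ndarray):
    """P(X >= count) for X ~ Poisson(lam), the island enrichment p-value."""
    return stats.poisson.sf(np.asarray(count) - 1, lam)


def bin_tags(
    tags: TagSet,
    window: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> dict[str, np.ndarray]:
    """Counts per fixed non-overlapping window, tiled from position 0.

    A tag at position p falls in window ``p // window``.  With
    ``chrom_lengths`` the count vector covers the whole chromosome;
    otherwise it extends to the last occupied window.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    out: dict[str, np.ndarray] = {}
    chroms = set(tags.positions)
    if chrom_lengths is not None:
        chroms |= set(chrom_lengths)
    for chrom in sorted(chroms):
        pos = tags.on(chrom)
        if chrom_lengths is not None:
            n_win = -(-chrom_lengths[chrom] // window)
            if len(pos) and pos[-1] >= chrom_lengths[chrom]:
                raise ValueError(f"tag beyond {chrom} length")
        else:
            n_win = (int(pos[-1]) // window + 1) if len(pos) else 0
        out[chrom] = np.bincount(pos // window, minlength=n_win).astype(np.int64)
    return out


def local_background(
    counts: np.ndarray, window: int, local_bp: int
) -> np.ndarray:
    """Per-window control rate: max(own count, truncated local mean).

    The local mean runs over ``local_bp`` of sequence centred on the
    window (truncated at chromosome ends).  Taking the max keeps the
    expectation conservative: a control window that randomly dips below
    its neighbourhood cannot create a spurious enrichment call, while
    genuinely signal-free neighbourhoods are unaffected.
    ``local_bp <= window`` disables the smoothing.
    """
    n = len(counts)
    half = int(round(local_bp / window)) // 2
    if half < 1 or n == 0:
        return counts.astype(float)
    csum = np.concatenate([[0], np.cumsum(counts)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    local_mean = (csum[hi] - csum[lo]) / (hi - lo)
    return np.maximum(counts, local_mean)


def _islands_from_eligible(
    eligible_idx: np.ndarray, window: int, gap: int
) -> list[tuple[int, int]]:
    """Group eligible window indices into (first, last) island runs.

    Two eligible windows i < j join the same island when the bp gap
    between them, (j - i - 1) * window, is <= gap.
    """
    if len(eligible_idx) == 0:
        return []
    max_skip = gap // window  # number of ineligible windows that may intervene
    runs = []
    first = last = int(eligible_idx[0])
    n_elig = 1
    for j in eligible_idx[1:]:
        j = int(j)
        if (j - last - 1) <= max_skip:
            last = j
            n_elig += 1
        else:
            runs.append((first, last, n_elig))
            first = last = j
            n_elig = 1
    runs.append((first, last, n_elig))
    return runs


def background_depth_ratio(
    t_counts: Mapping[str, np.ndarray],
    c_counts: Mapping[str, np.ndarray],
    fold_cut: float = 5.0,
) -> float:
    """Effective depth ratio t/c estimated from signal-free windows.

    Total-count scaling is biased for condition-vs-condition
    comparisons: the totals include each condition's own signal mass,
    so regions occupied equally in both conditions would appear
    differential.  Instead the ratio is taken over windows where
    neither sample exceeds ``fold_cut`` times its genome-wide mean
    (plus 3, to keep the cut meaningful at sparse depth) — i.e. over
    the common Poisson background.
    """
    chroms = sorted(set(t_counts) | set(c_counts))
    ts, cs = [], []
    for chrom in chroms:
        tc = t_counts.get(chrom, np.empty(0, dtype=np.int64))
        cc = c_counts.get(chrom, np.empty(0, dtype=np.int64))
        n = max(len(tc), len(cc))
        ts.append(np.pad(tc, (0, n - len(tc))))
        cs.append(np.pad(cc, (0, n - len(cc))))
    t = np.concatenate(ts) if ts else np.empty(0, dtype=np.int64)
    c = np.concatenate(cs) if cs else np.empty(0, dtype=np.int64)
    if len(t) == 0 or t.sum() == 0 or c.sum() == 0:
        return 1.0
    cut_t = fold_cut * t.mean() + 3.0
    cut_c = fold_cut * c.mean() + 3.0
    mask = (t <= cut_t) & (c <= cut_c)
    tb, cb = t[mask].sum(), c[mask].sum()
    if tb == 0 or cb == 0:
        return 1.0
    return float(tb / cb)


def binomial_upper_tail(
    t: int | np.ndarray, c: int | np.ndarray, p0: float
) -> np.ndarray:
    """P(X >= t) for X ~ Binomial(t + c, p0): the conditional
    (exact two-sample Poisson) test of treatment count t against a
    control count c that is itself a noisy sample."""
    t = np.asarray(t)
    return stats.binom.sf(t - 1, t + np.asarray(c), p0)


def call_islands(
    treatment: TagSet,
    control: TagSet,
    cfg: PeakCallingConfig,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    two_sample: bool = False,
) -> list[PeakRecord]:
    """Two-stage island calling of ``treatment`` against ``control``.

    In the default (input-control) mode the control expectation per
    window is ``(background + pseudocount) * scale`` with
    ``scale = treatment_total / control_total`` (1.0 for an empty
    control, leaving the pseudocount alone) and window/island
    significance is the Poisson upper tail at that expectation.

    With ``two_sample=True`` the control is another ChIP condition whose
    counts are just as noisy as the treatment's, so significance uses
    the conditional binomial test instead: under equal rates,
    t | (t + c) ~ Binomial(t + c, T / (T + C)).  A fixed-λ Poisson here
    would treat every control dip as real and overcall small
    differential islands at strongly occupied sites.  The reported
    expectation remains the library-scaled control count.

    Islands with p >= ``cfg.p_cutoff`` are discarded.
    """
    t_counts = bin_tags(treatment, cfg.window, chrom_lengths)
    c_counts = bin_tags(control, cfg.window, chrom_lengths)
    t_total, c_total = treatment.total, control.total
    if c_total == 0:
        two_sample = False  # degenerate: fall back to pseudocount Poisson
    if two_sample:
        # depth ratio from the shared background, not raw totals, so
        # equal occupancy never reads as differential
        scale = background_depth_ratio(t_counts, c_counts)
    else:
        scale = (t_total / c_total) if c_total > 0 else 1.0
    p0 = scale / (1.0 + scale)

    peaks: list[PeakRecord] = []
    for chrom in sorted(t_counts):
        tc = t_counts[chrom]
        cc = c_counts.get(chrom, np.empty(0, dtype=np.int64))
        n = max(len(tc), len(cc))
        if n == 0:
            continue
        tc = np.pad(tc, (0, n - len(tc)))
        cc = np.pad(cc, (0, n - len(cc)))
        lam = (local_background(cc, cfg.window, cfg.local_background_bp)
               + cfg.pseudocount) * scale
        if two_sample:
            pvals = binomial_upper_tail(tc, cc, p0)
        else:
            with np.errstate(divide="ignore"):
                pvals = poisson_upper_tail(tc, lam)
        eligible = np.flatnonzero((tc > 0) & (pvals < cfg.eligibility_p))
        min_elig = (
            cfg.min_eligible_windows_diff if two_sample else cfg.min_eligible_windows
        )
        for first, last, n_elig in _islands_from_eligible(
            eligible, cfg.window, cfg.gap
        ):
            if n_elig < min_elig:
                continue
            start, end = first * cfg.window, (last + 1) * cfg.window
            count = int(tc[first : last + 1].sum())
            expected = float(lam[first : last + 1].sum())
            if two_sample:
                c_span = int(cc[first : last + 1].sum())
                p = float(binomial_upper_tail(count, c_span, p0))
            else:
                p = float(poisson_upper_tail(count, expected))
            if p < cfg.p_cutoff:
                peaks.append(
                    PeakRecord(GenomicInterval(chrom, start, end), count, expected, p)
                )
    return peaks


def call_differential(
    cond_a: TagSet,
    cond_b: TagSet,
    cfg: PeakCallingConfig,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> list[PeakRecord]:
    """Regions enriched in ``cond_a`` over ``cond_b``: the island
    machinery with the other condition standing in for the control,
    scored with the two-sample conditional test."""
    return call_islands(cond_a, cond_b, cfg, chrom_lengths, two_sample=True)


def _overlap_with(
    records: Sequence[PeakRecord], others: Sequence[PeakRecord], min_overlap: int
) -> dict[int, int]:
    """index of record -> max bp overlap with any interval in ``others``."""
    hits: dict[int, int] = {}
    other_ivs = [o.interval for o in others]
    for i, rec in enumerate(records):
        best = 0
        for iv in other_ivs:
            best = max(best, rec.interval.intersection_length(iv))
        if best >= min_overlap:
            hits[i] = best
    return hits


def classify(
    antibody: str,
    ctrl_peaks: Sequence[PeakRecord],
    kd_peaks: Sequence[PeakRecord],
    diff_ctrl_over_kd: Sequence[PeakRecord],
    diff_kd_over_ctrl: Sequence[PeakRecord],
    min_overlap: int = 1,
) -> ClassifiedPeakSet:
    """Derive COMMON / INCREASE / DECREASE from four peak sets.

    DECREASE regions are control standard peaks overlapping a
    control-over-kd differential peak; INCREASE regions are kd standard
    peaks overlapping a kd-over-control differential peak; COMMON
    regions are control standard peaks overlapping a kd standard peak
    (the control interval is reported).  A region qualifying for both
    differential classes keeps the class whose differential peak
    overlaps it by more bp; exact ties are flagged and dropped, so
    INCREASE and DECREASE never overlap.
    """
    dec_hits = _overlap_with(ctrl_peaks, diff_ctrl_over_kd, min_overlap)
    inc_hits = _overlap_with(kd_peaks, diff_kd_over_ctrl, min_overlap)
    common_hits = _overlap_with(ctrl_peaks, kd_peaks, min_overlap)

    decrease = {i: ctrl_peaks[i] for i in dec_hits}
    increase = {i: kd_peaks[i] for i in inc_hits}
    conflicts: list[PeakRecord] = []

    # resolve regions claimed by both classes via overlapping intervals
    drop_dec, drop_inc = set(), set()
    for di, drec in decrease.items():
        for ii, irec in increase.items():
            if drec.interval.intersection_length(irec.interval) >= min_overlap:
                if dec_hits[di] > inc_hits[ii]:
                    drop_inc.add(ii)
                elif dec_hits[di] < inc_hits[ii]:
                    drop_dec.add(di)
                else:
                    drop_dec.add(di)
                    drop_inc.add(ii)
                    conflicts.extend([drec, irec])

    return ClassifiedPeakSet(
        antibody=antibody,
        ctrl=list(ctrl_peaks),
        kd=list(kd_peaks),
        common=[ctrl_peaks[i] for i in sorted(common_hits)],
        increase=[rec for i, rec in sorted(increase.items()) if i not in drop_inc],
        decrease=[rec for i, rec in sorted(decrease.items()) if i not in drop_dec],
        conflicts=conflicts,
    )


def write_peaks_bed(
    peaks: Sequence[PeakRecord], path: str | Path, peak_class: str = "."
) -> None:
    """BED6+ output: name, -log10(p) as score, then count/expected/class."""
    with open(path, "w") as fh:
        for i, p in enumerate(
            sorted(peaks, key=lambda r: (r.interval.chrom, r.interval.start)), 1
        ):
            score = -np.log10(p.pvalue) if p.pvalue > 0 else 999.0
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"peak{i}\t{score:.3f}\t.\t{p.count}\t{p.expected:.4f}\t"
                f"{p.pvalue:.6g}\t{peak_class}\n"
            )
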