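"""Average tag-coverage profiles around peak centres.

For quality control, raw 1 bp tag coverage is gathered in +/-2.5 kb
windows centred on each peak's centre, averaged per offset across peaks
and smoothed with LOESS (locally weighted linear regression, tricube
weights).  Narrow factors should peak sharply at offset 0; broad marks
spread flatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .intervals import GenomicInterval
from .synthetic import TagSet

__all__ = ["CoverageProfile", "coverage_matrix", "average_and_smooth", "peak_centres"]


@dataclass
class CoverageProfile:
    offsets: np.ndarray     # -halfwidth .. +halfwidth, step 1
    mean: np.ndarray        # per-offset mean raw coverage
    smoothed: np.ndarray    # LOESS-smoothed mean
    n_peaks: int
    span: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tmean\tsmoothed\n")
            for o, m, s in zip(self.offsets, self.mean, self.smoothed):
                fh.write(f"{o}\t{m:.6g}\t{s:.6g}\n")


def peak_centres(intervals: Sequence[GenomicInterval]) -> list[tuple[str, int]]:
    """Midpoint (rounded down) of each peak interval."""
    return [(iv.chrom, (iv.start + iv.end) // 2) for iv in intervals]


def coverage_matrix(
    tags: TagSet,
    centres: Sequence[tuple[str, int]],
    halfwidth: int = 2500,
) -> np.ndarray:
    """peaks x offsets matrix; cell (i, o) counts tags at centre_i + o.

    Offsets run -halfwidth..+halfwidth inclusive.  Window positions
    falling outside the chromosome simply collect zero coverage (there
    are no tags there by construction).
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    width = 2 * halfwidth + 1
    mat = np.zeros((len(centres), width), dtype=np.int64)
    for i, (chrom, c) in enumerate(centres):
        pos = tags.on(chrom)
        lo = np.searchsorted(pos, c - halfwidth, side="left")
        hi = np.searchsorted(pos, c + halfwidth, side="right")
        if hi > lo:
            offsets = pos[lo:hi] - (c - halfwidth)
            mat[i] = np.bincount(offsets, minlength=width)
    return mat


def average_and_smooth(matrix: np.ndarray, span: float = 0.3) -> CoverageProfile:
    """Column means followed by LOESS smoothing.

    ``span`` is the LOESS fraction (share of points in each local
    linear fit).  Local-linear smoothing reproduces constant and
    exactly linear mean profiles unchanged.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("need a non-empty peaks x offsets matrix")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    width = matrix.shape[1]
    halfwidth = (width - 1) // 2
    offsets = np.arange(-halfwidth, width - halfwidth)
    mean = matrix.mean(axis=0)
    smoothed = lowess(
        mean, offsets.astype(float), frac=span, it=0, return_sorted=False
    )
    return CoverageProfile(
        offsets=offsets,
        mean=mean,
        smoothed=np.asarray(smoothed),
        n_peaks=matrix.shape[0],
        span=span,
    )
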