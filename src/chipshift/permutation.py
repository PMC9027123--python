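"""Shuffle-null enrichment test for concurrent binding patterns.

The question: among a *basic gene set* (downregulated genes carrying a
differential Smarca4 peak), partitioned into a DECREASE group (size
``n_D``) and an INCREASE group (size ``N - n_D``), is a concurrent
ChIP signal of some other antibody/peak-class combination over- or
under-represented in one group?

The null redistributes the ``k`` signal-carrying genes uniformly over
the ``N`` basic-set genes, splitting each shuffle at the observed
DECREASE/INCREASE ratio and recording the DECREASE-side count ``x*``.
That draw is exactly Hypergeometric(N, k, n_D) — sampled directly, once
per shuffle, independently across shuffles — which scipy's closed form
cross-checks in the tests.  Empirical p-values use add-one smoothing so
they are never zero; an observation more extreme than *every* shuffle
earns the "highly significant" tier.  Significance is Bonferroni-
corrected over the number of combinations tested in a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "EmptyBasicSetError",
    "build_basic_set",
    "count_concurrent",
    "permutation_test",
    "bonferroni_threshold",
    "run_permutation_suite",
]

TESTED_CLASSES = ("ctrl", "kd", "DECREASE", "INCREASE", "COMMON")


class EmptyBasicSetError(ValueError):
    """No gene qualifies for the basic set."""


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1_000_000
    tail_alpha: float = 0.025      # per tail, pre-correction
    n_tests: int = 1               # Bonferroni m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.tail_alpha < 0.5):
            raise ValueError("tail_alpha must be in (0, 0.5)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass(frozen=True)
class PermutationResult:
    antibody: str
    peak_class: str
    partition: str              # which group x_obs counts (DECREASE side)
    n_basic: int                # N
    n_group: int                # group size the count refers to
    k_signal: int               # genes with the signal anywhere in the basic set
    observed: int               # x_obs
    null_mean: float
    p_lower: float              # P(x* <= x_obs), add-one smoothed
    p_upper: float              # P(x* >= x_obs), add-one smoothed
    p_two_sided: float          # min(1, 2 * min(tails))
    direction: str              # positive | negative | none
    tier: str                   # none | significant | highly-significant


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test alpha after Bonferroni correction over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def build_basic_set(
    down_genes: Iterable[str], smarca4_membership: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Split downregulated genes by their differential Smarca4 class.

    The basic set contains downregulated genes with a Smarca4 DECREASE
    or INCREASE membership; genes with only standard/COMMON Smarca4
    signal are excluded.  A gene carrying both differential classes
    (via distinct peaks) is resolved to the class with more supporting
    peaks and dropped on a tie.  Returns (D_group, I_group), each
    sorted.
    """
    down = set(down_genes)
    sub = smarca4_membership[
        smarca4_membership["gene_id"].isin(down)
        & smarca4_membership["peak_class"].isin(["DECREASE", "INCREASE"])
    ]
    d_group, i_group = [], []
    for gene, rows in sub.groupby("gene_id"):
        by_class = rows.groupby("peak_class")["n_peaks"].sum()
        n_dec = int(by_class.get("DECREASE", 0))
        n_inc = int(by_class.get("INCREASE", 0))
        if n_dec > n_inc:
            d_group.append(gene)
        elif n_inc > n_dec:
            i_group.append(gene)
        # tie: ambiguous, excluded
    if not d_group and not i_group:
        raise EmptyBasicSetError(
            "no downregulated gene carries a differential Smarca4 peak"
        )
    return sorted(d_group), sorted(i_group)


def count_concurrent(
    group: Iterable[str],
    membership: pd.DataFrame,
    antibody: str,
    peak_class: str,
) -> int:
    """Genes of ``group`` with >= 1 peak of ``antibody`` x ``peak_class``."""
    sub = membership[
        (membership["antibody"] == antibody)
        & (membership["peak_class"] == peak_class)
        & (membership["n_peaks"] > 0)
    ]
    return len(set(group) & set(sub["gene_id"]))


def _null_sample(
    N: int, n_D: int, k: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B shuffles: k labelled genes among N, count of labels in the
    n_D-sized group.  Uniform placement without replacement within each
    shuffle == one hypergeometric draw per shuffle."""
    if k == 0 or n_D == 0:
        return np.zeros(B, dtype=np.int64)
    return rng.hypergeometric(k, N - k, n_D, size=B)


def permutation_test(
    N: int,
    n_D: int,
    k: int,
    x_obs: int,
    cfg: PermutationConfig,
    antibody: str = "",
    peak_class: str = "",
    partition: str = "DECREASE",
    null_sample: Optional[np.ndarray] = None,
) -> PermutationResult:
    """Empirical two-sided test of ``x_obs`` against the shuffle null.

    ``N`` basic-set genes, ``n_D`` in the tested group, ``k`` of them
    carrying the signal, ``x_obs`` signal carriers observed in the
    group.  ``null_sample`` lets a caller reuse one set of shuffles for
    the complementary group so the two results are exactly symmetric.
    """
    if not (0 <= k <= N and 0 <= n_D <= N):
        raise ValueError("need 0 <= k <= N and 0 <= n_D <= N")
    if not (max(0, k - (N - n_D)) <= x_obs <= min(k, n_D)):
        raise ValueError("x_obs outside the feasible range")
    rng = np.random.default_rng(cfg.seed)
    xs = (
        null_sample
        if null_sample is not None
        else _null_sample(N, n_D, k, cfg.n_permutations, rng)
    )
    B = len(xs)
    n_le = int(np.count_nonzero(xs <= x_obs))
    n_ge = int(np.count_nonzero(xs >= x_obs))
    p_lower = (n_le + 1) / (B + 1)
    p_upper = (n_ge + 1) / (B + 1)
    p_two = min(1.0, 2.0 * min(p_lower, p_upper))

    expected = k * n_D / N if N else 0.0
    if x_obs > expected:
        direction = "positive"
    elif x_obs < expected:
        direction = "negative"
    else:
        direction = "none"

    per_tail = bonferroni_threshold(cfg.tail_alpha, cfg.n_tests)
    if x_obs > xs.max() or x_obs < xs.min():
        tier = "highly-significant"
    elif min(p_lower, p_upper) <= per_tail:
        tier = "significant"
    else:
        tier = "none"

    return PermutationResult(
        antibody=antibody,
        peak_class=peak_class,
        partition=partition,
        n_basic=N,
        n_group=n_D,
        k_signal=k,
        observed=x_obs,
        null_mean=float(xs.mean()),
        p_lower=p_lower,
        p_upper=p_upper,
        p_two_sided=p_two,
        direction=direction,
        tier=tier,
    )


def run_permutation_suite(
    d_group: Sequence[str],
    i_group: Sequence[str],
    membership: pd.DataFrame,
    antibodies: Sequence[str],
    cfg: PermutationConfig,
    peak_classes: Sequence[str] = TESTED_CLASSES,
) -> list[PermutationResult]:
    """Test every antibody x peak-class combination over both partitions.

    Bonferroni m is the number of combinations actually tested (one
    null per combination serves both partitions, which makes the
    D-group and I-group results exactly mirror one another).
    Combinations with no signal carrier in the basic set (k = 0) are
    reported with p = 1 and tier none.
    """
    basic = list(d_group) + list(i_group)
    N, n_D = len(basic), len(d_group)
    if N == 0:
        raise EmptyBasicSetError("empty basic set")
    combos = [(ab, pc) for ab in antibodies for pc in peak_classes]
    m = len(combos)
    if m == 0:
        return []
    cfg_m = PermutationConfig(
        n_permutations=cfg.n_permutations,
        tail_alpha=cfg.tail_alpha,
        n_tests=m,
        seed=cfg.seed,
    )
    seeds = np.random.SeedSequence(cfg.seed).spawn(m)
    results = []
    for (ab, pc), ss in zip(combos, seeds):
        k = count_concurrent(basic, membership, ab, pc)
        x_d = count_concurrent(d_group, membership, ab, pc)
        rng = np.random.default_rng(ss)
        xs = _null_sample(N, n_D, k, cfg_m.n_permutations, rng)
        results.append(
            permutation_test(
                N, n_D, k, x_d, cfg_m, ab, pc, "DECREASE", null_sample=xs
            )
        )
        results.append(
            permutation_test(
                N, N - n_D, k, k - x_d, cfg_m, ab, pc, "INCREASE",
                null_sample=k - xs,
            )
        )
    return results


def results_frame(results: Sequence[PermutationResult]) -> pd.DataFrame:
    """Tabular view of a permutation run (one row per test)."""
    return pd.DataFrame([r.__dict__ for r in results])
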