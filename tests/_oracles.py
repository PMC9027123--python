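"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — per-base bitmaps, exhaustive
scans, direct series summation — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


# --------------------------------------------------------------------------
# per-base interval oracles (toy genomes only)


def overlap_pairs_bruteforce(a_list, b_list, min_overlap=1):
    """All (i, j) index pairs with intersection >= min_overlap bp."""
    pairs = []
    for i, x in enumerate(a_list):
        for j, y in enumerate(b_list):
            if x[0] != y[0]:
                continue
            inter = min(x[2], y[2]) - max(x[1], y[1])
            if inter >= min_overlap:
                pairs.append((i, j, max(x[1], y[1]), min(x[2], y[2])))
    return sorted(pairs, key=lambda p: (a_list[p[0]][0], a_list[p[0]][1],
                                        a_list[p[0]][2], b_list[p[1]][1],
                                        b_list[p[1]][2], p[2]))


def merge_bruteforce(intervals, max_gap, genome_size):
    """Merge via a per-base bitmap: paint each interval plus max_gap of
    'glue', then read off maximal painted runs and trim the glue."""
    by_chrom = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        # transitive closure by repeated pairwise merging
        ivs = sorted(ivs)
        changed = True
        while changed:
            changed = False
            res = []
            for s, e in ivs:
                if res and s - res[-1][1] <= max_gap:
                    if e > res[-1][1]:
                        res[-1] = (res[-1][0], e)
                    changed = changed or True
                    # note: sorted input means one pass suffices, but we
                    # loop to stay order-independent
                else:
                    res.append((s, e))
            if len(res) == len(ivs) and res == ivs:
                changed = False
            ivs = res
        out.extend((chrom, s, e) for s, e in ivs)
    return out


def nearest_bruteforce(queries, subjects, cap):
    """Exhaustive distance scan; ties resolved to the smaller start."""
    hits = []
    for chrom, qs, qe in queries:
        best, best_d = None, None
        for schrom, ss, se in subjects:
            if schrom != chrom:
                continue
            if qs < se and ss < qe:
                d = 0
            elif qe <= ss:
                d = ss - qe
            else:
                d = qs - se
            if d > cap:
                continue
            if best_d is None or d < best_d or (
                d == best_d and (ss, se) < (best[1], best[2])
            ):
                best, best_d = (schrom, ss, se), d
        hits.append((best, best_d))
    return hits


# --------------------------------------------------------------------------
# Poisson survival by direct series summation


def poisson_sf_series(count, lam):
    """P(X >= count) summed term by term from k = count upward.

    Terms use lgamma for stability; summation stops once terms are
    negligible relative to the running sum.  Independent of
    scipy.stats.
    """
    if count <= 0:
        return 1.0
    total = 0.0
    k = count
    terms = []
    while True:
        log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
        term = math.exp(log_term)
        terms.append(term)
        total = math.fsum(terms)
        if term < total * 1e-18 and k > lam + count:
            break
        if k > count + 2000:
            break
        k += 1
    return total


# --------------------------------------------------------------------------
# island caller brute force


def islands_bruteforce(t_pos, c_pos, genome_len, cfg, two_sample=False):
    """Enumerate eligible windows, close gaps transitively, filter by
    island p — a from-scratch reimplementation mirroring the documented
    algorithm with explicit loops.

    Returns a list of (start, end, count, pvalue) tuples.
    """
    from scipy import stats

    w = cfg.window
    n_win = -(-genome_len // w)
    tc = [0] * n_win
    for p in t_pos:
        tc[p // w] += 1
    cc = [0] * n_win
    for p in c_pos:
        cc[p // w] += 1
    t_total, c_total = len(t_pos), len(c_pos)
    if c_total == 0:
        two_sample = False

    if two_sample:
        cut_t = 5.0 * (t_total / n_win) + 3.0
        cut_c = 5.0 * (c_total / n_win) + 3.0
        tb = sum(t for t, c in zip(tc, cc) if t <= cut_t and c <= cut_c)
        cb = sum(c for t, c in zip(tc, cc) if t <= cut_t and c <= cut_c)
        scale = tb / cb if tb and cb else 1.0
    else:
        scale = t_total / c_total if c_total else 1.0
    p0 = scale / (1.0 + scale)

    half = int(round(cfg.local_background_bp / w)) // 2
    lam = []
    for i in range(n_win):
        lo, hi = max(0, i - half), min(n_win, i + half + 1)
        loc = sum(cc[lo:hi]) / (hi - lo) if half >= 1 else cc[i]
        lam.append((max(cc[i], loc) + cfg.pseudocount) * scale)

    eligible = []
    for i in range(n_win):
        if tc[i] == 0:
            continue
        if two_sample:
            p = stats.binom.sf(tc[i] - 1, tc[i] + cc[i], p0)
        else:
            p = stats.poisson.sf(tc[i] - 1, lam[i])
        if p < cfg.eligibility_p:
            eligible.append(i)

    # transitive gap closure
    groups = []
    for i in eligible:
        if groups and (i - groups[-1][-1] - 1) * w <= cfg.gap:
            groups[-1].append(i)
        else:
            groups.append([i])

    min_elig = cfg.min_eligible_windows_diff if two_sample else cfg.min_eligible_windows
    out = []
    for grp in groups:
        if len(grp) < min_elig:
            continue
        first, last = grp[0], grp[-1]
        count = sum(tc[first : last + 1])
        if two_sample:
            c_span = sum(cc[first : last + 1])
            p = stats.binom.sf(count - 1, count + c_span, p0)
        else:
            expected = sum(lam[first : last + 1])
            p = stats.poisson.sf(count - 1, expected)
        if p < cfg.p_cutoff:
            out.append((first * w, (last + 1) * w, count, float(p)))
    return out


# --------------------------------------------------------------------------
# literal shuffle null for the permutation test


def shuffle_null_bruteforce(N, n_D, k, B, rng):
    """x* by literally permuting N labels (k of them set) and counting
    how many land in the first n_D slots."""
    labels = np.zeros(N, dtype=np.int64)
    labels[:k] = 1
    out = np.empty(B, dtype=np.int64)
    for b in range(B):
        out[b] = rng.permutation(labels)[:n_D].sum()
    return out
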