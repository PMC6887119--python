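"""Independent brute-force oracles used to validate the package's
implementations. Each oracle is written from the operation's definition via
exhaustive enumeration or a different algorithmic route, never by calling
the code under test."""

from __future__ import annotations

import itertools
import re
from collections import Counter


def tally_rt_stops(alignments, reference_length):
    """Brute-force RT-stop tally: Counter of (pos - 1) per forward read with
    pos >= 2."""
    sites = Counter()
    for rec in alignments:
        if rec.reverse:
            continue
        if 2 <= rec.pos <= reference_length:
            sites[rec.pos - 1] += 1
    return sites


def _qualifying_runs(seq, min_len):
    return [
        (m.start(), m.end())
        for m in re.finditer(r"G+", seq)
        if m.end() - m.start() >= min_len
    ]


def g4_oracle(sequence, tract_length=3, loop_min=1, loop_max=12, n_tracts=4):
    """All greedy non-overlapping chains of n_tracts consecutive maximal
    G-runs with gaps in [loop_min, loop_max]; returns 1-based (start, end)."""
    seq = sequence.upper().replace("U", "T")
    runs = _qualifying_runs(seq, tract_length)
    valid_starts = []
    for i in range(len(runs) - n_tracts + 1):
        gaps = [
            runs[i + t + 1][0] - runs[i + t][1] for t in range(n_tracts - 1)
        ]
        if all(loop_min <= g <= loop_max for g in gaps):
            valid_starts.append(i)
    hits = []
    blocked_until = -1  # last run index consumed
    for i in valid_starts:
        if i <= blocked_until:
            continue
        hits.append((runs[i][0] + 1, runs[i + n_tracts - 1][1]))
        blocked_until = i + n_tracts - 1
    return hits


GGC_RE = re.compile(r"(?:GG[CA])+")


def ggc_oracle(sequence, min_repeats=4):
    """Regex-based leftmost greedy scan for GG[C|A] tandem runs; returns
    1-based (start, end, n_repeats)."""
    seq = sequence.upper().replace("U", "T")
    hits = []
    pos = 0
    while pos <= len(seq) - 3 * min_repeats:
        m = GGC_RE.match(seq, pos)
        if m and (m.end() - m.start()) // 3 >= min_repeats:
            k = (m.end() - m.start()) // 3
            hits.append((m.start() + 1, m.start() + 3 * k, k))
            pos = m.start() + 3 * k
        else:
            pos += 1
    return hits


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def max_pairs_bruteforce(sequence, min_loop=3):
    """Maximum nested pairing by exhaustive recursion over the partner of the
    first position (enumerates every valid structure)."""
    seq = sequence.upper().replace("U", "T")
    return _best_sub(seq, min_loop)


def _best_sub(seq, min_loop, _cache={}):
    key = (seq, min_loop)
    if key in _cache:
        return _cache[key]
    n = len(seq)
    if n <= min_loop + 1:
        return 0
    best = _best_sub(seq[1:], min_loop)
    for k in range(min_loop + 1, n):
        if (seq[0], seq[k]) in _PAIRS:
            cand = (
                1
                + _best_sub(seq[1:k], min_loop)
                + _best_sub(seq[k + 1 :], min_loop)
            )
            best = max(best, cand)
    _cache[key] = best
    return best


def mannwhitney_enumeration(values_a, values_b):
    """U for group a by direct pair counting, and the exact two-sided p by
    enumerating every assignment of the pooled values to group a."""
    def u_stat(a, b):
        u = 0.0
        for x in a:
            for y in b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    n_a = len(values_a)
    pooled = list(values_a) + list(values_b)
    u_obs = u_stat(values_a, values_b)
    n_ab = n_a * len(values_b)
    u_lo, u_hi = min(u_obs, n_ab - u_obs), max(u_obs, n_ab - u_obs)
    total = extreme = 0
    eps = 1e-9
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n_a):
        combo_set = set(combo)
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in idx if i not in combo_set]
        u = u_stat(a, b)
        total += 1
        if u <= u_lo + eps or u >= u_hi - eps:
            extreme += 1
    return u_obs, min(1.0, extreme / total)


_DNA_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_DNA_GU = {("G", "T"), ("T", "G")}


def duplex_bruteforce(oligo, rrna, min_pairs=4, allow_GU=False):
    """All-substrings search for the longest antiparallel complementary
    stretch; returns (n_pairs, rrna_start_1based, oligo_start_1based) of the
    best hit (ties: smallest rRNA start, then smallest oligo start), or None.
    """
    oligo = oligo.upper().replace("U", "T")
    rrna = rrna.upper().replace("U", "T")
    pairs = _DNA_WC | _DNA_GU if allow_GU else _DNA_WC
    best = None
    m, n = len(oligo), len(rrna)
    for k in range(min(m, n), min_pairs - 1, -1):
        for oi in range(m - k + 1):
            for rj in range(n - k + 1):
                ok = True
                for t in range(k):
                    # oligo 5'->3' pairs rRNA 3'->5'
                    if (oligo[oi + t], rrna[rj + k - 1 - t]) not in pairs:
                        ok = False
                        break
                if ok:
                    cand = (-k, rj + 1, oi + 1)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            break
    if best is None:
        return None
    neg_k, rrna_start, oligo_start = best
    return (-neg_k, rrna_start, oligo_start)
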