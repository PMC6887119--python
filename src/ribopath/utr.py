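"""5' UTR sequence features, motif scanning and group statistics.

Features: length, G+C percent, G-quadruplex hits ((GxN1-12)4 with maximal
G-tract extension), (GGC/A)>=4 tandem repeats, a Nussinov maximum-pairing
structure proxy, and 5' TOP flagging. Statistics: Mann-Whitney U with an
exact small-sample branch, Pearson chi-square 2x2 motif enrichment and a PCA
of standardized features.

Sequences may be DNA or RNA; U and T are equivalent (normalized to T
internally), case-insensitive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MotifSpec",
    "G4Hit",
    "RepeatHit",
    "gc_content",
    "scan_g4",
    "scan_ggc_repeats",
    "structure_score",
    "flag_top",
    "mannwhitney_u",
    "motif_enrichment",
    "feature_pca",
    "utr_feature_table",
]

PYRIMIDINES = frozenset("CT")


def _norm(sequence: str) -> str:
    """Uppercase and collapse U onto T."""
    return sequence.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifSpec:
    """Parameters for G-quadruplex and (GGC/A) tandem-repeat scanning."""

    kind: str = "g_quadruplex"  # or "ggc_repeat"
    tract_length: int = 3  # minimum G-run length; 2 for the G2 variant
    loop_min: int = 1
    loop_max: int = 12
    n_tracts: int = 4
    repeat_units: tuple[str, ...] = ("GGC", "GGA")
    min_repeats: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("g_quadruplex", "ggc_repeat"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.loop_min > self.loop_max:
            raise ValueError("loop_min > loop_max")
        if self.n_tracts < 2:
            raise ValueError("n_tracts must be >= 2")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")


G4_SPEC = MotifSpec(kind="g_quadruplex", tract_length=3)
G2_SPEC = MotifSpec(kind="g_quadruplex", tract_length=2)
GGC_SPEC = MotifSpec(kind="ggc_repeat")


@dataclass(frozen=True)
class G4Hit:
    """One G-quadruplex match; coordinates 1-based inclusive."""

    start: int
    end: int
    tract_len: int
    n_tracts: int


@dataclass(frozen=True)
class RepeatHit:
    """One (GGC/A) tandem run; coordinates 1-based inclusive."""

    start: int
    end: int
    n_repeats: int


def gc_content(sequence: str) -> float:
    """Percent G+C over non-N characters."""
    seq = _norm(sequence)
    if not seq:
        raise ValueError("empty sequence")
    denom = sum(1 for c in seq if c != "N")
    if denom == 0:
        raise ValueError("sequence is all N")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / denom


def _g_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of G with length >= min_len as 0-based [start, end)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def scan_g4(sequence: str, spec: MotifSpec = G4_SPEC) -> list[G4Hit]:
    """Greedy left-to-right non-overlapping (GxN{loop_min-loop_max})n scan.

    G-tracts are maximal runs of >= ``tract_length`` Gs; a hit chains
    ``n_tracts`` consecutive such runs whose inter-run gaps all lie in
    [loop_min, loop_max]. After a hit, scanning resumes at the next run past
    it, so alternative overlapping registers are not enumerated.
    """
    if spec.kind != "g_quadruplex":
        raise ValueError("spec.kind must be 'g_quadruplex'")
    seq = _norm(sequence)
    runs = _g_runs(seq, spec.tract_length)
    hits: list[G4Hit] = []
    i = 0
    while i + spec.n_tracts <= len(runs):
        ok = True
        for t in range(spec.n_tracts - 1):
            gap = runs[i + t + 1][0] - runs[i + t][1]
            if not (spec.loop_min <= gap <= spec.loop_max):
                ok = False
                break
        if ok:
            start = runs[i][0]
            end = runs[i + spec.n_tracts - 1][1]
            hits.append(
                G4Hit(
                    start=start + 1,
                    end=end,
                    tract_len=min(
                        runs[i + t][1] - runs[i + t][0]
                        for t in range(spec.n_tracts)
                    ),
                    n_tracts=spec.n_tracts,
                )
            )
            i += spec.n_tracts
        else:
            i += 1
    return hits


def scan_ggc_repeats(
    sequence: str, spec: MotifSpec = GGC_SPEC
) -> list[RepeatHit]:
    """Greedy left-to-right scan for tandem runs of GG[C|A] units.

    At each position, count consecutive in-frame units from
    ``spec.repeat_units`` (mixed C/A units allowed); a run of >=
    ``min_repeats`` units is reported and scanning resumes past it.
    """
    if spec.kind != "ggc_repeat":
        raise ValueError("spec.kind must be 'ggc_repeat'")
    seq = _norm(sequence)
    unit_len = len(spec.repeat_units[0])
    units = set(spec.repeat_units)
    hits: list[RepeatHit] = []
    i = 0
    n = len(seq)
    while i + unit_len * spec.min_repeats <= n:
        k = 0
        while seq[i + k * unit_len : i + (k + 1) * unit_len] in units:
            k += 1
        if k >= spec.min_repeats:
            hits.append(
                RepeatHit(start=i + 1, end=i + k * unit_len, n_repeats=k)
            )
            i += k * unit_len
        else:
            i += 1
    return hits


_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)


def structure_score(sequence: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (Nussinov dynamic program).

    Watson-Crick plus GU wobble pairs; a pair (i, j) requires at least
    ``min_loop`` unpaired bases between i and j. A coarse, monotone proxy for
    secondary-structure content, not a thermodynamic prediction.
    """
    seq = _norm(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if (seq[i], seq[j]) in _PAIRS:
                inner = dp[i + 1, j - 1] if j - 1 >= i + 1 else 0
                best = max(best, inner + 1)
            for k in range(i + 1, j):
                if (seq[i], seq[k]) in _PAIRS and k - i > min_loop:
                    left = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            dp[i, j] = best
    return int(dp[0, n - 1])


def flag_top(sequence: str, min_pyrimidine_tract: int = 4) -> bool:
    """5' TOP rule: C at +1 followed by >= ``min_pyrimidine_tract`` pyrimidines.

    The sequence must begin at the annotated transcription start site.
    """
    seq = _norm(sequence)
    if len(seq) < 1 + min_pyrimidine_tract:
        return False
    if seq[0] != "C":
        return False
    return all(c in PYRIMIDINES for c in seq[1 : 1 + min_pyrimidine_tract])


def _u_statistic(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """U for group a via midrank sums."""
    pooled = np.concatenate([values_a, values_b])
    ranks = stats.rankdata(pooled)
    n_a = values_a.size
    r_a = ranks[:n_a].sum()
    return float(r_a - n_a * (n_a + 1) / 2.0)


def _exact_two_sided_p(
    pooled_ranks: np.ndarray, n_a: int, u_obs: float
) -> float:
    """Exact two-sided p by enumerating all group-a index subsets."""
    n = pooled_ranks.size
    n_b = n - n_a
    offset = n_a * (n_a + 1) / 2.0
    u_lo = min(u_obs, n_a * n_b - u_obs)
    u_hi = max(u_obs, n_a * n_b - u_obs)
    total = 0
    extreme = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n), n_a):
        u = pooled_ranks[list(combo)].sum() - offset
        total += 1
        if u <= u_lo + eps or u >= u_hi - eps:
            extreme += 1
    return min(1.0, extreme / total)


def mannwhitney_u(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_max_n: int = 16,
) -> tuple[float, float]:
    """Mann-Whitney U (group a) and two-sided p-value.

    Exact p by full enumeration of rank assignments when
    n_a + n_b <= ``exact_max_n``; otherwise normal approximation with tie
    correction and continuity correction. Identical pooled values give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return u, 1.0
    ranks = stats.rankdata(pooled)
    if n_a + n_b <= exact_max_n:
        p = _exact_two_sided_p(ranks, n_a, u)
    else:
        n = n_a + n_b
        mean_u = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var_u <= 0:
            return u, 1.0
        z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * stats.norm.sf(z))
    return u, p


def motif_enrichment(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, 1 df) on a 2x2 table.

    Rows: class; columns: motif presence/absence. Returns (statistic, p).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in contingency table")
    (a, b), (c, d) = t
    statistic = n * (a * d - b * c) ** 2 / (row[0] * row[1] * col[0] * col[1])
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def feature_pca(features) -> tuple[np.ndarray, np.ndarray, list]:
    """PCA of a standardized feature table.

    Accepts a DataFrame or 2-D array (rows = UTRs, columns = features).
    Zero-variance features are dropped with a warning. Features are z-scored;
    loadings are orthonormal eigenvectors of the correlation structure with a
    deterministic sign (largest-magnitude loading positive per component).

    Returns (loadings [features x components], variance_explained fractions
    summing to 1, kept feature names/indices).
    """
    import warnings

    import pandas as pd

    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = list(range(x.shape[1]))
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 features")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance features: {dropped}")
        x = x[:, keep]
        names = [names[i] for i in np.flatnonzero(keep)]
        sd = sd[keep]
    z = (x - x.mean(axis=0)) / sd
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    for k in range(loadings.shape[1]):
        imax = np.argmax(np.abs(loadings[:, k]))
        if loadings[imax, k] < 0:
            loadings[:, k] = -loadings[:, k]
    var = s**2
    return loadings, var / var.sum(), names


def utr_feature_table(
    records,
    g4_spec: MotifSpec = G4_SPEC,
    ggc_spec: MotifSpec = GGC_SPEC,
    external_dg: dict[str, float] | None = None,
):
    """Per-UTR feature table from (id, sequence) pairs.

    ``external_dg`` optionally supplies externally computed folding free
    energies (kcal/mol) keyed by id; the Nussinov pair count is always
    reported as ``structure_score``.
    """
    import pandas as pd

    rows = []
    for utr_id, seq in records:
        g4 = scan_g4(seq, g4_spec)
        ggc = scan_ggc_repeats(seq, ggc_spec)
        row = {
            "id": utr_id,
            "length": len(seq),
            "gc_percent": gc_content(seq),
            "n_g4": len(g4),
            "n_ggc": len(ggc),
            "has_g4": bool(g4),
            "has_ggc": bool(ggc),
            "structure_score": structure_score(seq),
            "is_top": flag_top(seq),
        }
        if external_dg is not None:
            row["dG_kcal_per_mol"] = external_dg.get(utr_id, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")
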