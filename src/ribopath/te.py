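"""Translation-efficiency quantification from polysome-profiling counts.

Monosomal (80S) and polysomal (>2 ribosomes) fraction libraries are
normalized with spike-in median-of-ratios size factors; per-gene translation
efficiency (TE) is the polysomal/monosomal abundance ratio, compared between
conditions as a log2 fold change (FC TE, control over treated — positive
values mean the treatment reduced TE), tested per gene across replicates and
classified with asymmetric thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleDesign",
    "size_factors",
    "compute_te",
    "fc_te",
    "test_te_change",
    "bh_adjust",
    "classify_te",
    "te_pipeline",
]

MONOSOMAL = "monosomal"
POLYSOMAL = "polysomal"
FRACTIONS = (MONOSOMAL, POLYSOMAL)

TE_DOWN = "TE_down"
TE_UP = "TE_up"
UNCHANGED = "unchanged"


@dataclass
class SampleDesign:
    """Sample sheet: one row per sequencing library.

    ``table`` columns: sample_id, fraction (monosomal|polysomal), condition,
    replicate. Every (condition, fraction) cell needs >= 2 replicates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "fraction", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        bad = set(self.table["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fractions: {sorted(bad)}")
        for cond, sub in self.table.groupby("condition"):
            for frac in FRACTIONS:
                n = (sub["fraction"] == frac).sum()
                if n == 0:
                    raise ValueError(
                        f"condition {cond!r} lacks {frac} samples"
                    )
                if n < 2:
                    raise ValueError(
                        f"condition {cond!r} has <2 {frac} replicates"
                    )

    @property
    def conditions(self) -> list[str]:
        # stable first-appearance order; first condition is the reference
        return list(dict.fromkeys(self.table["condition"]))

    def samples(self, condition: str, fraction: str) -> list[str]:
        sub = self.table[
            (self.table["condition"] == condition)
            & (self.table["fraction"] == fraction)
        ].sort_values("replicate")
        return list(sub["sample_id"])


def size_factors(
    counts: pd.DataFrame, reference_rows: pd.Index | list[str] | None = None
) -> pd.Series:
    """Median-of-ratios size factors.

    For each reference row i (spike-ins by default; all rows when
    ``reference_rows`` is None) with no zero entry, compute its geometric
    mean across samples; factor_j is the median over those rows of
    counts[i, j] / geomean_i, rescaled so the factors' geometric mean is 1.
    """
    if reference_rows is None:
        ref = counts
    else:
        ref = counts.loc[list(reference_rows)]
    mat = ref.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no reference row is positive in every sample; consider the "
            "all-genes fallback (reference_rows=None)"
        )
    mat = mat[usable]
    log_geomean = np.log(mat).mean(axis=1)
    ratios = mat / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    return counts.div(factors, axis=1)


def compute_te(
    normalized_counts: pd.DataFrame,
    design: SampleDesign,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene TE per condition.

    TE = (mean polysomal + pseudocount) / (mean monosomal + pseudocount),
    means taken over the replicates of each condition.
    """
    if (normalized_counts.to_numpy() < 0).any():
        raise ValueError("normalized counts must be nonnegative")
    out = {}
    for cond in design.conditions:
        poly = normalized_counts[design.samples(cond, POLYSOMAL)].mean(axis=1)
        mono = normalized_counts[design.samples(cond, MONOSOMAL)].mean(axis=1)
        out[cond] = (poly + pseudocount) / (mono + pseudocount)
    return pd.DataFrame(out)


def fc_te(te_control, te_treated):
    """log2(TE_control / TE_treated); positive = treatment reduced TE."""
    te_control = np.asarray(te_control, dtype=float)
    te_treated = np.asarray(te_treated, dtype=float)
    if (te_control <= 0).any() or (te_treated <= 0).any():
        raise ValueError("TE values must be positive")
    out = np.log2(te_control / te_treated)
    return out.item() if out.ndim == 0 else out


def replicate_log2_te(
    normalized_counts: pd.DataFrame,
    design: SampleDesign,
    condition: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-replicate log2 TE for one condition (genes x replicates).

    Monosomal and polysomal libraries are paired by replicate index.
    """
    mono = design.samples(condition, MONOSOMAL)
    poly = design.samples(condition, POLYSOMAL)
    if len(mono) != len(poly):
        raise ValueError(
            f"condition {condition!r}: unpaired replicates "
            f"({len(mono)} monosomal vs {len(poly)} polysomal)"
        )
    cols = {}
    for r, (m, p) in enumerate(zip(mono, poly)):
        cols[r] = np.log2(
            (normalized_counts[p] + pseudocount)
            / (normalized_counts[m] + pseudocount)
        )
    return pd.DataFrame(cols)


def welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values.

    Rows where both groups have zero variance and equal means get p = 1
    (no-signal convention).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate] = 1.0
    return p


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene-wise variances.

    Moment matching on log sample variances (scaled chi-square model): the
    excess spread of log(s2) beyond the trigamma(df/2) sampling component
    determines the prior df d0; no excess means complete shrinkage
    (d0 = inf). Genes with zero variance are excluded from the fit.
    """
    from scipy.special import polygamma

    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(s2.mean() if s2.size else 1.0)
    z = np.log(s2[ok])
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    excess = z.var(ddof=1) - polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = e.mean()
    else:
        # invert trigamma(d0/2) = excess by bisection
        lo, hi = 1e-6, 1e7
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if polygamma(1, mid / 2.0) > excess:
                lo = mid
            else:
                hi = mid
        d0 = 0.5 * (lo + hi)
        log_s0 = e.mean() + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
    return float(d0), float(np.exp(log_s0))


def moderated_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise moderated t-test p-values (limma-style variance shrinkage).

    Gene-wise pooled variances are shrunk toward an empirical-Bayes prior
    fitted across genes; the t statistic uses the posterior variance with
    df = residual df + prior df. Restores power at very small replicate
    numbers while staying calibrated under the null.
    """
    n_a, n_b = a.shape[1], b.shape[1]
    df = n_a + n_b - 2
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    d0, s0_sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_post = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_post = d0 + df
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(se == 0, np.where(diff == 0, 0.0, np.inf), t)
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    p = np.asarray(p, dtype=float)
    p[np.isnan(p)] = 1.0
    return np.minimum(p, 1.0)


def permutation_p_rows(
    a: np.ndarray, b: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Row-wise label-permutation p-values for the mean difference.

    Small-n robust alternative to the Welch test; p = (1 + #{|perm diff| >=
    |obs diff|}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    pooled = np.hstack([a, b])
    n_a = a.shape[1]
    obs = np.abs(a.mean(axis=1) - b.mean(axis=1))
    hits = np.zeros(pooled.shape[0], dtype=int)
    n_total = pooled.shape[1]
    for _ in range(n_perm):
        idx = rng.permutation(n_total)
        pa = pooled[:, idx[:n_a]]
        pb = pooled[:, idx[n_a:]]
        hits += np.abs(pa.mean(axis=1) - pb.mean(axis=1)) >= obs - 1e-12
    return (1.0 + hits) / (1.0 + n_perm)


def test_te_change(
    log2_te_a: pd.DataFrame,
    log2_te_b: pd.DataFrame,
    method: str = "welch",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Per-gene p-value comparing per-replicate log2 TE between conditions."""
    a = log2_te_a.to_numpy(dtype=float)
    b = log2_te_b.to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    if method == "welch":
        p = welch_t_rows(a, b)
    elif method == "moderated":
        p = moderated_t_rows(a, b)
    elif method == "permutation":
        p = permutation_p_rows(a, b, n_perm=n_perm, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(p, index=log2_te_a.index, name="p_value")


test_te_change.__test__ = False  # not a pytest test despite the name


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def classify_te(
    log2_fc_te,
    p_adj,
    down_threshold: float = 1.0,
    up_threshold: float = -0.7,
    alpha: float = 0.05,
):
    """Classify genes as TE_down / TE_up / unchanged.

    TE_down: p_adj < alpha and fc > down_threshold (treatment reduced TE);
    TE_up:   p_adj < alpha and fc < up_threshold; otherwise unchanged.
    """
    if not (down_threshold > 0 > up_threshold):
        raise ValueError("require down_threshold > 0 > up_threshold")
    fc = np.atleast_1d(np.asarray(log2_fc_te, dtype=float))
    padj = np.atleast_1d(np.asarray(p_adj, dtype=float))
    labels = np.full(fc.shape, UNCHANGED, dtype=object)
    sig = padj < alpha
    labels[sig & (fc > down_threshold)] = TE_DOWN
    labels[sig & (fc < up_threshold)] = TE_UP
    if np.ndim(log2_fc_te) == 0:
        return labels[0]
    return labels


def te_pipeline(
    counts: pd.DataFrame,
    design: SampleDesign,
    spike_prefix: str = "ERCC-",
    pseudocount: float = 0.5,
    min_total_count: int = 10,
    down_threshold: float = 1.0,
    up_threshold: float = -0.7,
    alpha: float = 0.05,
    norm: str = "spike-in",
    test_method: str = "moderated",
) -> pd.DataFrame:
    """End-to-end TE table from a raw count matrix.

    Normalizes with spike-in median-of-ratios (``norm='all-genes'`` falls
    back to every row), computes TE per condition, log2 FC TE between the
    first (reference/control) and second condition, per-gene p-values on
    per-replicate log2 TE (moderated t by default; 'welch' and 'permutation'
    available), BH adjustment across tested genes and class labels. Genes with total raw count < ``min_total_count`` are dropped
    before testing. Spike-in rows are normalized but excluded from the
    output table.
    """
    conds = design.conditions
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    control, treated = conds
    is_spike = counts.index.str.startswith(spike_prefix)
    if norm == "spike-in":
        if not is_spike.any():
            raise ValueError(
                f"no spike-in rows with prefix {spike_prefix!r}; "
                "use norm='all-genes'"
            )
        factors = size_factors(counts, counts.index[is_spike])
    elif norm == "all-genes":
        factors = size_factors(counts)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    normed = normalize_counts(counts, factors)

    keep = (counts.sum(axis=1) >= min_total_count) & ~is_spike
    normed = normed.loc[keep]

    te = compute_te(normed, design, pseudocount)
    lfc = fc_te(te[control], te[treated])
    rep_a = replicate_log2_te(normed, design, control, pseudocount)
    rep_b = replicate_log2_te(normed, design, treated, pseudocount)
    p = test_te_change(rep_a, rep_b, method=test_method)
    p_adj = bh_adjust(p.to_numpy())
    labels = classify_te(
        lfc, p_adj, down_threshold, up_threshold, alpha
    )
    return pd.DataFrame(
        {
            "gene_id": te.index,
            f"te_{control}": te[control].to_numpy(),
            f"te_{treated}": te[treated].to_numpy(),
            "log2_fc_te": np.asarray(lfc),
            "p_value": p.to_numpy(),
            "p_adj": p_adj,
            "te_class": labels,
        }
    ).set_index("gene_id")
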