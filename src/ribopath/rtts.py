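"""Reverse-transcriptase termination (RT-stop) site calling on an rRNA reference.

An RT stop locates a crosslink adduct: reverse transcription arrests one
nucleotide 3' of the adduct, so the crosslinked residue is the nucleotide
immediately 5'-adjacent to the 5' end of each aligned cDNA read. This module
tallies those per-nucleotide termination events, ranks the most abundant
sites, annotates them against named helix intervals and contrasts two
profiles.

Coordinates are 1-based inclusive throughout; export to BED/bedGraph converts
to 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignedRead",
    "RTStopProfile",
    "HelixMap",
    "DEFAULT_HELIX_MAP",
    "call_rt_stops",
    "top_sites",
    "annotate_site",
    "region_fraction",
    "compare_profiles",
]


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record: a read's 5' end on the reference sense strand.

    ``pos`` is the 1-based leftmost aligned reference position of the read
    after soft-clipping (for forward-strand alignments this is the 5' end).
    """

    read_id: str
    reference: str
    pos: int
    reverse: bool = False


@dataclass
class SkipReport:
    """Counts of records excluded from site calling."""

    reverse_strand: int = 0
    malformed: int = 0

    @property
    def total(self) -> int:
        return self.reverse_strand + self.malformed


@dataclass
class RTStopProfile:
    """Per-nucleotide termination-event counts on one reference.

    ``counts[i]`` holds the number of termination events at 1-based
    position ``i + 1``.
    """

    reference_name: str
    reference_length: int
    counts: np.ndarray
    total_reads: int = 0
    skipped: SkipReport = field(default_factory=SkipReport)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.reference_length,):
            raise ValueError(
                f"counts length {self.counts.size} != reference length "
                f"{self.reference_length}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() > self.total_reads:
            raise ValueError("sum(counts) exceeds total_reads")

    def count_at(self, position: int) -> int:
        """Termination events at a 1-based position."""
        return int(self.counts[position - 1])

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


class HelixMap:
    """Named 1-based inclusive intervals on the reference (gaps allowed)."""

    def __init__(self, intervals: Mapping[str, tuple[int, int]]):
        for label, (start, end) in intervals.items():
            if start > end:
                raise ValueError(f"interval {label}: start {start} > end {end}")
        labels = list(intervals)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                sa, ea = intervals[a]
                sb, eb = intervals[b]
                if sa <= eb and sb <= ea:
                    raise ValueError(f"overlapping intervals: {a} and {b}")
        self.intervals = dict(intervals)

    def __getitem__(self, label: str) -> tuple[int, int]:
        return self.intervals[label]

    def items(self):
        return self.intervals.items()


#: ES6S helices of 18S rRNA (1-based inclusive nt intervals).
DEFAULT_HELIX_MAP = HelixMap(
    {
        "ES6S_A": (681, 735),
        "ES6S_B": (740, 793),
        "ES6S_CD": (795, 864),
        "ES6S_E": (865, 910),
    }
)


def call_rt_stops(
    alignments: Iterable[AlignedRead],
    reference_name: str,
    reference_length: int,
) -> RTStopProfile:
    """Tally RT-stop sites from aligned reads.

    For each sense-strand read whose 5' end maps at 1-based position ``p``,
    the termination site ``p - 1`` is incremented. Reads at ``p = 1``
    contribute to ``total_reads`` but have no 5'-adjacent nucleotide and add
    no site. Reverse-strand reads are skipped and counted in the skip report;
    out-of-range positions are skipped as malformed. Alignments naming a
    different reference raise ``ValueError``.
    """
    counts = np.zeros(reference_length, dtype=np.int64)
    total = 0
    skipped = SkipReport()
    for rec in alignments:
        if rec.reference != reference_name:
            raise ValueError(
                f"alignment references {rec.reference!r}, expected "
                f"{reference_name!r}"
            )
        if rec.reverse:
            skipped.reverse_strand += 1
            continue
        if not isinstance(rec.pos, (int, np.integer)) or not (
            1 <= rec.pos <= reference_length
        ):
            skipped.malformed += 1
            continue
        total += 1
        if rec.pos >= 2:
            counts[rec.pos - 2] += 1  # site = pos - 1, stored 0-based
    return RTStopProfile(
        reference_name=reference_name,
        reference_length=reference_length,
        counts=counts,
        total_reads=total,
        skipped=skipped,
    )


def top_sites(profile: RTStopProfile, k: int = 18) -> list[tuple[int, int]]:
    """The ``k`` highest-count positions as (1-based position, count).

    Sorted by count descending, ties broken by ascending position. Positions
    with zero counts are never returned, so fewer than ``k`` entries may come
    back.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    nonzero = np.flatnonzero(profile.counts)
    order = sorted(nonzero, key=lambda i: (-profile.counts[i], i))
    return [(int(i) + 1, int(profile.counts[i])) for i in order[:k]]


def annotate_site(position: int, helix_map: HelixMap | None = None) -> str | None:
    """Label of the interval containing a 1-based position, else ``None``."""
    if helix_map is None:
        helix_map = DEFAULT_HELIX_MAP
    if position < 1:
        raise ValueError("position must be >= 1")
    for label, (start, end) in helix_map.items():
        if start <= position <= end:
            return label
    return None


def region_fraction(
    profile: RTStopProfile, start: int = 700, end: int = 910
) -> float:
    """Fraction of all termination events falling inside [start, end].

    Returns 0.0 for an empty profile.
    """
    if not (1 <= start <= end <= profile.reference_length):
        raise ValueError("require 1 <= start <= end <= reference_length")
    total = profile.counts.sum()
    if total == 0:
        return 0.0
    return float(profile.counts[start - 1 : end].sum() / total)


def compare_profiles(
    profile_a: RTStopProfile,
    profile_b: RTStopProfile,
    pseudocount: float = 1.0,
):
    """Per-position enrichment of profile_b over profile_a.

    Rates are count/total per profile; the log2 ratio uses ``pseudocount``
    added to the raw counts (Laplace smoothing of the rates), so disjoint
    supports stay finite. Positions with zero counts in both profiles are
    omitted. Returns a pandas DataFrame with columns position, count_a,
    count_b, rate_a, rate_b, log2_ratio (b over a).
    """
    import pandas as pd

    if profile_a.reference_length != profile_b.reference_length:
        raise ValueError("profiles have differing reference lengths")
    ca = profile_a.counts.astype(float)
    cb = profile_b.counts.astype(float)
    keep = (ca > 0) | (cb > 0)
    ta = ca.sum()
    tb = cb.sum()
    length = profile_a.reference_length
    rate_a = np.where(ta > 0, ca / max(ta, 1.0), 0.0)
    rate_b = np.where(tb > 0, cb / max(tb, 1.0), 0.0)
    smooth_a = (ca + pseudocount) / (ta + pseudocount * length)
    smooth_b = (cb + pseudocount) / (tb + pseudocount * length)
    log2_ratio = np.log2(smooth_b / smooth_a)
    pos = np.flatnonzero(keep)
    return pd.DataFrame(
        {
            "position": pos + 1,
            "count_a": ca[pos].astype(int),
            "count_b": cb[pos].astype(int),
            "rate_a": rate_a[pos],
            "rate_b": rate_b[pos],
            "log2_ratio": log2_ratio[pos],
        }
    )


def profile_table(
    profile: RTStopProfile, helix_map: HelixMap | None = None
):
    """Full site table (position, count, rate, helix) for nonzero positions."""
    import pandas as pd

    if helix_map is None:
        helix_map = DEFAULT_HELIX_MAP
    pos = np.flatnonzero(profile.counts) + 1
    total = max(profile.n_sites, 1)
    return pd.DataFrame(
        {
            "position": pos,
            "count": profile.counts[pos - 1],
            "rate": profile.counts[pos - 1] / total,
            "helix": [annotate_site(int(p), helix_map) or "" for p in pos],
        }
    )
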