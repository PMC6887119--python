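"""Solvent-side mRNA path geometry and oligo-rRNA duplex mapping.

The mRNA path across the solvent side of the scanning complex is modelled as
a fully stretched single strand: distance from the entry channel is linear in
nucleotide index with a fixed rise per base (default 4.5 A, origin at mRNA
position +11). Oligo placement on the rRNA is located by the longest
contiguous antiparallel perfect-complementarity stretch, mirroring RNase H
protection of a DNA-RNA heteroduplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PathModel",
    "DuplexHit",
    "path_distance",
    "map_oligo_duplex",
    "annotate_path_contacts",
]


@dataclass(frozen=True)
class PathModel:
    """Linear path model: distance = (position - origin) * rise_per_base."""

    origin_position: int = 11
    rise_per_base: float = 4.5

    def __post_init__(self) -> None:
        if self.rise_per_base <= 0:
            raise ValueError("rise_per_base must be positive")


def path_distance(nt_position: int, model: PathModel = PathModel()) -> float:
    """Distance in Angstrom of an mRNA nucleotide from the entry channel.

    Positions upstream of the origin give a signed negative distance
    (inside-channel positions) with a warning.
    """
    distance = (nt_position - model.origin_position) * model.rise_per_base
    if distance < 0:
        warnings.warn(
            f"position {nt_position} is upstream of the entry-channel origin "
            f"{model.origin_position}; returning signed negative distance"
        )
    return float(distance)


@dataclass(frozen=True)
class DuplexHit:
    """Longest contiguous oligo-rRNA duplex.

    ``rrna_interval`` is 1-based inclusive on the rRNA; ``oligo_paired_range``
    is 1-based inclusive on the oligo (5'->3'); overhangs are the unpaired
    oligo tails flanking the paired range.
    """

    rrna_interval: tuple[int, int]
    oligo_paired_range: tuple[int, int]
    unpaired_5prime_len: int
    unpaired_3prime_len: int
    n_pairs: int


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def map_oligo_duplex(
    oligo_sequence: str,
    rrna_sequence: str,
    min_pairs: int = 4,
    allow_GU: bool = False,
) -> DuplexHit | None:
    """Longest contiguous antiparallel complementary stretch, or None.

    Watson-Crick pairing; GU wobble optionally allowed (RNA-RNA mode; keep it
    off for DNA-RNA heteroduplexes, which RNase H requires to be strict).
    Ties are broken by the smallest rRNA start, then by the smallest oligo
    start. Returns None when no stretch reaches ``min_pairs``.
    """
    oligo = _norm(oligo_sequence)
    rrna = _norm(rrna_sequence)
    if not oligo or not rrna:
        raise ValueError("sequences must be nonempty")
    pairs = _WC | _GU if allow_GU else _WC
    m, n = len(oligo), len(rrna)
    # run[j] = length of the antiparallel complementary run ending with
    # oligo position i paired to rRNA position j (oligo ascending pairs
    # with rRNA descending).
    prev = np.zeros(n + 2, dtype=np.int32)
    best = None  # (n_pairs, rrna_start, oligo_start)
    for i in range(m):
        cur = np.zeros(n + 2, dtype=np.int32)
        oi = oligo[i]
        for j in range(n):
            if (oi, rrna[j]) in pairs:
                cur[j] = prev[j + 1] + 1
                k = int(cur[j])
                if k >= min_pairs:
                    rrna_start = j + 1  # run spans rRNA [j+1, j+k] 1-based
                    oligo_start = i - k + 2
                    cand = (-k, rrna_start, oligo_start)
                    if best is None or cand < best:
                        best = cand
        prev = cur
    if best is None:
        return None
    neg_k, rrna_start, oligo_start = best
    k = -neg_k
    return DuplexHit(
        rrna_interval=(rrna_start, rrna_start + k - 1),
        oligo_paired_range=(oligo_start, oligo_start + k - 1),
        unpaired_5prime_len=oligo_start - 1,
        unpaired_3prime_len=m - (oligo_start + k - 1),
        n_pairs=k,
    )


def annotate_path_contacts(
    positions,
    model: PathModel = PathModel(),
    helix_map=None,
):
    """Table of (position, distance_A[, helix]) for mRNA contact positions.

    Duplicate positions are preserved; rows are ordered by position. When a
    ``helix_map`` is given the positions are additionally annotated against
    its intervals (useful when the input positions are rRNA coordinates).
    """
    import pandas as pd

    from .rtts import annotate_site

    pos = sorted(int(p) for p in positions)
    if any(p < 1 for p in pos):
        raise ValueError("positions must be >= 1")
    table = pd.DataFrame(
        {
            "position": pos,
            "distance_A": [path_distance(p, model) for p in pos],
        }
    )
    if helix_map is not None:
        table["helix"] = [
            annotate_site(p, helix_map) or "" for p in table["position"]
        ]
    return table
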