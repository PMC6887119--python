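"""Synthetic 5' UTR sequences with controlled GC, length and planted motifs.

Base composition is drawn i.i.d. with P(G) = P(C) = gc_target / 2 (so the
realized GC count is binomial), lengths are lognormal, and G-quadruplex or
(GGC/A)4 motifs are planted verbatim at recorded positions with per-group
probabilities. A G-free alphabet option supports negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["UTRGroup", "UTRSimSpec", "gen_utrs"]


@dataclass(frozen=True)
class UTRGroup:
    """One sequence group (e.g. a TE class) with its own GC and motif rates."""

    name: str
    n: int
    gc_target: float = 0.5
    p_g4: float = 0.0
    p_ggc: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must be in [0, 1]")
        for p in (self.p_g4, self.p_ggc):
            if not 0.0 <= p <= 1.0:
                raise ValueError("planting probabilities must be in [0, 1]")


@dataclass
class UTRSimSpec:
    """Parameters for one synthetic UTR set."""

    groups: list[UTRGroup]
    length_mean: float = 200.0  # lognormal parameters on the natural scale
    length_cv: float = 0.5
    min_length: int = 30
    g_free: bool = False  # draw backbone from {A, C, T} only
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        if self.min_length < 1:
            raise ValueError("lengths must be >= 1")
        if self.length_mean < self.min_length:
            raise ValueError("length_mean below min_length")

    @property
    def n_sequences(self) -> int:
        return sum(g.n for g in self.groups)


def _g4_motif(rng: np.random.Generator, tract: int = 3) -> str:
    """A concrete (G{tract}N1-3)4 instance with non-G loop bases."""
    loops = [
        "".join(rng.choice(list("ACT"), size=rng.integers(1, 4)))
        for _ in range(3)
    ]
    g = "G" * tract
    return g + loops[0] + g + loops[1] + g + loops[2] + g


def _ggc_motif(rng: np.random.Generator, n_repeats: int = 4) -> str:
    units = rng.choice(["GGC", "GGA"], size=n_repeats)
    return "".join(units)


def _draw_backbone(
    rng: np.random.Generator, length: int, gc: float, g_free: bool
) -> np.ndarray:
    if g_free:
        letters = np.array(list("ACT"))
        probs = np.array([(1 - gc) / 2, gc, (1 - gc) / 2])
    else:
        letters = np.array(list("ACGT"))
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(letters, size=length, p=probs)


def gen_utrs(spec: UTRSimSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate sequences and the planted-motif truth table.

    Returns ``(records, truth)`` with records as (id, sequence) pairs and a
    truth table with columns id, group, length, planted_g4, g4_pos,
    planted_ggc, ggc_pos (1-based plant start positions, 0 when absent).
    A planted motif overwrites the backbone at a position chosen so the two
    motif kinds never overlap. Raises when a motif is longer than the
    sequence.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log(1.0 + spec.length_cv**2))
    mu = np.log(spec.length_mean) - sigma**2 / 2.0

    records: list[tuple[str, str]] = []
    rows = []
    counter = 0
    for group in spec.groups:
        for _ in range(group.n):
            length = max(
                spec.min_length, int(round(rng.lognormal(mu, sigma)))
            )
            seq = _draw_backbone(rng, length, group.gc_target, spec.g_free)
            plant_g4 = rng.random() < group.p_g4
            plant_ggc = rng.random() < group.p_ggc
            g4_pos = ggc_pos = 0
            if plant_g4:
                motif = _g4_motif(rng)
                if len(motif) > length:
                    raise ValueError(
                        f"motif length {len(motif)} exceeds sequence "
                        f"length {length}"
                    )
                # plant in the first half so a second motif fits after it
                hi = max(1, length - len(motif) - 15)
                g4_pos = int(rng.integers(0, max(1, hi // 2))) + 1
                seq[g4_pos - 1 : g4_pos - 1 + len(motif)] = list(motif)
            if plant_ggc:
                motif = _ggc_motif(rng)
                if len(motif) > length:
                    raise ValueError(
                        f"motif length {len(motif)} exceeds sequence "
                        f"length {length}"
                    )
                # keep clear of a planted G4 (max 21 nt) so neither motif
                # is clobbered; drop the plant when there is no room
                lo = g4_pos - 1 + 25 if plant_g4 else 0
                hi = length - len(motif)
                if lo > hi:
                    plant_ggc = False
                else:
                    ggc_pos = int(rng.integers(lo, hi + 1)) + 1
                    seq[ggc_pos - 1 : ggc_pos - 1 + len(motif)] = list(motif)
            utr_id = f"utr{counter:05d}"
            counter += 1
            records.append((utr_id, "".join(seq)))
            rows.append(
                {
                    "id": utr_id,
                    "group": group.name,
                    "length": length,
                    "planted_g4": plant_g4,
                    "g4_pos": g4_pos,
                    "planted_ggc": plant_ggc,
                    "ggc_pos": ggc_pos,
                }
            )
    return records, pd.DataFrame(rows).set_index("id")
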