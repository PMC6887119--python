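"""Simulated RT-termination-site sequencing reads with planted crosslink sites.

A crosslink at nucleotide ``s`` arrests reverse transcription one nucleotide
3' of the adduct, so the cDNA's 5' end maps at ``s + 1`` on the reference.
Signal reads are allotted to planted sites multinomially in proportion to
their intensities; background reads start uniformly over the reference. An
optional geometric read-through parameter lets a fraction of signal reads
slip past the adduct (default 0: pure RT-stop model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..rtts import AlignedRead

__all__ = ["RTTSSimSpec", "gen_rtts_reads"]


@dataclass
class RTTSSimSpec:
    """Parameters for one simulated RTTS library."""

    reference_length: int
    planted_sites: list[tuple[int, float]]  # (1-based position, intensity)
    background_rate: float = 0.0  # expected reads per nt
    n_reads: int = 10_000
    read_length: int = 30
    read_through: float = 0.0  # geometric slippage prob past the adduct
    reference_name: str = "rRNA_18S"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length < 2:
            raise ValueError("reference_length must be >= 2")
        for pos, intensity in self.planted_sites:
            if not 2 <= pos <= self.reference_length:
                raise ValueError(
                    f"planted site {pos} outside [2, {self.reference_length}]"
                    " (position 1 has no 5'-adjacent nucleotide)"
                )
            if intensity <= 0:
                raise ValueError("site intensities must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0.0 <= self.read_through < 1.0:
            raise ValueError("read_through must be in [0, 1)")


def gen_rtts_reads(
    spec: RTTSSimSpec,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Simulate aligned reads and the planted-site truth table.

    Returns ``(alignments, truth)`` where the truth table has columns
    position, intensity, expected_fraction (fraction of all reads expected to
    start at position + 1). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positions = [p for p, _ in spec.planted_sites]
    intensities = np.array([w for _, w in spec.planted_sites], dtype=float)
    background_mass = spec.background_rate * spec.reference_length
    total_mass = intensities.sum() + background_mass
    if total_mass <= 0:
        probs = np.array([])
        p_background = 1.0 if spec.n_reads else 0.0
    else:
        probs = intensities / total_mass
        p_background = background_mass / total_mass

    truth = pd.DataFrame(
        {
            "position": positions,
            "intensity": intensities,
            "expected_fraction": probs if len(positions) else [],
        }
    )

    if spec.n_reads == 0:
        return [], truth

    categories = (
        np.concatenate([probs, [p_background]])
        if total_mass > 0
        else np.array([1.0])
    )
    counts = rng.multinomial(spec.n_reads, categories)
    alignments: list[AlignedRead] = []
    read_no = 0
    for site_idx, n in enumerate(counts[:-1] if total_mass > 0 else []):
        site = positions[site_idx]
        starts = np.full(n, site + 1)
        if spec.read_through > 0 and n:
            # geometric slippage: each extra nt read through w.p. read_through
            slip = rng.geometric(1.0 - spec.read_through, size=n) - 1
            starts = np.maximum(starts - slip, 1)
        for s in starts:
            alignments.append(
                AlignedRead(
                    read_id=f"read{read_no}",
                    reference=spec.reference_name,
                    pos=int(s),
                )
            )
            read_no += 1
    n_background = int(counts[-1])
    if n_background:
        starts = rng.integers(1, spec.reference_length + 1, size=n_background)
        for s in starts:
            alignments.append(
                AlignedRead(
                    read_id=f"read{read_no}",
                    reference=spec.reference_name,
                    pos=int(s),
                )
            )
            read_no += 1
    return alignments, truth
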