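"""Allelic-imbalance status vectors.

An individual is in allelic imbalance (AI) when its two chromosomes express a
transcript unequally.  In the simulation model this happens exactly in
heterozygotes of the regulatory site.  The direction flag records which of the
two arbitrarily numbered chromosomes is up-regulated (+1 = chromosome 1,
-1 = chromosome 2); it exists only for AI individuals and is only consumed by
the haplotype-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DiploidCohort, RegulatorySite

__all__ = [
    "AIStatusVector",
    "assign_ai_from_rsite",
    "assign_ai_triallelic",
    "random_ai_assignment",
    "read_ai_table",
    "write_ai_table",
]


@dataclass
class AIStatusVector:
    """Per-individual AI flag and optional direction.

    ``direction[i]`` is +1 when chromosome 1 of individual ``i`` is
    up-regulated, -1 when chromosome 2 is, and 0 when absent (non-AI
    individuals, or unphased use).
    """

    ai: np.ndarray
    direction: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.ai = np.asarray(self.ai, dtype=bool)
        if self.direction is None:
            self.direction = np.zeros(self.ai.shape, dtype=np.int8)
        else:
            self.direction = np.asarray(self.direction, dtype=np.int8)
        if self.direction.shape != self.ai.shape:
            raise ValueError("direction and ai must have the same length")
        if np.any((self.direction != 0) & ~self.ai):
            raise ValueError("direction present for a non-AI individual")
        if not np.isin(self.direction, (-1, 0, 1)).all():
            raise ValueError("direction must be -1, 0 or +1")

    @property
    def n_individuals(self) -> int:
        return self.ai.shape[0]

    @property
    def n_ai(self) -> int:
        return int(self.ai.sum())

    def flipped(self) -> "AIStatusVector":
        """Globally flip the up/down convention (every direction negated)."""
        return AIStatusVector(self.ai.copy(), -self.direction, self.ids)


def assign_ai_from_rsite(
    cohort: DiploidCohort, rsite: RegulatorySite
) -> AIStatusVector:
    """AI = heterozygous at the bi-allelic regulatory site.

    The derived allele r is (by convention) the up-regulating one, so
    direction = +1 when chromosome 1 carries r.  The convention is global and
    arbitrary; every downstream test is invariant to flipping it.
    """
    if rsite.is_triallelic:
        raise ValueError("use assign_ai_triallelic for a tri-allelic site")
    r = rsite.index
    h1, h2 = cohort.haplotypes()
    a1, a2 = h1[:, r], h2[:, r]
    ai = a1 != a2
    direction = np.where(ai, np.where(a1 == 1, 1, -1), 0).astype(np.int8)
    return AIStatusVector(ai=ai, direction=direction)


def assign_ai_triallelic(
    cohort: DiploidCohort, rsite: RegulatorySite
) -> AIStatusVector:
    """AI = the two haplotypes confer different expression ranks.

    Direction points at the chromosome with the higher rank.
    """
    if not rsite.is_triallelic or rsite.expression_map is None:
        raise ValueError("rsite must be tri-allelic with an expression map")
    i, j = rsite.site_indices
    h1, h2 = cohort.haplotypes()
    lut = np.full(4, -1, dtype=np.int8)
    for cls, rank in rsite.expression_map.items():
        lut[cls] = rank
    r1 = lut[2 * h1[:, i] + h1[:, j]]
    r2 = lut[2 * h2[:, i] + h2[:, j]]
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("cohort contains a haplotype class outside the trio")
    ai = r1 != r2
    direction = np.where(ai, np.where(r1 > r2, 1, -1), 0).astype(np.int8)
    return AIStatusVector(ai=ai, direction=direction)


def random_ai_assignment(
    n_individuals: int,
    k_ai: int,
    seed: int | np.random.Generator | None = None,
) -> AIStatusVector:
    """Null AI assignment: a uniform subset of ``k_ai`` individuals flagged AI.

    Directions are independent fair coins, the null the haplotype tests
    assume for false-positive-rate estimation.
    """
    if not (0 <= k_ai <= n_individuals):
        raise ValueError("k_ai out of range")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ai = np.zeros(n_individuals, dtype=bool)
    ai[rng.choice(n_individuals, size=k_ai, replace=False)] = True
    direction = np.where(ai, rng.choice((-1, 1), size=n_individuals), 0)
    return AIStatusVector(ai=ai, direction=direction.astype(np.int8))


def read_ai_table(path) -> AIStatusVector:
    """Read an AI-status TSV: columns individual_id, ai (0/1), direction."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    ai = df["ai"].astype(int).to_numpy().astype(bool)
    if "direction" in df.columns:
        direction = (
            pd.to_numeric(df["direction"], errors="coerce")
            .fillna(0)
            .astype(np.int8)
            .to_numpy()
        )
    else:
        direction = None
    return AIStatusVector(ai=ai, direction=direction,
                          ids=df["individual_id"].tolist())


def write_ai_table(status: AIStatusVector, path) -> None:
    ids = status.ids or [f"ind{i}" for i in range(status.n_individuals)]
    df = pd.DataFrame(
        {
            "individual_id": ids,
            "ai": status.ai.astype(int),
            "direction": [
                d if d != 0 else "NA" for d in status.direction
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
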