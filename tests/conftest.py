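"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: exact
rational enumeration (``fractions.Fraction`` + ``math.comb``) for the 2x3
Fisher test and the two-sided binomial, so the vectorised log-space
implementations are checked against an arithmetic route that cannot share
their bugs.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from aimap.simulate import DiploidCohort, HaplotypePanel


def oracle_fisher_2x3(ai_row, non_ai_row) -> float:
    """Exact 2x3 Fisher p by brute-force rational enumeration."""
    a = tuple(int(x) for x in ai_row)
    b = tuple(int(x) for x in non_ai_row)
    cols = tuple(a[i] + b[i] for i in range(3))
    r1 = sum(a)
    N = r1 + sum(b)
    if r1 == 0 or sum(b) == 0 or sum(c > 0 for c in cols) < 2:
        return 1.0

    def prob(row):
        num = Fraction(1)
        for c, x in zip(cols, row):
            num *= math.comb(c, x)
        return num / math.comb(N, r1)

    p_obs = prob(a)
    total = Fraction(0)
    for x1 in range(min(r1, cols[0]) + 1):
        for x2 in range(min(r1 - x1, cols[1]) + 1):
            x3 = r1 - x1 - x2
            if x3 > cols[2]:
                continue
            p = prob((x1, x2, x3))
            if p <= p_obs:
                total += p
    return float(min(total, Fraction(1)))


def oracle_binomial_two_sided(n: int, k: int) -> float:
    """Two-sided exact binomial p at 1/2 by rational point-probability sums."""
    if n == 0:
        return 1.0
    denom = Fraction(2) ** n
    p_obs = Fraction(math.comb(n, k), 1) / denom
    total = sum(
        (Fraction(math.comb(n, j), 1) / denom
         for j in range(n + 1)
         if Fraction(math.comb(n, j), 1) / denom <= p_obs),
        Fraction(0),
    )
    return float(min(total, Fraction(1)))


def all_2x3_tables(max_total: int):
    """Every 2x3 table of non-negative counts with grand total <= max_total."""
    for total in range(max_total + 1):
        for flat in itertools.product(range(total + 1), repeat=5):
            if sum(flat) <= total:
                last = total - sum(flat)
                yield (flat[0], flat[1], flat[2]), (flat[3], flat[4], last)


def panel_from_rows(rows, positions=None) -> HaplotypePanel:
    """Build a panel from string rows like '0110' (rows are chromosomes)."""
    alleles = np.array([[int(c) for c in row] for row in rows], dtype=np.int8)
    if positions is None:
        n_sites = alleles.shape[1]
        positions = (np.arange(n_sites) + 1) / (n_sites + 1)
    return HaplotypePanel(alleles=alleles, positions=np.asarray(positions,
                                                               dtype=float))


def identity_cohort(panel: HaplotypePanel) -> DiploidCohort:
    """Pair chromosomes (0,1), (2,3), ... in panel order."""
    pairs = np.arange(panel.n_chromosomes).reshape(-1, 2)
    return DiploidCohort(panel=panel, pairs=pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(20120607)


@pytest.fixture(scope="session")
def small_panels():
    """A batch of small simulated no-recombination panels for property tests."""
    from aimap.simulate import SimulationConfig, simulate_panels

    cfg = SimulationConfig(n_individuals=12, theta=12.0, n_reps=1)
    gen = np.random.default_rng(42)
    return [p for p in simulate_panels(cfg, gen, n_reps=30) if p.n_sites >= 3]
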