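"""The three allelic-imbalance mapping tests and supporting statistics.

Given individuals partitioned into AI (allelic-imbalance) and non-AI classes,
each candidate SNP is tested for linkage disequilibrium with the hypothetical
regulatory site:

* **contingency genotype test** — a 2x3 Fisher exact test on
  {AI, non-AI} x {AA, Aa, aa} genotype counts.  Uses no phase information,
  which makes it immune to haplotype-phasing errors.
* **binomial haplotype test** — among AI individuals heterozygous at the SNP,
  the count of chromosomes where a given allele sits on the up-regulated copy
  is compared with a fair coin (exact two-sided binomial at p = 1/2).
* **linear regression test** — a categorical AI response (+1/-1 for AI by
  direction, 0 for non-AI) regressed on the ordered-allele contrast between
  chromosomes 1 and 2; two-sided t-test on the slope.

Scalar entry points return :class:`TestResult`; the ``*_matrix`` variants are
vectorised across the SNPs of a phased cohort and are what the simulation
experiments run.  Exact p-values are computed by enumeration (2x3 tables) or
from cached binomial tail tables; two-sided rules follow the point-probability
criterion with a relative tie tolerance of 1e-7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom
from scipy.stats import t as t_dist

__all__ = [
    "ContingencyTable2x3",
    "TestResult",
    "LDResult",
    "fisher_exact_2x3",
    "fisher_2x3_pvalue",
    "contingency_genotype_test",
    "contingency_test_matrix",
    "binomial_haplotype_test",
    "binomial_test_matrix",
    "linear_regression_test",
    "regression_test_matrix",
    "ld_r2",
    "classify_trio_position",
]

_TIE_RTOL = 1e-7
_P_FLOOR = 1e-300  # keeps log(1/p) finite for zero-residual fits


@dataclass(frozen=True)
class ContingencyTable2x3:
    """Counts of {AI, non-AI} rows by {AA, Aa, aa} genotype columns."""

    counts: tuple[tuple[int, int, int], tuple[int, int, int]]

    @classmethod
    def from_arrays(cls, ai_row, non_ai_row) -> "ContingencyTable2x3":
        a = tuple(int(x) for x in ai_row)
        b = tuple(int(x) for x in non_ai_row)
        if len(a) != 3 or len(b) != 3 or min(a + b) < 0:
            raise ValueError("need two rows of three non-negative counts")
        return cls((a, b))

    @property
    def total(self) -> int:
        return sum(self.counts[0]) + sum(self.counts[1])


@dataclass
class TestResult:
    """Outcome of one mapping test at one SNP."""

    test: str
    p_value: float
    statistic: float
    n_used: int
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must be in (0, 1]")

    @property
    def log10_inv_p(self) -> float:
        return float(-np.log10(self.p_value))


@dataclass
class LDResult:
    r2: float
    D: float
    freq1: float
    freq2: float
    flags: set[str] = field(default_factory=set)


# --------------------------------------------------------------------------
# 2x3 Fisher exact test
# --------------------------------------------------------------------------

_LGAMMA = gammaln(np.arange(1, 1026))  # log(k!) for k = 0..1024


def _log_comb(n, k):
    return _LGAMMA[n] - _LGAMMA[k] - _LGAMMA[n - k]


_FISHER_CACHE: dict[tuple[int, int, int, int, int, int], float] = {}


def fisher_2x3_pvalue(ai_row, non_ai_row) -> float:
    """Exact two-sided p for a 2x3 table, memoised on the six counts.

    The p-value is the total probability, under the multivariate
    hypergeometric null with the observed margins, of every table whose
    probability does not exceed the observed table's (point-probability rule,
    ties included within a 1e-7 relative tolerance).
    """
    a = (int(ai_row[0]), int(ai_row[1]), int(ai_row[2]))
    b = (int(non_ai_row[0]), int(non_ai_row[1]), int(non_ai_row[2]))
    key = a + b
    cached = _FISHER_CACHE.get(key)
    if cached is not None:
        return cached

    c = (a[0] + b[0], a[1] + b[1], a[2] + b[2])
    r1 = sum(a)
    r2 = sum(b)
    N = r1 + r2
    # a degenerate margin admits a single table
    if r1 == 0 or r2 == 0 or sum(cj > 0 for cj in c) < 2:
        _FISHER_CACHE[key] = 1.0
        return 1.0

    a1 = np.arange(min(r1, c[0]) + 1)
    a2 = np.arange(min(r1, c[1]) + 1)
    A1, A2 = np.meshgrid(a1, a2, indexing="ij")
    A3 = r1 - A1 - A2
    valid = (A3 >= 0) & (A3 <= c[2])
    A3c = np.clip(A3, 0, c[2])
    logp = (
        _log_comb(c[0], A1)
        + _log_comb(c[1], A2)
        + _log_comb(c[2], A3c)
        - _log_comb(N, r1)
    )
    log_obs = (
        _log_comb(c[0], a[0])
        + _log_comb(c[1], a[1])
        + _log_comb(c[2], a[2])
        - _log_comb(N, r1)
    )
    take = valid & (logp <= log_obs + np.log1p(_TIE_RTOL))
    p = float(np.exp(logp[take]).sum())
    p = min(p, 1.0)
    _FISHER_CACHE[key] = p
    return p


def fisher_exact_2x3(table: ContingencyTable2x3) -> TestResult:
    """Fisher's exact test on a 2x3 contingency table."""
    a, b = table.counts
    flags: set[str] = set()
    c = tuple(a[i] + b[i] for i in range(3))
    if sum(a) == 0 or sum(b) == 0 or sum(cj > 0 for cj in c) < 2:
        flags.add("degenerate")
    p = fisher_2x3_pvalue(a, b)
    return TestResult(
        test="contingency",
        p_value=p,
        statistic=p,
        n_used=table.total,
        flags=flags,
    )


def contingency_genotype_test(genotypes, ai) -> TestResult:
    """Genotype-based mapping test at one SNP.

    ``genotypes`` holds 0/1/2 copies of one allele per individual (unordered;
    phase never enters), with negative values meaning missing.  ``ai`` is the
    boolean AI flag per individual.  Individuals with missing genotypes are
    dropped from the table.
    """
    g = np.asarray(genotypes)
    ai = np.asarray(ai, dtype=bool)
    keep = g >= 0
    g, ai = g[keep], ai[keep]
    rows = []
    for mask in (ai, ~ai):
        rows.append([int((g[mask] == k).sum()) for k in (0, 1, 2)])
    table = ContingencyTable2x3.from_arrays(*rows)
    res = fisher_exact_2x3(table)
    res.n_used = int(keep.sum())
    if ai.all() or not ai.any():
        res.flags.add("degenerate")
    return res


def contingency_test_matrix(genotypes, ai, columns=None) -> np.ndarray:
    """Vectorised contingency test across the columns of a genotype matrix.

    ``genotypes`` is (n_individuals x n_sites) with entries 0/1/2; returns an
    array of p-values (1.0 where not computed).
    """
    G = np.asarray(genotypes)
    ai = np.asarray(ai, dtype=bool)
    n_sites = G.shape[1]
    if columns is None:
        columns = np.arange(n_sites)
    p = np.ones(n_sites)
    ga, gb = G[ai], G[~ai]
    counts_a = np.stack([(ga == k).sum(axis=0) for k in (0, 1, 2)])
    counts_b = np.stack([(gb == k).sum(axis=0) for k in (0, 1, 2)])
    for j in columns:
        p[j] = fisher_2x3_pvalue(counts_a[:, j], counts_b[:, j])
    return p


# --------------------------------------------------------------------------
# binomial haplotype test
# --------------------------------------------------------------------------

_BINOM_ROWS: dict[int, np.ndarray] = {}


def _binom_half_row(n: int) -> np.ndarray:
    """Two-sided exact p at p=1/2 for every k of a given n (cached)."""
    row = _BINOM_ROWS.get(n)
    if row is None:
        pmf = binom.pmf(np.arange(n + 1), n, 0.5)
        row = np.array(
            [min(1.0, pmf[pmf <= pmf[k] * (1 + _TIE_RTOL)].sum())
             for k in range(n + 1)]
        )
        _BINOM_ROWS[n] = row
    return row


def binomial_haplotype_test(hap1, hap2, direction) -> TestResult:
    """Binomial haplotype test at one SNP.

    ``hap1``/``hap2`` are the SNP alleles on chromosomes 1 and 2 of the AI
    individuals; ``direction`` says which chromosome is up-regulated.  Only AI
    individuals heterozygous at the SNP contribute; ``k`` counts those with
    the derived allele on the up-regulated chromosome, tested against a fair
    coin.
    """
    h1 = np.asarray(hap1)
    h2 = np.asarray(hap2)
    d = np.asarray(direction)
    if np.any(d == 0):
        raise ValueError("binomial test needs a direction for every AI individual")
    het = h1 != h2
    up = np.where(d == 1, h1, h2)
    n = int(het.sum())
    k = int(((up == 1) & het).sum())
    if n == 0:
        return TestResult("binomial", 1.0, 0.0, 0, {"degenerate"})
    p = float(_binom_half_row(n)[k])
    return TestResult("binomial", p, float(k), n)


def binomial_test_matrix(h1_ai, h2_ai, direction_ai) -> np.ndarray:
    """Vectorised binomial test across SNP columns for the AI individuals."""
    h1 = np.asarray(h1_ai)
    h2 = np.asarray(h2_ai)
    d = np.asarray(direction_ai).reshape(-1, 1)
    up = np.where(d == 1, h1, h2)
    het = h1 != h2
    n = het.sum(axis=0)
    k = ((up == 1) & het).sum(axis=0)
    nmax = int(n.max(initial=0))
    table = np.ones((nmax + 1, nmax + 1))
    for m in np.unique(n):
        if m > 0:
            table[m, : m + 1] = _binom_half_row(int(m))
    return table[n, k]


# --------------------------------------------------------------------------
# linear regression test
# --------------------------------------------------------------------------

def regression_test_matrix(h1, h2, response) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS slope t-test across SNP columns.

    ``response`` is the categorical AI intensity per individual (+1/-1/0); the
    predictor at each SNP is the ordered-allele contrast chromosome1 -
    chromosome2.  Returns (slopes, p-values).  Constant predictors give p = 1;
    zero-residual fits with a nonzero slope get the 1e-300 floor.
    """
    x = np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float)
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    xm = x - x.mean(axis=0)
    ym = y - y.mean()
    sxx = (xm * xm).sum(axis=0)
    sxy = (xm * ym[:, None]).sum(axis=0)
    syy = float((ym * ym).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    if syy <= 0 or n < 3:
        return slope, np.ones_like(slope)
    r2 = np.where(sxx > 0, sxy**2 / (np.where(sxx > 0, sxx, 1.0) * syy), 0.0)
    df = n - 2
    perfect = (r2 >= 1.0 - 1e-12) & (sxx > 0)
    r2c = np.clip(r2, 0.0, 1.0 - 1e-15)
    t = np.sqrt(r2c * df / (1.0 - r2c))
    p = 2.0 * t_dist.sf(t, df)
    p = np.where(sxx <= 0, 1.0, p)
    p = np.where(perfect, _P_FLOOR, p)
    p = np.clip(p, _P_FLOOR, 1.0)
    return slope, p


def linear_regression_test(hap1, hap2, ai) -> TestResult:
    """Categorical-AI linear regression test at one SNP.

    ``hap1``/``hap2`` are the SNP's ordered alleles for all individuals; ``ai``
    is an :class:`~aimap.ai_status.AIStatusVector` (or anything with ``ai`` and
    ``direction`` attributes).  Response is +1/-1 by AI direction and 0 for
    non-AI individuals.
    """
    h1 = np.asarray(hap1).reshape(-1, 1)
    h2 = np.asarray(hap2).reshape(-1, 1)
    y = np.where(ai.ai, ai.direction, 0)
    if y.shape[0] < 3:
        raise ValueError("regression needs at least 3 individuals")
    slope, p = regression_test_matrix(h1, h2, y)
    flags: set[str] = set()
    x = h1[:, 0] - h2[:, 0]
    if np.all(x == x[0]):
        flags.add("degenerate")
    if p[0] <= _P_FLOOR:
        flags.add("perfect_fit")
    return TestResult("regression", float(p[0]), float(slope[0]),
                      y.shape[0], flags)


# --------------------------------------------------------------------------
# linkage disequilibrium and haplotype-trio classification
# --------------------------------------------------------------------------

def ld_r2(site1, site2) -> LDResult:
    """Pairwise LD between two sites given per-chromosome alleles.

    D = f11 - p1 p2 over derived alleles; r^2 = D^2 / (p1 q1 p2 q2).
    """
    a = np.asarray(site1, dtype=float)
    b = np.asarray(site2, dtype=float)
    p1 = a.mean()
    p2 = b.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return LDResult(float("nan"), float("nan"), p1, p2, {"undefined"})
    f11 = (a * b).mean()
    D = f11 - p1 * p2
    r2 = D * D / (p1 * (1 - p1) * p2 * (1 - p2))
    return LDResult(float(r2), float(D), float(p1), float(p2))


def classify_trio_position(site_a, site_r) -> str:
    """Classify the mutation history of an (A-site, R-site) pair.

    With known ancestral states, the set of two-site haplotypes present
    identifies the order of the two mutations on the genealogy: a missing
    derived-A/ancestral-R haplotype means the A mutation arose on an r
    background (``below``); a missing ancestral-A/derived-R haplotype means
    the A mutation came first (``above``); a missing doubly derived haplotype
    means the mutations sit on disjoint branches (``parallel``).  All four
    haplotypes present means the pair is at or near linkage equilibrium
    (``all_four``); fewer than three is ``undefined``.
    """
    a = np.asarray(site_a, dtype=bool)
    r = np.asarray(site_r, dtype=bool)
    present = {(bool(x), bool(y)) for x, y in zip(a, r)}
    if len(present) < 3:
        return "undefined"
    if len(present) == 4:
        return "all_four"
    missing = ({(False, False), (False, True), (True, False), (True, True)}
               - present).pop()
    return {
        (True, False): "below",     # derived A never on ancestral R
        (False, True): "above",     # ancestral A never with derived R
        (True, True): "parallel",   # derived alleles never together
        (False, False): "undefined",  # no ancestral haplotype: not a clean trio
    }[missing]
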