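"""Coalescent haplotype panels for allelic-imbalance mapping experiments.

Panels are binary haplotype matrices (0 = ancestral, 1 = derived allele) with
per-site positions on [0, 1], generated internally with msprime under an
infinite-sites model, or parsed from standard ``ms``-format output so published
runs can be reproduced bit-for-bit.  On top of a panel the module selects
regulatory sites (bi- or tri-allelic), pairs chromosomes into diploid
individuals and locates phase-tracking SNPs for switch-error accounting.

Scaling convention: the simulator works on a unit-length sequence with one
haploid population of size 1 (pairwise coalescence rate 1, expected pairwise
tree height 1 generation), so per-unit mutation and recombination rates of
``theta / 2`` and ``rho / 2`` reproduce the standard coalescent scaling
(expected segregating sites ``theta * H_{n-1}``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import msprime
import numpy as np

__all__ = [
    "SimulationConfig",
    "HotspotSpec",
    "HaplotypePanel",
    "RegulatorySite",
    "DiploidCohort",
    "simulate_panel",
    "simulate_panels",
    "parse_ms_output",
    "write_ms_output",
    "select_regulatory_site",
    "pair_into_diploids",
    "make_triallelic_site",
    "flag_tracking_snp",
]


@dataclass(frozen=True)
class HotspotSpec:
    """A single recombination hotspot concentrating most of the genetic map.

    ``mass_fraction`` of the total recombination rate falls inside a window of
    ``width_bp`` base pairs centred at ``center_fraction`` of the sequence.
    """

    center_fraction: float = 0.5
    width_bp: float = 1000.0
    mass_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.mass_fraction <= 1.0):
            raise ValueError("mass_fraction must be in (0, 1]")
        if self.width_bp <= 0:
            raise ValueError("width_bp must be positive")
        if not (0.0 < self.center_fraction < 1.0):
            raise ValueError("center_fraction must be inside (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one coalescent experiment.

    theta and rho are population-scaled rates for the whole simulated segment
    (theta = 4*Ne*mu*L).  ``Ne`` and ``mu`` are informational; when both are
    given the derived sequence length is ``theta / (4 Ne mu)``.
    """

    n_individuals: int = 50
    theta: float = 50.0
    rho: float = 0.0
    n_reps: int = 2000
    hotspot: HotspotSpec | None = None
    seed: int | None = None
    Ne: float | None = 12_500.0
    mu: float | None = 2e-8

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 diploid individuals")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals

    @property
    def seq_length_bp(self) -> float | None:
        if self.Ne is None or self.mu is None:
            return None
        return self.theta / (4.0 * self.Ne * self.mu)


@dataclass
class HaplotypePanel:
    """Binary haplotype matrix: rows are chromosomes, columns are sites.

    ``positions`` are site coordinates on [0, 1], strictly increasing.
    """

    alleles: np.ndarray
    positions: np.ndarray
    seq_length_bp: float | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions length must equal the site count")
        if self.n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary (0 ancestral, 1 derived)")

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_sites == 0

    def derived_freq(self) -> np.ndarray:
        """Per-site derived-allele frequency across chromosomes."""
        return self.alleles.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.derived_freq()
        return np.minimum(f, 1.0 - f)

    def positions_bp(self) -> np.ndarray:
        if self.seq_length_bp is None:
            raise ValueError("panel has no base-pair scale")
        return self.positions * self.seq_length_bp


@dataclass(frozen=True)
class RegulatorySite:
    """The (hypothetical) cis-regulatory polymorphism planted in a panel.

    Bi-allelic sites carry one index; tri-allelic regulatory sites are built
    from two SNPs and carry an ``expression_map`` from two-site haplotype class
    to expression rank (0 lowest).  Haplotype classes are coded
    ``2 * allele(site1) + allele(site2)``.
    """

    site_indices: tuple[int, ...]
    target_r_freq: float
    achieved_r_freq: float
    expression_map: dict[int, int] | None = None
    position_class: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.achieved_r_freq < 1.0):
            raise ValueError("achieved_r_freq must be inside (0, 1)")
        if self.expression_map is not None:
            if len(set(self.expression_map.values())) != 3:
                raise ValueError("tri-allelic expression_map needs 3 distinct ranks")

    @property
    def is_triallelic(self) -> bool:
        return len(self.site_indices) == 2

    @property
    def index(self) -> int:
        """Index of the (single) regulatory SNP; bi-allelic sites only."""
        if self.is_triallelic:
            raise ValueError("tri-allelic site has two indices")
        return self.site_indices[0]


@dataclass
class DiploidCohort:
    """Individuals as ordered chromosome pairs over a haplotype panel.

    Pair order is meaningful: column 0 is "chromosome 1", column 1 is
    "chromosome 2" of each individual, the arbitrary numbering that phased
    tests refer to.
    """

    panel: HaplotypePanel
    pairs: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n_individuals, 2) array")

    @property
    def n_individuals(self) -> int:
        return self.pairs.shape[0]

    def haplotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """Phased allele matrices (chromosome 1, chromosome 2), each n x S."""
        return (
            self.panel.alleles[self.pairs[:, 0]].copy(),
            self.panel.alleles[self.pairs[:, 1]].copy(),
        )

    def genotypes(self) -> np.ndarray:
        """Unordered genotype matrix (0, 1, 2 copies of the derived allele)."""
        h1, h2 = self.haplotypes()
        return h1 + h2


def _rate_map(config: SimulationConfig) -> msprime.RateMap | float:
    """Per-unit recombination rate (map) on the unit sequence."""
    rate_total = config.rho / 2.0  # haploid N = 1: scaled rate is rho / 2
    hs = config.hotspot
    if hs is None or config.rho == 0:
        return rate_total
    if config.seq_length_bp is None:
        raise ValueError("hotspot width in bp needs Ne and mu to set a scale")
    width = hs.width_bp / config.seq_length_bp
    lo = hs.center_fraction - width / 2.0
    hi = hs.center_fraction + width / 2.0
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("hotspot window falls outside the sequence")
    rate_in = hs.mass_fraction * rate_total / width
    rate_out = (1.0 - hs.mass_fraction) * rate_total / (1.0 - width)
    return msprime.RateMap(
        position=[0.0, lo, hi, 1.0], rate=[rate_out, rate_in, rate_out]
    )


def simulate_panel(config: SimulationConfig, seed: int | None = None) -> HaplotypePanel:
    """Simulate one haplotype panel of ``2 * n_individuals`` chromosomes.

    Mutations follow an infinite-sites binary model, so every site is
    bi-allelic with known ancestral state.  A replicate may carry zero
    segregating sites (an empty panel); callers discard those.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    return next(simulate_panels(config, rng, n_reps=1))


def simulate_panels(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_reps: int | None = None,
) -> Iterator[HaplotypePanel]:
    """Yield ``n_reps`` independent panels drawing seeds from ``rng``."""
    if n_reps is None:
        n_reps = config.n_reps
    rate = _rate_map(config)
    for _ in range(n_reps):
        ts = msprime.sim_ancestry(
            samples=config.n_chromosomes,
            ploidy=1,
            population_size=1.0,
            sequence_length=1.0,
            recombination_rate=rate,
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=config.theta / 2.0,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        alleles = mts.genotype_matrix().T.astype(np.int8)
        yield HaplotypePanel(
            alleles=alleles,
            positions=mts.sites_position.copy(),
            seq_length_bp=config.seq_length_bp,
        )


def parse_ms_output(stream: io.TextIOBase | str) -> list[HaplotypePanel]:
    """Parse standard ms-format output into one panel per replicate block.

    Expects the usual ``//`` / ``segsites:`` / ``positions:`` structure with
    0/1 haplotype rows.  Raises ``ValueError`` with a line number on ragged
    rows or non-binary characters.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    panels: list[HaplotypePanel] = []
    lines = stream.readlines()
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].startswith("//"):
            i += 1
            continue
        i += 1
        # skip blank lines between the block marker and the header
        while i < n and not lines[i].strip():
            i += 1
        if i >= n or not lines[i].startswith("segsites:"):
            raise ValueError(f"line {i + 1}: expected 'segsites:' after '//'")
        segsites = int(lines[i].split(":", 1)[1])
        i += 1
        if segsites == 0:
            panels.append(
                HaplotypePanel(np.zeros((0, 0), np.int8), np.zeros(0))
            )
            continue
        if i >= n or not lines[i].startswith("positions:"):
            raise ValueError(f"line {i + 1}: expected 'positions:'")
        positions = np.array([float(x) for x in lines[i].split()[1:]])
        if len(positions) != segsites:
            raise ValueError(f"line {i + 1}: {len(positions)} positions, "
                             f"segsites: {segsites}")
        i += 1
        rows = []
        while i < n and lines[i].strip() and not lines[i].startswith("//"):
            row = lines[i].strip()
            if len(row) != segsites:
                raise ValueError(
                    f"line {i + 1}: row of length {len(row)}, expected {segsites}"
                )
            if set(row) - {"0", "1"}:
                raise ValueError(f"line {i + 1}: non-binary character in row")
            rows.append([int(c) for c in row])
            i += 1
        if not rows:
            raise ValueError(f"line {i + 1}: replicate block with no haplotypes")
        panels.append(HaplotypePanel(np.array(rows, np.int8), positions))
    return panels


def write_ms_output(panels: Sequence[HaplotypePanel], stream: io.TextIOBase,
                    header: str = "aimap simulate") -> None:
    """Write panels as an ms-format stream (inverse of :func:`parse_ms_output`)."""
    stream.write(f"{header}\n\n")
    for panel in panels:
        stream.write("//\n")
        stream.write(f"segsites: {panel.n_sites}\n")
        if panel.is_empty:
            stream.write("\n")
            continue
        pos = " ".join(f"{p:.6f}" for p in panel.positions)
        stream.write(f"positions: {pos}\n")
        for row in panel.alleles:
            stream.write("".join(map(str, row)) + "\n")
        stream.write("\n")


def select_regulatory_site(
    panel: HaplotypePanel,
    target_r_freq: float,
    window: float = 0.05,
    rule: str = "nearest",
    max_position: float | None = None,
) -> RegulatorySite | None:
    """Pick the regulatory SNP at a target derived-allele frequency.

    ``rule='nearest'`` returns the site whose derived frequency is nearest the
    target within ``±window`` (ties to the lowest site index).
    ``rule='leftmost'`` returns the lowest-position qualifying site, which is a
    frequency-unbiased draw from the qualifying set and pins the site to one
    sequence end when ``max_position`` restricts the search.  Returns ``None``
    when no site qualifies (the replicate is then dropped upstream).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if panel.is_empty:
        return None
    f = panel.derived_freq()
    ok = np.abs(f - target_r_freq) <= window
    if max_position is not None:
        ok &= panel.positions <= max_position
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    if rule == "nearest":
        best = idx[np.argmin(np.abs(f[idx] - target_r_freq))]
    elif rule == "leftmost":
        best = idx[np.argmin(panel.positions[idx])]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return RegulatorySite(
        site_indices=(int(best),),
        target_r_freq=target_r_freq,
        achieved_r_freq=float(f[best]),
    )


def pair_into_diploids(
    panel: HaplotypePanel, seed: int | np.random.Generator | None = None
) -> DiploidCohort:
    """Randomly pair the panel's chromosomes into diploid individuals.

    A uniform random perfect matching; the order inside each pair defines
    chromosome 1 vs chromosome 2.
    """
    if panel.n_chromosomes % 2:
        raise ValueError("cannot pair an odd number of chromosomes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perm = rng.permutation(panel.n_chromosomes)
    return DiploidCohort(panel=panel, pairs=perm.reshape(-1, 2))


# haplotype-class codes for a two-site regulatory region:
# 2 * allele(site1) + allele(site2)
_H00, _H01, _H10, _H11 = 0, 1, 2, 3


def make_triallelic_site(
    panel: HaplotypePanel,
    freqs: tuple[float, float, float] = (0.4, 0.3, 0.3),
    position_class: str = "below",
    tolerance: float = 0.05,
) -> RegulatorySite | None:
    """Build a tri-allelic regulatory site from two SNPs of a no-recombination panel.

    The three haplotype classes (ancestral, intermediate, derived) must occur
    at ``freqs`` within ``±tolerance`` each, and exactly three of the four
    two-site haplotypes may be present.  ``position_class`` fixes the
    background of the second mutation: ``'below'`` requires it on chromosomes
    already carrying the first derived allele (classes {00, 10, 11});
    ``'parallel'`` requires it on the ancestral background (classes
    {00, 10, 01}).  Site pairs are scanned in index order and the first
    qualifying pair wins.  The expression map ranks ancestral < intermediate <
    derived; in the parallel case the more frequent of the two single-mutant
    haplotypes is taken as the intermediate (the older mutation), ties to the
    left site.
    """
    if position_class not in ("below", "parallel"):
        raise ValueError("position_class must be 'below' or 'parallel'")
    if abs(sum(freqs) - 1.0) > 1e-9:
        raise ValueError("class frequencies must sum to 1")
    if panel.is_empty or panel.n_sites < 2:
        return None
    f_anc, f_int, f_der = freqs
    H = panel.alleles.astype(bool)
    f = panel.derived_freq()
    tol = tolerance

    if position_class == "below":
        # carrier of the first mutation spans intermediate + derived classes
        cand1 = np.flatnonzero(np.abs(f - (f_int + f_der)) <= 2 * tol)
        cand2 = np.flatnonzero(np.abs(f - f_der) <= tol)
    else:
        cand1 = np.flatnonzero(np.abs(f - f_int) <= tol)
        cand2 = np.flatnonzero(np.abs(f - f_der) <= tol)

    for i in cand1:
        for j in cand2:
            if i == j:
                continue
            gi, gj = H[:, i], H[:, j]
            n = panel.n_chromosomes
            f11 = np.count_nonzero(gi & gj) / n
            f10 = np.count_nonzero(gi & ~gj) / n
            f01 = np.count_nonzero(~gi & gj) / n
            f00 = 1.0 - f11 - f10 - f01
            if position_class == "below":
                if f01 != 0 or f11 == 0 or f10 == 0:
                    continue  # needs a clean nested trio
                if (abs(f00 - f_anc) > tol or abs(f10 - f_int) > tol
                        or abs(f11 - f_der) > tol):
                    continue
                expr = {_H00: 0, _H10: 1, _H11: 2}
                achieved = f10 + f11
            else:
                if f11 != 0 or f10 == 0 or f01 == 0:
                    continue  # needs disjoint single-mutant classes
                pair_ok = (
                    abs(f00 - f_anc) <= tol
                    and abs(min(f10, f01) - min(f_int, f_der)) <= tol
                    and abs(max(f10, f01) - max(f_int, f_der)) <= tol
                )
                if not pair_ok:
                    continue
                if f10 >= f01:
                    expr = {_H00: 0, _H10: 1, _H01: 2}
                else:
                    expr = {_H00: 0, _H01: 1, _H10: 2}
                achieved = f10 + f01
            return RegulatorySite(
                site_indices=(int(i), int(j)),
                target_r_freq=f_int + f_der,
                achieved_r_freq=float(achieved),
                expression_map=expr,
                position_class=position_class,
            )
    return None


def flag_tracking_snp(
    panel: HaplotypePanel,
    rsite: RegulatorySite,
    cohort: DiploidCohort,
    ai_mask: np.ndarray,
    terminal_fraction: float = 0.1,
) -> int:
    """Locate a phase-tracking SNP at the sequence end opposite the R site.

    The tracking SNP must lie within the terminal ``terminal_fraction`` of the
    sequence farthest from the regulatory site and be heterozygous in every AI
    individual, so the true assignment of its alleles to the up- and
    down-regulated chromosomes can be recorded before rephasing.  When several
    sites qualify the one farthest from the R site is chosen.
    """
    ai_mask = np.asarray(ai_mask, dtype=bool)
    rpos = panel.positions[rsite.site_indices[0]]
    if rpos <= 0.5:
        in_window = panel.positions >= 1.0 - terminal_fraction
    else:
        in_window = panel.positions <= terminal_fraction
    h1, h2 = cohort.haplotypes()
    het_in_ai = (h1[ai_mask] != h2[ai_mask]).all(axis=0)
    idx = np.flatnonzero(in_window & het_in_ai)
    if idx.size == 0:
        raise ValueError("no tracking SNP heterozygous in all AI individuals "
                         "at the far end of the sequence")
    far = idx[np.argmax(np.abs(panel.positions[idx] - rpos))]
    return int(far)
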