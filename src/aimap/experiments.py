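"""End-to-end simulation experiments: power, FPR, hotspot crossing, tri-allelic sites.

Three reproducible, seeded recipes mirror the package's benchmark designs:

* ``run_table1`` — no-recombination (or uniform-recombination) replicates,
  regulatory SNP selected at target derived frequencies {0.15, 0.35, 0.5,
  0.85}; pooled power of the three tests, plus false-positive rates under
  random AI assignment with the expected heterozygote counts {12, 22, 25, 13}.
* ``run_table3`` — a central 1 kb hotspot carrying 90% of the recombination
  between the regulatory site (pinned to one sequence end) and the rest of
  the sequence; reports the proportion of significant SNPs that map across
  the hotspot, with true phase or after synthetic switch-error corruption.
* ``run_table4`` — a tri-allelic regulatory site assembled from two SNPs at
  haplotype-class frequencies 0.4/0.3/0.3, in both mutation-order
  configurations; pooled power plus FPR with 33 random AI individuals.

Power and FPR are pooled over SNPs (every A-site SNP with MAF >= ``maf_min``
across all retained replicates counts once), and every run is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ai_status import (AIStatusVector, assign_ai_from_rsite,
                        assign_ai_triallelic, random_ai_assignment)
from .evaluation import inject_switch_errors
from .simulate import (DiploidCohort, HaplotypePanel, HotspotSpec,
                       RegulatorySite, SimulationConfig, make_triallelic_site,
                       pair_into_diploids, select_regulatory_site,
                       simulate_panels)
from .stats import (binomial_test_matrix, contingency_test_matrix,
                    regression_test_matrix)

__all__ = [
    "ExperimentRecipe",
    "TESTS",
    "R_TARGETS",
    "K_AI_NULL",
    "run_table1",
    "run_table3",
    "run_table4",
    "Table1Result",
    "Table3Result",
    "Table4Result",
]

TESTS = ("binomial", "contingency", "regression")
R_TARGETS = (0.15, 0.35, 0.5, 0.85)

# expected Rr heterozygote counts among 50 diploids at the four achieved
# r frequencies; used verbatim for the null (random-AI) runs
K_AI_NULL = {0.15: 12, 0.35: 22, 0.5: 25, 0.85: 13}

# regulatory-SNP selection windows reproducing the benchmark achieved-frequency
# distributions (see docs/methods.md)
R_WINDOWS = {0.15: 0.05, 0.35: 0.10, 0.5: 0.10, 0.85: 0.10}


@dataclass(frozen=True)
class ExperimentRecipe:
    """Bundle of design parameters shared by the three experiment runners."""

    name: str
    config: SimulationConfig
    r_targets: tuple[float, ...] = R_TARGETS
    alpha: float = 0.01
    maf_min: float = 0.05
    k_ai: dict[float, int] = field(default_factory=lambda: dict(K_AI_NULL))
    windows: dict[float, float] = field(default_factory=lambda: dict(R_WINDOWS))


def table1_recipe(reps: int = 2000, recombination: bool = False,
                  seed: int | None = None) -> ExperimentRecipe:
    cfg = SimulationConfig(n_individuals=50, theta=50.0,
                           rho=25.0 if recombination else 0.0,
                           n_reps=reps, seed=seed)
    return ExperimentRecipe(name="table1", config=cfg)


def table3_recipe(reps: int = 1000, seed: int | None = None) -> ExperimentRecipe:
    cfg = SimulationConfig(
        n_individuals=50, theta=100.0, rho=50.0, n_reps=reps, seed=seed,
        hotspot=HotspotSpec(center_fraction=0.5, width_bp=1000.0,
                            mass_fraction=0.9),
    )
    return ExperimentRecipe(name="table3", config=cfg)


def table4_recipe(reps: int = 2000, seed: int | None = None) -> ExperimentRecipe:
    cfg = SimulationConfig(n_individuals=50, theta=50.0, rho=0.0,
                           n_reps=reps, seed=seed)
    return ExperimentRecipe(name="table4", config=cfg)


def _phased_pvalues(h1: np.ndarray, h2: np.ndarray, status: AIStatusVector,
                    tests=TESTS) -> dict[str, np.ndarray]:
    """P-value arrays over all SNP columns of a phased cohort."""
    out: dict[str, np.ndarray] = {}
    if "contingency" in tests:
        out["contingency"] = contingency_test_matrix(h1 + h2, status.ai)
    if "binomial" in tests:
        ai = status.ai
        out["binomial"] = binomial_test_matrix(h1[ai], h2[ai],
                                               status.direction[ai])
    if "regression" in tests:
        y = np.where(status.ai, status.direction, 0)
        _, out["regression"] = regression_test_matrix(h1, h2, y)
    return out


class _PooledCounts:
    """Significant / total SNP counts pooled across replicates."""

    def __init__(self) -> None:
        self.sig = 0
        self.total = 0

    def add(self, p: np.ndarray, cols: np.ndarray, alpha: float) -> None:
        self.sig += int((p[cols] < alpha).sum())
        self.total += cols.size

    @property
    def rate(self) -> float:
        return self.sig / self.total if self.total else float("nan")


def _a_site_columns(panel: HaplotypePanel, exclude: tuple[int, ...],
                    maf_min: float) -> np.ndarray:
    keep = panel.maf() >= maf_min
    for idx in exclude:
        keep[idx] = False
    return np.flatnonzero(keep)


@dataclass
class Table1Result:
    reps: int
    power: dict[str, dict[float, float]]
    fpr: dict[str, dict[float, float]]
    retained: dict[float, int]
    mean_achieved_freq: dict[float, float]
    mean_n_ai: dict[float, float]
    n_snps: dict[float, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for test in self.power:
            for target in self.power[test]:
                rows.append({
                    "test": test, "r_target": target,
                    "power": self.power[test][target],
                    "fpr": self.fpr[test][target],
                    "retained": self.retained[target],
                    "mean_achieved_freq": self.mean_achieved_freq[target],
                    "mean_n_ai": self.mean_n_ai[target],
                    "n_snps": self.n_snps[target],
                })
        return pd.DataFrame(rows)


def run_table1(recipe: ExperimentRecipe | None = None, reps: int | None = None,
               seed: int = 0, tests=TESTS,
               min_retained: int = 50) -> Table1Result:
    """Power and FPR of the three tests at the four regulatory frequencies."""
    if recipe is None:
        recipe = table1_recipe()
    if reps is None:
        reps = recipe.config.n_reps
    rng = np.random.default_rng(seed)
    targets = recipe.r_targets
    power = {t: {x: _PooledCounts() for x in targets} for t in tests}
    fpr = {t: {x: _PooledCounts() for x in targets} for t in tests}
    retained = {x: 0 for x in targets}
    sum_freq = {x: 0.0 for x in targets}
    sum_nai = {x: 0 for x in targets}

    for panel in simulate_panels(recipe.config, rng, n_reps=reps):
        if panel.is_empty:
            continue
        cohort = pair_into_diploids(panel, rng)
        h1, h2 = cohort.haplotypes()
        for target in targets:
            rsite = select_regulatory_site(
                panel, target, window=recipe.windows[target], rule="leftmost")
            if rsite is None:
                continue
            retained[target] += 1
            sum_freq[target] += rsite.achieved_r_freq
            status = assign_ai_from_rsite(cohort, rsite)
            sum_nai[target] += status.n_ai
            if status.n_ai == 0 or status.n_ai == cohort.n_individuals:
                continue
            cols = _a_site_columns(panel, rsite.site_indices, recipe.maf_min)
            if cols.size == 0:
                continue
            pvals = _phased_pvalues(h1, h2, status, tests)
            for test in tests:
                power[test][target].add(pvals[test], cols, recipe.alpha)
            null = random_ai_assignment(cohort.n_individuals,
                                        recipe.k_ai[target], rng)
            null_p = _phased_pvalues(h1, h2, null, tests)
            for test in tests:
                fpr[test][target].add(null_p[test], cols, recipe.alpha)

    low = [x for x in targets if retained[x] < min(min_retained, reps)]
    if low:
        raise RuntimeError(
            f"insufficient retained replicates for targets {low}: "
            f"{[retained[x] for x in low]}")
    return Table1Result(
        reps=reps,
        power={t: {x: power[t][x].rate for x in targets} for t in tests},
        fpr={t: {x: fpr[t][x].rate for x in targets} for t in tests},
        retained=retained,
        mean_achieved_freq={x: sum_freq[x] / retained[x] for x in targets},
        mean_n_ai={x: sum_nai[x] / retained[x] for x in targets},
        n_snps={x: power[tests[0]][x].total for x in targets},
    )


@dataclass
class Table3Result:
    reps: int
    crossing: dict[str, dict[float, float]]
    n_significant: dict[str, dict[float, int]]
    retained: dict[float, int]


def run_table3(recipe: ExperimentRecipe | None = None, reps: int | None = None,
               seed: int = 0, tests=TESTS, phase: str = "known",
               error_rate: float = 0.5,
               targets: tuple[float, ...] | None = None,
               end_fraction: float = 0.1) -> Table3Result:
    """Proportion of significant SNPs separated from the R site by the hotspot.

    The regulatory SNP is the leftmost qualifying site within the first
    ``end_fraction`` of the sequence, so the hotspot lies between it and the
    far (transcribed) end.  ``phase='injected_errors'`` corrupts the phased
    haplotypes with switch errors at the hotspot midpoint (probability
    ``error_rate`` per individual) before the haplotype-based tests run; the
    contingency test sees only genotypes and is unaffected by construction.
    """
    if recipe is None:
        recipe = table3_recipe()
    if reps is None:
        reps = recipe.config.n_reps
    if targets is None:
        targets = recipe.r_targets
    if phase not in ("known", "injected_errors"):
        raise ValueError("phase must be 'known' or 'injected_errors'")
    rng = np.random.default_rng(seed)
    sig_cross = {t: {x: 0 for x in targets} for t in tests}
    sig_total = {t: {x: 0 for x in targets} for t in tests}
    retained = {x: 0 for x in targets}
    midpoint = recipe.config.hotspot.center_fraction if recipe.config.hotspot else 0.5

    for panel in simulate_panels(recipe.config, rng, n_reps=reps):
        if panel.is_empty:
            continue
        cohort = pair_into_diploids(panel, rng)
        h1, h2 = cohort.haplotypes()
        for target in targets:
            rsite = select_regulatory_site(
                panel, target, window=recipe.windows[target],
                rule="leftmost", max_position=end_fraction)
            if rsite is None:
                continue
            retained[target] += 1
            status = assign_ai_from_rsite(cohort, rsite)
            if status.n_ai == 0 or status.n_ai == cohort.n_individuals:
                continue
            cols = _a_site_columns(panel, rsite.site_indices, recipe.maf_min)
            if cols.size == 0:
                continue
            # the draw is unconditional so both phase modes consume the same
            # random stream and are comparable replicate-for-replicate
            hit = np.flatnonzero(rng.random(cohort.n_individuals) < error_rate)
            if phase == "injected_errors":
                u1, u2 = inject_switch_errors(h1, h2, panel.positions, hit,
                                              midpoint)
            else:
                u1, u2 = h1, h2
            pvals = _phased_pvalues(u1, u2, status, tests)
            rpos = panel.positions[rsite.index]
            r_right = rpos > midpoint
            for test in tests:
                sig = cols[pvals[test][cols] < recipe.alpha]
                sig_total[test][target] += sig.size
                crossed = (panel.positions[sig] > midpoint) != r_right
                sig_cross[test][target] += int(crossed.sum())

    crossing = {
        t: {x: (sig_cross[t][x] / sig_total[t][x]
                if sig_total[t][x] else float("nan"))
            for x in targets}
        for t in tests
    }
    return Table3Result(reps=reps, crossing=crossing,
                        n_significant=sig_total, retained=retained)


@dataclass
class Table4Result:
    reps: int
    power: dict[str, dict[str, float]]      # test -> position class -> power
    fpr: dict[str, float]
    retained: dict[str, int]
    mean_n_ai: dict[str, float]


def run_table4(recipe: ExperimentRecipe | None = None, reps: int | None = None,
               seed: int = 0, tests=TESTS,
               freqs: tuple[float, float, float] = (0.4, 0.3, 0.3),
               tolerance: float = 0.05, k_ai_null: int = 33,
               min_retained: int = 25) -> Table4Result:
    """Power of the three tests for a tri-allelic regulatory site.

    Each no-recombination replicate is searched for a two-SNP trio at class
    frequencies ``freqs`` in both mutation-order configurations ('below' =
    second mutation nested in the first, 'parallel' = disjoint backgrounds).
    AI individuals are those whose two haplotypes carry different expression
    ranks.  FPR assigns ``k_ai_null`` random AI individuals on the qualifying
    replicates.
    """
    if recipe is None:
        recipe = table4_recipe()
    if reps is None:
        reps = recipe.config.n_reps
    rng = np.random.default_rng(seed)
    classes = ("below", "parallel")
    power = {t: {c: _PooledCounts() for c in classes} for t in tests}
    fpr = {t: _PooledCounts() for t in tests}
    retained = {c: 0 for c in classes}
    sum_nai = {c: 0 for c in classes}

    for panel in simulate_panels(recipe.config, rng, n_reps=reps):
        if panel.is_empty or panel.n_sites < 3:
            continue
        cohort = pair_into_diploids(panel, rng)
        h1, h2 = cohort.haplotypes()
        fpr_done = False
        for cls in classes:
            rsite = make_triallelic_site(panel, freqs, cls, tolerance)
            if rsite is None:
                continue
            retained[cls] += 1
            status = assign_ai_triallelic(cohort, rsite)
            sum_nai[cls] += status.n_ai
            if status.n_ai == 0 or status.n_ai == cohort.n_individuals:
                continue
            cols = _a_site_columns(panel, rsite.site_indices, recipe.maf_min)
            if cols.size == 0:
                continue
            pvals = _phased_pvalues(h1, h2, status, tests)
            for test in tests:
                power[test][cls].add(pvals[test], cols, recipe.alpha)
            if not fpr_done:
                null = random_ai_assignment(cohort.n_individuals, k_ai_null,
                                            rng)
                null_p = _phased_pvalues(h1, h2, null, tests)
                for test in tests:
                    fpr[test].add(null_p[test], cols, recipe.alpha)
                fpr_done = True

    low = [c for c in classes if retained[c] < min(min_retained, reps)]
    if low:
        raise RuntimeError(
            f"insufficient tri-allelic replicates for {low}: "
            f"{[retained[c] for c in low]}")
    return Table4Result(
        reps=reps,
        power={t: {c: power[t][c].rate for c in classes} for t in tests},
        fpr={t: fpr[t].rate for t in tests},
        retained=retained,
        mean_n_ai={c: (sum_nai[c] / retained[c] if retained[c] else float("nan"))
                   for c in classes},
    )
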