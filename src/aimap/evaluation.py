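"""Replicate-level experiment metrics and phasing-error machinery.

Power and false-positive rate are pooled over SNPs: the fraction of tested
A-site SNPs (MAF >= 5% by default, regulatory site excluded) reaching
p < 0.01, under the causal AI model or under random AI assignment
respectively.  The module also provides the synthetic switch-error injector
used in place of an external phasing program, switch-error accounting against
a phase-tracking SNP, the hotspot-crossing proportion, the top-5 mapping
distance and site-frequency spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .simulate import HaplotypePanel

__all__ = [
    "power_estimate",
    "inject_switch_errors",
    "switch_error_count",
    "switch_error_class",
    "hotspot_crossing_proportion",
    "top5_distance",
    "site_frequency_spectrum",
    "PhaserAdapter",
    "SwitchErrorInjector",
]


def power_estimate(p_values, mafs, alpha: float = 0.01,
                   maf_min: float = 0.05) -> float:
    """Pooled fraction of MAF-qualifying SNPs significant at ``alpha``.

    Raises ``ValueError`` when no SNP passes the MAF filter (the caller
    normally pools counts across replicates before calling this).
    """
    p = np.asarray(p_values, dtype=float)
    maf = np.asarray(mafs, dtype=float)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError("no SNP passes the MAF filter")
    return float((p[keep] < alpha).mean())


def inject_switch_errors(hap1, hap2, positions, individuals,
                         breakpoint: float) -> tuple[np.ndarray, np.ndarray]:
    """Swap chromosome 1/2 alleles past ``breakpoint`` for chosen individuals.

    Emulates a phasing switch error: everything at positions > breakpoint
    moves to the other chromosome.  Involutive — applying the same swap twice
    restores the input.
    """
    h1 = np.array(hap1, copy=True)
    h2 = np.array(hap2, copy=True)
    pos = np.asarray(positions, dtype=float)
    tail = pos > breakpoint
    for i in np.atleast_1d(np.asarray(individuals, dtype=int)):
        h1[i, tail], h2[i, tail] = h2[i, tail].copy(), h1[i, tail].copy()
    return h1, h2


def switch_error_count(true_h1, true_h2, new_h1, new_h2, rsite_index: int,
                       tracking_index: int, ai_mask) -> tuple[int, list[int]]:
    """Count AI individuals whose phase flipped between R site and tracking SNP.

    For each AI individual, the truth records which chromosome carries the
    derived regulatory allele and which tracking allele rides with it; after
    rephasing, an error is flagged when the tracking allele assigned to the
    r-carrying chromosome disagrees with the truth.  Individuals not
    heterozygous at both sites in the rephased data are excluded (returned in
    the second element).
    """
    ai_idx = np.flatnonzero(np.asarray(ai_mask, dtype=bool))
    errors = 0
    excluded: list[int] = []
    for i in ai_idx:
        t1r, t2r = true_h1[i, rsite_index], true_h2[i, rsite_index]
        t1t, t2t = true_h1[i, tracking_index], true_h2[i, tracking_index]
        n1r, n2r = new_h1[i, rsite_index], new_h2[i, rsite_index]
        n1t, n2t = new_h1[i, tracking_index], new_h2[i, tracking_index]
        if t1r == t2r or t1t == t2t or n1r == n2r or n1t == n2t:
            excluded.append(int(i))
            continue
        true_linked = t1t if t1r == 1 else t2t   # tracking allele on r chromosome
        new_linked = n1t if n1r == 1 else n2t
        if true_linked != new_linked:
            errors += 1
    return errors, excluded


def switch_error_class(count: int) -> str:
    """The reporting class for a replicate's switch-error count."""
    return str(count) if count < 3 else "3+"


def hotspot_crossing_proportion(significant_positions, rsite_position: float,
                                hotspot_midpoint: float = 0.5) -> float:
    """Fraction of significant SNPs across the hotspot midpoint from the R site.

    SNPs inside the hotspot window are assigned a side by the midpoint.
    """
    pos = np.asarray(significant_positions, dtype=float)
    if pos.size == 0:
        raise ValueError("no significant SNPs")
    r_right = rsite_position > hotspot_midpoint
    return float(((pos > hotspot_midpoint) != r_right).mean())


def top5_distance(p_values, positions, rsite_position: float,
                  k: int = 5) -> tuple[float, bool]:
    """Mean distance to the R site of the k smallest-p SNPs.

    Ties in p are broken toward the R site.  Returns (mean distance,
    complete) where ``complete`` is False when fewer than k SNPs were
    available and all were used.
    """
    p = np.asarray(p_values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    dist = np.abs(pos - rsite_position)
    order = np.lexsort((dist, p))
    take = order[: min(k, p.size)]
    return float(dist[take].mean()), p.size >= k


def site_frequency_spectrum(panel: HaplotypePanel, fold: bool = False
                            ) -> np.ndarray:
    """Histogram of sites per derived-allele count (or minor count if folded).

    Bin ``i`` of the unfolded spectrum counts sites whose derived allele is on
    exactly ``i`` chromosomes; the folded spectrum uses the minor-allele count
    and has ``n // 2 + 1`` bins.
    """
    if panel.is_empty:
        n = panel.n_chromosomes if panel.alleles.size else 0
        size = (n // 2 + 1) if fold else max(n + 1, 1)
        return np.zeros(size, dtype=int)
    n = panel.n_chromosomes
    counts = panel.alleles.sum(axis=0)
    if fold:
        counts = np.minimum(counts, n - counts)
        return np.bincount(counts, minlength=n // 2 + 1)
    return np.bincount(counts, minlength=n + 1)


class PhaserAdapter(Protocol):
    """Contract for plugging an external phasing program into the pipeline.

    An adapter maps unordered genotypes to phased haplotypes; the package's
    experiments only require this call signature, so any external tool can be
    wired in by writing genotypes in its native format, running it, and
    reading the haplotypes back.
    """

    def phase(self, genotypes: np.ndarray, positions: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
        """Return (hap1, hap2) matrices consistent with ``genotypes``."""
        ...


@dataclass
class SwitchErrorInjector:
    """A synthetic 'phaser' that corrupts true haplotypes with switch errors.

    Stands in for an external phasing program when studying how phase errors
    degrade the haplotype-based tests: for each individual, with probability
    ``error_rate``, chromosome arms past ``breakpoint`` are swapped.
    """

    breakpoint: float = 0.5
    error_rate: float = 0.5
    seed: int | None = None

    def corrupt(self, hap1, hap2, positions) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        n = np.asarray(hap1).shape[0]
        hit = np.flatnonzero(rng.random(n) < self.error_rate)
        return inject_switch_errors(hap1, hap2, positions, hit, self.breakpoint)
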