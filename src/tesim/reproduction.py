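"""One round of sexual reproduction: parent sampling, meiosis, transposition.

Fecundity selection: each offspring draws its mother from the females and its
father from the males, independently and with replacement, with probability
proportional to fitness.  Meiosis follows the Haldane model: per chromosome a
Poisson number of crossovers (mean ``rr[cM/Mbp] * length[Mbp] / 100``) at
uniform positions, no interference, and free assortment between chromosomes.
Transposition happens after recombination, into the finished gamete: the
number of new copies is Poisson with mean ``u * n / 2`` where ``n`` is the
parent's diploid copy number, zero for piRNA-producing parents.  A candidate
landing on a site already occupied in the receiving gamete is discarded.

These functions are the single-offspring reference path; the generation-level
loop in :mod:`tesim.engine` uses compiled kernels implementing the same model.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeArchitecture
from .population import Individual, Population, is_pirna_producer

__all__ = [
    "ExtinctionError",
    "sample_parent_pair",
    "make_gamete",
    "transpose_into_gamete",
    "make_offspring",
]


class ExtinctionError(RuntimeError):
    """No viable mating pair: every female or every male has zero fitness."""


def _weighted_index(weights: np.ndarray, rng: np.random.Generator) -> int:
    cum = np.cumsum(weights)
    r = rng.random() * cum[-1]
    return int(np.searchsorted(cum, r, side="right"))


def sample_parent_pair(
    pop: Population,
    fitnesses: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw (mother_index, father_index) with probability proportional to fitness.

    ``fitnesses`` is the per-individual fitness vector for the current
    generation.  Raises :class:`ExtinctionError` when either sex has no
    individual with positive fitness.
    """
    w = np.asarray(fitnesses, dtype=np.float64)
    females = np.flatnonzero(pop.sex == 0)
    males = np.flatnonzero(pop.sex == 1)
    if females.size == 0 or w[females].sum() <= 0 or males.size == 0 or w[males].sum() <= 0:
        raise ExtinctionError("no viable female/male parent with positive fitness")
    mother = females[_weighted_index(w[females], rng)]
    father = males[_weighted_index(w[males], rng)]
    return int(mother), int(father)


def make_gamete(
    parent: Individual, arch: GenomeArchitecture, rng: np.random.Generator
) -> np.ndarray:
    """Recombined haploid gamete (before transposition).

    Per chromosome the starting parental haplotype is chosen uniformly (free
    assortment) and the gamete alternates between the two parental haplotypes
    at each crossover.
    """
    segments = []
    starts, ends = arch.chrom_starts, arch.chrom_ends
    lam = arch.crossover_means
    haps = (parent.hap1, parent.hap2)
    for c in range(arch.n_chrom):
        k = rng.poisson(lam[c]) if lam[c] > 0 else 0
        breaks = np.sort(rng.integers(starts[c], ends[c], size=k)) if k else np.empty(0, np.int64)
        cur = int(rng.integers(0, 2))
        bounds = np.concatenate(([starts[c]], breaks, [ends[c]]))
        for s in range(bounds.size - 1):
            lo, hi = bounds[s], bounds[s + 1]
            src = haps[cur]
            segments.append(src[(src >= lo) & (src < hi)])
            cur = 1 - cur
    return np.concatenate(segments) if segments else np.empty(0, np.int64)


def transpose_into_gamete(
    gamete: np.ndarray,
    parent: Individual,
    u: float,
    arch: GenomeArchitecture,
    model: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add novel transposition events to a finished gamete.

    The effective transposition rate is zero when the parent produces piRNAs;
    collisions are checked only against the receiving gamete.
    """
    if u < 0:
        raise ValueError("transposition rate u must be non-negative")
    u_eff = 0.0 if is_pirna_producer(parent, arch, model) else u
    lam = u_eff * parent.n / 2.0
    k = rng.poisson(lam) if lam > 0 else 0
    out = list(gamete)
    occupied = set(out)
    for cand in rng.integers(0, arch.g, size=k):
        cand = int(cand)
        if cand not in occupied:
            occupied.add(cand)
            out.append(cand)
    return np.sort(np.asarray(out, dtype=np.int64))


def make_offspring(
    mother: Individual,
    father: Individual,
    arch: GenomeArchitecture,
    u: float,
    model: str,
    rng: np.random.Generator,
) -> Individual:
    """One offspring: a transposed gamete from each parent, random sex,
    maternal piRNAs deposited iff the mother currently produces piRNAs.

    The father's producer status never contributes to ``m`` (males inherit
    maternal piRNAs but cannot transmit them).
    """
    if mother.sex != "F" or father.sex != "M":
        raise ValueError("mother must be female and father male")
    hap1 = transpose_into_gamete(make_gamete(mother, arch, rng), mother, u, arch, model, rng)
    hap2 = transpose_into_gamete(make_gamete(father, arch, rng), father, u, arch, model, rng)
    sex = "F" if rng.random() < 0.5 else "M"
    m = 1 if is_pirna_producer(mother, arch, model) else 0
    return Individual(hap1=hap1, hap2=hap2, sex=sex, m=m)
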