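"""Individuals, populations, piRNA-producer logic and fitness.

A haplotype is a strictly increasing ``int64`` array of insertion positions in
``[0, g)``.  A diploid individual carries two haplotypes, a sex and a binary
maternal-piRNA status ``m`` (piRNAs deposited by the mother: present/absent).
Populations are stored flat (one concatenated position array plus haplotype
offsets) so that the simulation kernels can run over them without boxing.

Epigenetic state is *not* stored per insertion: a "paramutated TE" is simply
an insertion at a paramutable locus carried by an individual with ``m=1``.
Losing the chromosomal copy therefore reactivates the TE in the offspring
even when maternal piRNAs were deposited.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from pathlib import Path

import numpy as np

from .genome import GenomeArchitecture, classify_positions

__all__ = [
    "Individual",
    "Population",
    "count_by_class",
    "is_pirna_producer",
    "fitness",
    "insertion_frequency",
    "is_fixed",
    "fixed_positions",
    "exists_fixed_producing_locus",
    "generate_base_population",
    "read_base_population",
    "write_base_population",
]

_SEX_CODE = {"F": 0, "M": 1}
_SEX_CHAR = {0: "F", 1: "M"}


def _as_haplotype(positions, g: int | None = None) -> np.ndarray:
    hap = np.asarray(positions, dtype=np.int64)
    if hap.ndim != 1:
        raise ValueError("haplotype must be one-dimensional")
    if hap.size:
        if np.any(np.diff(hap) <= 0):
            raise ValueError("haplotype positions must be strictly increasing")
        if hap[0] < 0 or (g is not None and hap[-1] >= g):
            raise ValueError("haplotype position outside [0, g)")
    return hap


@dataclass
class Individual:
    """A diploid individual: two haplotypes, sex and maternal-piRNA status."""

    hap1: np.ndarray
    hap2: np.ndarray
    sex: str = "F"
    m: int = 0

    def __post_init__(self):
        self.hap1 = _as_haplotype(self.hap1)
        self.hap2 = _as_haplotype(self.hap2)
        if self.sex not in _SEX_CODE:
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.m not in (0, 1):
            raise ValueError("maternal piRNA status m must be 0 or 1")

    @property
    def n(self) -> int:
        """Diploid TE copy number (both haplotypes)."""
        return int(self.hap1.size + self.hap2.size)

    def positions(self) -> np.ndarray:
        return np.concatenate([self.hap1, self.hap2])


class Population:
    """Fixed-size population of diploid individuals.

    Internally flat: ``positions`` holds every haplotype back to back and
    ``offsets[2i] .. offsets[2i+2]`` delimit individual ``i``'s haplotypes.
    """

    __slots__ = ("positions", "offsets", "sex", "m", "generation")

    def __init__(self, positions, offsets, sex, m, generation: int = 0):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=np.uint8)
        self.m = np.asarray(m, dtype=np.uint8)
        self.generation = int(generation)
        if self.offsets.size != 2 * self.size + 1:
            raise ValueError("offsets must have length 2N+1")

    # ---- construction -----------------------------------------------------

    @classmethod
    def from_individuals(cls, individuals, generation: int = 0) -> "Population":
        haps, sex, m = [], [], []
        for ind in individuals:
            haps.append(ind.hap1)
            haps.append(ind.hap2)
            sex.append(_SEX_CODE[ind.sex])
            m.append(ind.m)
        offsets = np.zeros(len(haps) + 1, dtype=np.int64)
        np.cumsum([h.size for h in haps], out=offsets[1:])
        positions = np.concatenate(haps) if haps else np.empty(0, dtype=np.int64)
        return cls(positions, offsets, sex, m, generation)

    # ---- basic accessors --------------------------------------------------

    @property
    def size(self) -> int:
        return int(self.sex.size)

    def haplotype(self, h: int) -> np.ndarray:
        return self.positions[self.offsets[h] : self.offsets[h + 1]]

    def individual(self, i: int) -> Individual:
        return Individual(
            hap1=self.haplotype(2 * i).copy(),
            hap2=self.haplotype(2 * i + 1).copy(),
            sex=_SEX_CHAR[int(self.sex[i])],
            m=int(self.m[i]),
        )

    def individuals(self):
        for i in range(self.size):
            yield self.individual(i)

    @property
    def total_copies(self) -> int:
        """Total TE copies across the whole population."""
        return int(self.positions.size)

    def copy_numbers(self) -> np.ndarray:
        """Diploid TE count per individual."""
        per_hap = np.diff(self.offsets)
        return (per_hap[0::2] + per_hap[1::2]).astype(np.int64)

    def __eq__(self, other):
        if not isinstance(other, Population):
            return NotImplemented
        return (
            np.array_equal(self.positions, other.positions)
            and np.array_equal(self.offsets, other.offsets)
            and np.array_equal(self.sex, other.sex)
            and np.array_equal(self.m, other.m)
        )


# ---- per-individual queries ----------------------------------------------


def count_by_class(ind: Individual, arch: GenomeArchitecture):
    """Counts of an individual's insertions per site class.

    Returns ``(n_total, n_cluster, n_paramutable_site, n_trigger_site, n_other)``
    summed over both haplotypes.
    """
    pos = ind.positions()
    codes = classify_positions(pos, arch)
    n_cluster = int(np.count_nonzero(codes == 0))
    n_trigger = int(np.count_nonzero(codes == 1))
    n_para = int(np.count_nonzero(codes == 2))
    n_other = int(np.count_nonzero(codes == 3))
    return pos.size, n_cluster, n_para, n_trigger, n_other


def is_pirna_producer(ind: Individual, arch: GenomeArchitecture, model: str = "trap") -> bool:
    """Does this individual produce piRNAs against the invading TE?

    Trap model: a cluster insertion suffices, or a paramutated TE (an
    insertion at a paramutable locus in an individual with maternal piRNAs).
    siRNA model: there are no clusters that produce; the defence is seeded by
    carrying both a trigger-site insertion and a paramutable-site insertion,
    or maintained maternally via a paramutated TE.  Trigger-site insertions
    never produce piRNAs by themselves.
    """
    _, n_cluster, n_para, n_trigger, _ = count_by_class(ind, arch)
    paramutated = ind.m == 1 and n_para >= 1
    if model == "trap":
        return n_cluster >= 1 or paramutated
    if model == "sirna":
        return (n_trigger >= 1 and n_para >= 1) or paramutated
    raise ValueError(f"unknown model {model!r}")


def fitness(
    ind: Individual,
    x: float,
    model: str = "linear",
    cluster_neutral: bool = False,
    arch: GenomeArchitecture | None = None,
) -> float:
    """Fitness from the diploid copy number.

    Linear: ``w = max(0, 1 - x * n)``; multiplicative: ``w = (1 - x)**n``.
    With ``cluster_neutral`` the cluster insertions are excluded from ``n``
    (requires ``arch``).  ``x`` is the deleterious effect per insertion.
    """
    if not 0 <= x <= 1:
        raise ValueError(f"selection coefficient x must be in [0, 1], got {x}")
    n_eff = ind.n
    if cluster_neutral:
        if arch is None:
            raise ValueError("cluster_neutral fitness needs the genome architecture")
        _, n_cluster, _, _, _ = count_by_class(ind, arch)
        n_eff -= n_cluster
    if model == "linear":
        return max(0.0, 1.0 - x * n_eff)
    if model == "multiplicative":
        return float((1.0 - x) ** n_eff)
    raise ValueError(f"unknown fitness model {model!r}")


# ---- population-level queries ----------------------------------------------


def insertion_frequency(pop: Population, pos: int) -> float:
    """Population frequency of the insertion at ``pos`` (carrier haplotypes / 2N)."""
    carriers = int(np.count_nonzero(pop.positions == pos))
    return carriers / (2 * pop.size)


def is_fixed(pop: Population, pos: int) -> bool:
    return insertion_frequency(pop, pos) == 1.0


def fixed_positions(pop: Population) -> np.ndarray:
    """Positions present on every haplotype (population frequency 1)."""
    if pop.size == 0:
        return np.empty(0, dtype=np.int64)
    haps = [pop.haplotype(h) for h in range(2 * pop.size)]
    return reduce(np.intersect1d, haps)


def exists_fixed_producing_locus(
    pop: Population, arch: GenomeArchitecture, model: str = "trap"
) -> bool:
    """Is the invasion irrevocably silenced by a fixed piRNA-producing locus?

    True once a cluster insertion is fixed (trap model), or once a
    paramutable-site insertion is fixed *and* every individual currently
    produces piRNAs.  The all-producer conjunct makes paramutation-based
    silencing self-perpetuating: every mother deposits piRNAs, so every
    offspring paramutates its (fixed) paramutable copy.
    """
    fixed = fixed_positions(pop)
    if fixed.size == 0:
        return False
    codes = classify_positions(fixed, arch)
    if model == "trap" and np.any(codes == 0):
        return True
    if np.any(codes == 2):
        return all(is_pirna_producer(ind, arch, model) for ind in pop.individuals())
    return False


# ---- base population --------------------------------------------------------


def generate_base_population(
    arch: GenomeArchitecture,
    N: int,
    n_insertions: int,
    rng_seed,
) -> Population:
    """Random base population seeding an invasion.

    ``n_insertions`` distinct uniform positions, each placed on one random
    haplotype of one random individual (every insertion starts at population
    frequency ``1/2N``); sexes random; no maternal piRNAs anywhere.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if n_insertions > arch.g:
        raise ValueError("more insertions than genomic sites")
    sites = rng.choice(arch.g, size=n_insertions, replace=False).astype(np.int64)
    hap_of_site = rng.integers(0, 2 * N, size=n_insertions)
    haps: list[list[int]] = [[] for _ in range(2 * N)]
    for s, h in zip(sites, hap_of_site):
        haps[int(h)].append(int(s))
    arrays = [np.sort(np.asarray(h, dtype=np.int64)) for h in haps]
    offsets = np.zeros(2 * N + 1, dtype=np.int64)
    np.cumsum([a.size for a in arrays], out=offsets[1:])
    positions = np.concatenate(arrays) if arrays else np.empty(0, np.int64)
    sex = rng.integers(0, 2, size=N).astype(np.uint8)
    m = np.zeros(N, dtype=np.uint8)
    return Population(positions, offsets, sex, m, generation=0)


# ---- plain-text population files --------------------------------------------

_HEADER = "#sex\tm\thap1\thap2"


def write_base_population(pop: Population, path) -> None:
    """One individual per line: sex, m, and comma-joined haplotype positions."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for i in range(pop.size):
            h1 = ",".join(str(p) for p in pop.haplotype(2 * i))
            h2 = ",".join(str(p) for p in pop.haplotype(2 * i + 1))
            fh.write(f"{_SEX_CHAR[int(pop.sex[i])]}\t{int(pop.m[i])}\t{h1}\t{h2}\n")


def _parse_hap_field(text: str, lineno: int, g: int | None) -> np.ndarray:
    if text == "":
        return np.empty(0, dtype=np.int64)
    try:
        hap = np.asarray([int(v) for v in text.split(",")], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed haplotype field {text!r}") from exc
    if np.unique(hap).size != hap.size:
        raise ValueError(f"line {lineno}: duplicate positions within a haplotype")
    hap = np.sort(hap)
    if hap.size and (hap[0] < 0 or (g is not None and hap[-1] >= g)):
        raise ValueError(f"line {lineno}: position outside [0, g)")
    return hap


def read_base_population(path, arch: GenomeArchitecture | None = None) -> Population:
    """Parse a population file written by :func:`write_base_population`."""
    g = arch.g if arch is not None else None
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"line {lineno}: expected 4 tab-separated fields")
            sex, m_s, h1_s, h2_s = parts
            if sex not in _SEX_CODE:
                raise ValueError(f"line {lineno}: sex must be F or M, got {sex!r}")
            if m_s not in ("0", "1"):
                raise ValueError(f"line {lineno}: m must be 0 or 1, got {m_s!r}")
            individuals.append(
                Individual(
                    hap1=_parse_hap_field(h1_s, lineno, g),
                    hap2=_parse_hap_field(h2_s, lineno, g),
                    sex=sex,
                    m=int(m_s),
                )
            )
    if not individuals:
        raise ValueError(f"{path}: no individuals found")
    return Population.from_individuals(individuals)
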