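"""Generation loop, interventions, phase detection and replicate management.

A TE invasion passes through three phases.  During the *rapid invasion* phase
the TE spreads uninhibited.  The *shotgun* phase starts once at least 99% of
individuals carry a piRNA-producing locus (segregating control).  The
*inactive* phase starts when a producing locus fixes — a fixed cluster
insertion, or a fixed paramutable-site insertion in a generation where every
individual produces piRNAs, which makes the maternal silencing channel
self-perpetuating.  Phase onsets latch: once entered, a phase is never left.

Within a generation the order of events is: interventions scheduled for the
generation (cluster removal) are applied first, then parental fitnesses and
producer statuses are computed, then N offspring are produced by repeated
fecundity-weighted pair sampling, meiosis and transposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from . import _kernels
from .genome import GenomeArchitecture, classify_positions, remove_clusters, removed_regions
from .population import Population, generate_base_population, read_base_population

__all__ = [
    "SimulationConfig",
    "PopStats",
    "ReplicateResult",
    "population_stats",
    "step_generation",
    "detect_phase",
    "apply_interventions",
    "classify_reactivation",
    "classify_pdpp",
    "run_replicate",
    "run_replicates",
]

logger = logging.getLogger("tesim")

BasePopSpec = Union[int, str, Population, Callable[..., Population]]


@dataclass
class SimulationConfig:
    """Everything needed to run one invasion scenario.

    ``basepop`` is either the number of randomly scattered founder insertions,
    a path to a population file, a ready :class:`Population`, or a callable
    ``f(arch, N, rng) -> Population`` (used by scenario builders that need a
    structured base population).
    """

    arch: GenomeArchitecture
    u: float = 0.1
    x: float = 0.0
    N: int = 1000
    generations: int = 5000
    fitness_model: str = "linear"
    cluster_neutral: bool = True
    model: str = "trap"
    basepop: BasePopSpec = 100
    remove_clusters_at: Optional[tuple[int, int]] = None  # (k, generation)
    seed: int = 1
    replicates: int = 1
    sample_every: int = 1
    early_stop: Optional[str] = None  # None | "shotgun" | "inactive" | "pdpp"
    copy_number_cap: float = 2_000.0

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.u < 0:
            raise ValueError("transposition rate u must be >= 0")
        if not 0 <= self.x <= 1:
            raise ValueError("selection coefficient x must be in [0, 1]")
        if self.fitness_model not in ("linear", "multiplicative"):
            raise ValueError(f"unknown fitness model {self.fitness_model!r}")
        if self.model not in ("trap", "sirna"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.early_stop not in (None, "shotgun", "inactive", "pdpp"):
            raise ValueError(f"unknown early_stop mode {self.early_stop!r}")


@dataclass
class PopStats:
    """Single-scan aggregates of one generation (inputs to summaries/phases)."""

    n_total: np.ndarray
    n_cluster: np.ndarray
    n_para_site: np.ndarray
    n_trigger: np.ndarray
    n_paramutated: np.ndarray  # paramutable-site insertions of m=1 carriers
    m: np.ndarray  # maternal piRNA status per individual
    producer: np.ndarray
    fitness: np.ndarray
    fixed: np.ndarray  # positions fixed in the population
    fixed_producing: int  # count of fixed piRNA-producing loci
    inactive: bool  # a fixed producing locus silences everyone

    @property
    def mean_n(self) -> float:
        return float(self.n_total.mean())

    @property
    def paramutated_mean(self) -> float:
        return float(self.n_paramutated.mean())

    @property
    def mean_fitness(self) -> float:
        return float(self.fitness.mean())

    @property
    def producer_fraction(self) -> float:
        return float(self.producer.mean())


def _arch_rule_params(arch: GenomeArchitecture):
    return (
        arch.chrom_ends,
        arch.cluster_ends,
        arch.para_period,
        arch.para_count,
        arch.para_all,
        arch.trig_period,
        arch.trig_count,
    )


def _codes_for(pop: Population, arch: GenomeArchitecture) -> np.ndarray:
    return _kernels.classify_codes(pop.positions, *_arch_rule_params(arch))


def population_stats(
    pop: Population,
    arch: GenomeArchitecture,
    cfg: SimulationConfig,
    codes: np.ndarray | None = None,
) -> PopStats:
    """Compute per-individual counts, producer flags, fitness and fixation state."""
    if codes is None:
        codes = _codes_for(pop, arch)
    n_tot, n_clu, n_par, n_tri = _kernels.count_codes(codes, pop.offsets)
    m = pop.m.astype(bool)
    n_paramutated = np.where(m, n_par, 0)
    paramutated = m & (n_par >= 1)
    if cfg.model == "trap":
        producer = (n_clu >= 1) | paramutated
    else:
        producer = ((n_tri >= 1) & (n_par >= 1)) | paramutated
    n_eff = n_tot - n_clu if cfg.cluster_neutral else n_tot
    if cfg.fitness_model == "linear":
        w = np.maximum(0.0, 1.0 - cfg.x * n_eff)
    else:
        w = (1.0 - cfg.x) ** n_eff
    fixed = _kernels.fixed_positions_flat(pop.positions, pop.offsets)
    fixed_producing = 0
    inactive = False
    if fixed.size:
        codes = classify_positions(fixed, arch)
        n_fixed_cluster = int(np.count_nonzero(codes == 0)) if cfg.model == "trap" else 0
        n_fixed_para = int(np.count_nonzero(codes == 2))
        all_producers = bool(producer.all())
        fixed_producing = n_fixed_cluster + (n_fixed_para if all_producers else 0)
        inactive = n_fixed_cluster > 0 or (n_fixed_para > 0 and all_producers)
    return PopStats(
        n_total=n_tot,
        n_cluster=n_clu,
        n_para_site=n_par,
        n_trigger=n_tri,
        n_paramutated=n_paramutated,
        m=pop.m.copy(),
        producer=producer,
        fitness=w,
        fixed=fixed,
        fixed_producing=fixed_producing,
        inactive=inactive,
    )


class ExtinctionSignal(Exception):
    """Raised internally when no viable mating pair exists."""


def _step(
    pop: Population,
    codes: np.ndarray,
    arch: GenomeArchitecture,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    stats: PopStats,
) -> tuple[Population, np.ndarray]:
    _kernels.seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
    chrom_bounds = np.concatenate(([0], arch.chrom_ends)).astype(np.int64)
    new_pos, new_codes, new_off, new_sex, new_m, extinct = _kernels.step_generation_flat(
        pop.positions,
        codes,
        pop.offsets,
        pop.sex,
        stats.producer.astype(np.uint8),
        stats.fitness.astype(np.float64),
        stats.n_total,
        chrom_bounds,
        arch.crossover_means,
        float(cfg.u),
        int(arch.g),
        *_arch_rule_params(arch),
    )
    if extinct:
        raise ExtinctionSignal
    return (
        Population(new_pos, new_off, new_sex, new_m, generation=pop.generation + 1),
        new_codes,
    )


def step_generation(
    pop: Population,
    arch: GenomeArchitecture,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    stats: PopStats | None = None,
) -> Population:
    """Advance the population by one discrete generation (N offspring)."""
    codes = _codes_for(pop, arch)
    if stats is None:
        stats = population_stats(pop, arch, cfg, codes=codes)
    new_pop, _ = _step(pop, codes, arch, cfg, rng, stats)
    return new_pop


def detect_phase(
    producer_fraction: float,
    inactive: bool,
    shotgun_onset: Optional[int],
    inactive_onset: Optional[int],
) -> str:
    """Current phase label given this generation's state and latched onsets."""
    if inactive or inactive_onset is not None:
        return "inactive"
    if shotgun_onset is not None or producer_fraction >= 0.99:
        return "shotgun"
    return "rapid"


def apply_interventions(
    pop: Population, arch: GenomeArchitecture, cfg: SimulationConfig, generation: int
) -> tuple[Population, GenomeArchitecture]:
    """Apply any intervention scheduled for ``generation`` (cluster removal).

    Removing k clusters deletes the cluster annotation of the first k
    chromosomes and purges the insertions inside those regions from every
    haplotype, mimicking a genomic deletion; the removed sequence stays
    insertable.
    """
    if cfg.remove_clusters_at is None or generation != cfg.remove_clusters_at[1]:
        return pop, arch
    k = cfg.remove_clusters_at[0]
    regions = removed_regions(arch, k)
    new_arch = remove_clusters(arch, k)
    if regions:
        starts = np.asarray([r[0] for r in regions], dtype=np.int64)
        ends = np.asarray([r[1] for r in regions], dtype=np.int64)
        new_pos, new_off = _kernels.purge_regions_flat(pop.positions, pop.offsets, starts, ends)
        pop = Population(new_pos, new_off, pop.sex, pop.m, generation=pop.generation)
    return pop, new_arch


def classify_reactivation(
    mean_n_by_generation: dict[int, float],
    removal_generation: int,
    final_generation: int,
    threshold: float = 1.5,
) -> bool:
    """Did copy numbers grow past ``threshold`` x the post-removal baseline?"""
    try:
        base = mean_n_by_generation[removal_generation]
        final = mean_n_by_generation[final_generation]
    except KeyError as exc:
        raise ValueError(f"missing generation in series: {exc}") from exc
    if base == 0:
        return final > 0
    return final > threshold * base


def classify_pdpp(stats: PopStats) -> str:
    """State of paramutation-dependent piRNA production (PDPP).

    ``fixed``: every individual produces piRNAs; ``lost``: nobody carries
    maternal piRNAs and nobody produces; otherwise ``segregating``.
    """
    if bool(stats.producer.all()):
        return "fixed"
    if not np.any(stats.m) and not np.any(stats.producer):
        return "lost"
    return "segregating"


@dataclass
class ReplicateResult:
    """Outcome of one simulated invasion."""

    replicate: int
    status: str  # ongoing | stopped | lost | extinct
    shotgun_onset: Optional[int]
    inactive_onset: Optional[int]
    minimum_fitness: float
    final_generation: int
    final_mean_n: float
    mean_n_at_shotgun: Optional[float] = None
    mean_cluster_at_shotgun: Optional[float] = None
    mean_paramutated_at_shotgun: Optional[float] = None
    mean_n_at_inactive: Optional[float] = None
    mean_cluster_at_inactive: Optional[float] = None
    mean_paramutated_at_inactive: Optional[float] = None
    mean_n_at_removal: Optional[float] = None
    reactivated: Optional[bool] = None
    halted_runaway: bool = False
    pdpp_outcome: Optional[str] = None
    extinction_proxy: bool = False  # minimum mean fitness < 0.1

    @property
    def fitness_cost(self) -> float:
        return 1.0 - self.minimum_fitness


def _build_base_population(cfg: SimulationConfig, rng: np.random.Generator) -> Population:
    bp = cfg.basepop
    if isinstance(bp, Population):
        return bp
    if isinstance(bp, int):
        return generate_base_population(cfg.arch, cfg.N, bp, rng)
    if isinstance(bp, str):
        return read_base_population(bp, cfg.arch)
    if callable(bp):
        return bp(cfg.arch, cfg.N, rng)
    raise TypeError(f"unsupported basepop spec: {bp!r}")


def run_replicate(cfg: SimulationConfig, replicate: int = 0, seed: int | None = None):
    """Run one replicate; returns ``(ReplicateResult, list[GenerationSummary])``."""
    from .summaries import build_summary  # local import to avoid a cycle

    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    arch = cfg.arch
    pop = _build_base_population(cfg, rng)
    if pop.size != cfg.N:
        raise ValueError(f"base population size {pop.size} does not match N={cfg.N}")

    shotgun_onset: Optional[int] = None
    inactive_onset: Optional[int] = None
    min_fitness = np.inf
    summaries = []
    status = "ongoing"
    halted_runaway = False
    mean_n_at = {}
    onset_stats = {"shotgun": None, "inactive": None}
    removal_gen = cfg.remove_clusters_at[1] if cfg.remove_clusters_at else None
    mean_n_at_removal = None

    gen = pop.generation
    codes = None
    had_tes = pop.total_copies > 0
    while True:
        new_pop, new_arch = apply_interventions(pop, arch, cfg, gen)
        if new_pop is not pop or new_arch is not arch:
            codes = None  # positions or annotations changed
        pop, arch = new_pop, new_arch
        if codes is None:
            codes = _codes_for(pop, arch)
        stats = population_stats(pop, arch, cfg, codes=codes)
        mean_fit = stats.mean_fitness
        min_fitness = min(min_fitness, mean_fit)
        if shotgun_onset is None and stats.producer_fraction >= 0.99:
            shotgun_onset = gen
            onset_stats["shotgun"] = stats
        if inactive_onset is None and stats.inactive:
            inactive_onset = gen
            onset_stats["inactive"] = stats
        phase = detect_phase(stats.producer_fraction, stats.inactive, shotgun_onset, inactive_onset)
        is_onset = gen in (shotgun_onset, inactive_onset, removal_gen)
        if gen % cfg.sample_every == 0 or gen == cfg.generations or is_onset:
            summaries.append(build_summary(replicate, gen, pop, stats, phase, status))
        mean_n_at[gen] = stats.mean_n
        if removal_gen is not None and gen == removal_gen:
            mean_n_at_removal = stats.mean_n

        # --- termination ---------------------------------------------------
        if pop.total_copies == 0:
            if had_tes:
                status = "lost"
            break
        if gen >= cfg.generations:
            break
        if stats.mean_n > cfg.copy_number_cap:
            # Runaway growth: with the defence gone and u>0 the expected copy
            # number can only keep growing, so the final comparison is settled.
            halted_runaway = True
            break
        past_removal = removal_gen is None or gen >= removal_gen
        # use the *current* inactive state, not the latched onset: a cluster
        # removal can reopen an invasion that had already been stopped
        if cfg.early_stop == "inactive" and stats.inactive and past_removal:
            break
        if cfg.early_stop == "shotgun" and shotgun_onset is not None:
            break
        if cfg.early_stop == "pdpp" and classify_pdpp(stats) != "segregating":
            break

        try:
            pop, codes = _step(pop, codes, arch, cfg, rng, stats)
        except ExtinctionSignal:
            status = "extinct"
            break
        gen += 1

    final_gen = gen
    if summaries and summaries[-1].generation != final_gen:
        summaries.append(build_summary(replicate, final_gen, pop, stats, phase, status))
    if status not in ("extinct", "lost"):
        status = "stopped" if inactive_onset is not None else "ongoing"
    reactivated = None
    if removal_gen is not None and mean_n_at_removal is not None:
        # carry the last observed value forward when the run halted early
        final_val = mean_n_at[final_gen]
        reactivated = (
            final_val > 1.5 * mean_n_at_removal
            if mean_n_at_removal > 0
            else final_val > 0
        )
    pdpp_outcome = classify_pdpp(stats)

    result = ReplicateResult(
        replicate=replicate,
        status=status,
        shotgun_onset=shotgun_onset,
        inactive_onset=inactive_onset,
        minimum_fitness=float(min_fitness),
        final_generation=final_gen,
        final_mean_n=mean_n_at[final_gen],
        mean_n_at_removal=mean_n_at_removal,
        reactivated=reactivated,
        halted_runaway=halted_runaway,
        pdpp_outcome=pdpp_outcome,
        extinction_proxy=bool(min_fitness < 0.1),
    )
    for key, prefix in (("shotgun", "shotgun"), ("inactive", "inactive")):
        s = onset_stats[key]
        if s is not None:
            setattr(result, f"mean_n_at_{prefix}", float(s.n_total.mean()))
            setattr(result, f"mean_cluster_at_{prefix}", float(s.n_cluster.mean()))
            setattr(result, f"mean_paramutated_at_{prefix}", float(s.paramutated_mean))
    return result, summaries


def run_replicates(cfg: SimulationConfig):
    """Run ``cfg.replicates`` invasions; replicate ``r`` uses seed ``seed + r``.

    Returns ``(results, summaries)`` where summaries concatenates the
    per-generation rows of all replicates in replicate order.  A failing
    replicate is logged and skipped rather than aborting the batch.
    """
    results = []
    all_summaries = []
    for r in range(cfg.replicates):
        try:
            res, summ = run_replicate(cfg, replicate=r, seed=cfg.seed + r)
        except Exception:  # noqa: BLE001 - propagate per-replicate failures as logs
            logger.exception("replicate %d failed", r)
            continue
        logger.info(
            "replicate %d: status=%s shotgun=%s inactive=%s final_n=%.2f",
            r,
            res.status,
            res.shotgun_onset,
            res.inactive_onset,
            res.final_mean_n,
        )
        results.append(res)
        all_summaries.extend(summ)
    return results, all_summaries
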