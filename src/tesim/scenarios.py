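"""Programmatic builders for every simulated experiment, plus validation checks.

All experiments share a common genomic backbone: five 10-Mbp chromosomes, a
uniform recombination rate of 4 cM/Mbp, piRNA clusters at the start of each
chromosome, and regularly spaced paramutable loci defined by a modulo rule.
Default invasion conditions: clusters covering 3% of the genome (300 kb per
chromosome), 10% paramutable loci, transposition rate u=0.1, N=1000 diploid
individuals, 100 founder insertions each at population frequency 1/2N, and
neutral TE copies (x=0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .engine import SimulationConfig, run_replicate
from .genome import GenomeArchitecture, modulo_rule_for_percent
from .population import Population

__all__ = [
    "default_architecture",
    "build_default_invasion",
    "build_pdpp_scenario",
    "build_remove_cluster_experiment",
    "build_sirna_scenario",
    "SweepSpec",
    "validation_oracles",
]

_N_CHROM = 5
_CHROM_LEN = 10_000_000  # bp
_RECOMB = 4.0  # cM/Mbp


def default_architecture(
    para_percent: float = 10.0,
    cluster_percent: float = 3.0,
    trigger_percent: float = 0.0,
) -> GenomeArchitecture:
    """Five 10-Mbp chromosomes; cluster size given as percent of the genome
    (split equally across chromosomes), paramutable/trigger loci as percent
    of sites."""
    cluster_bp = int(round(cluster_percent / 100.0 * _CHROM_LEN))
    pp, pc, pall = modulo_rule_for_percent(para_percent)
    tp, tc, tall = modulo_rule_for_percent(trigger_percent)
    if tall:
        raise ValueError("100% trigger sites is not a meaningful scenario")
    return GenomeArchitecture(
        chrom_lengths=(_CHROM_LEN,) * _N_CHROM,
        cluster_lengths=(cluster_bp,) * _N_CHROM,
        recomb_rates=(_RECOMB,) * _N_CHROM,
        para_period=pp,
        para_count=pc,
        para_all=pall,
        trig_period=tp,
        trig_count=tc,
    )


def build_default_invasion(
    para_percent: float = 10.0,
    cluster_percent: float = 3.0,
    u: float = 0.1,
    x: float = 0.0,
    N: int = 1000,
    generations: int = 5000,
    basepop: int = 100,
    **overrides,
) -> SimulationConfig:
    """The default invasion scenario with the given overrides.

    ``para_percent=0`` yields the classic trap model (silencing only by
    cluster insertions).  Cluster insertions are treated as selectively
    neutral whenever x > 0.
    """
    arch = default_architecture(para_percent=para_percent, cluster_percent=cluster_percent)
    overrides.setdefault("cluster_neutral", True)
    return SimulationConfig(
        arch=arch,
        u=u,
        x=x,
        N=N,
        generations=generations,
        basepop=basepop,
        **overrides,
    )


def _pdpp_basepop(arch: GenomeArchitecture, N: int, rng: np.random.Generator) -> Population:
    """All individuals homozygous for a TE at the single paramutable locus
    (position 0); maternal piRNAs in exactly half of them, irrespective of sex."""
    one = np.zeros(1, dtype=np.int64)
    positions = np.tile(one, 2 * N)
    offsets = np.arange(2 * N + 1, dtype=np.int64)
    sex = rng.integers(0, 2, size=N).astype(np.uint8)
    m = (np.arange(N) % 2 == 0).astype(np.uint8)
    return Population(positions, offsets, sex, m, generation=0)


def build_pdpp_scenario(
    u: float = 0.0,
    x: float = 0.0,
    N: int = 1000,
    recombination: float = _RECOMB,
    generations: int = 5000,
    **overrides,
) -> SimulationConfig:
    """Paramutation-dependent piRNA production (PDPP) drift/selection scenario.

    No piRNA clusters; a single paramutable locus at the start of chromosome 1
    carries a fixed homozygous TE insertion, so every individual always has a
    paramutable TE and the epigenetic trait alone segregates.  Half the base
    population starts with maternal piRNAs.
    """
    g = _N_CHROM * _CHROM_LEN
    arch = GenomeArchitecture(
        chrom_lengths=(_CHROM_LEN,) * _N_CHROM,
        cluster_lengths=(0,) * _N_CHROM,
        recomb_rates=(recombination,) * _N_CHROM,
        para_period=g,
        para_count=1,  # position 0 is the only paramutable locus
    )
    overrides.setdefault("early_stop", "pdpp")
    return SimulationConfig(
        arch=arch,
        u=u,
        x=x,
        N=N,
        generations=generations,
        basepop=_pdpp_basepop,
        cluster_neutral=False,
        **overrides,
    )


def build_remove_cluster_experiment(
    k_removed: int,
    para_percent: float,
    N: int = 1000,
    removal_generation: int = 3000,
    generations: int = 5000,
    **overrides,
) -> SimulationConfig:
    """Default invasion plus deletion of ``k_removed`` of the 5 piRNA clusters
    (annotation and contained insertions) at ``removal_generation``."""
    if not 0 <= k_removed <= _N_CHROM:
        raise ValueError(f"k_removed must be in [0, {_N_CHROM}]")
    cfg = build_default_invasion(
        para_percent=para_percent, N=N, generations=generations, **overrides
    )
    if k_removed > 0:
        cfg.remove_clusters_at = (k_removed, removal_generation)
    return cfg


def build_sirna_scenario(
    trigger_percent: float,
    para_percent: float = 10.0,
    u: float = 0.1,
    x: float = 0.0,
    N: int = 1000,
    generations: int = 5000,
    basepop: int = 100,
    **overrides,
) -> SimulationConfig:
    """siRNA-trigger model: no piRNA clusters; the defence starts in
    individuals carrying both a trigger-site and a paramutable-site insertion."""
    arch = default_architecture(
        para_percent=para_percent, cluster_percent=0.0, trigger_percent=trigger_percent
    )
    return SimulationConfig(
        arch=arch,
        u=u,
        x=x,
        N=N,
        generations=generations,
        basepop=basepop,
        model="sirna",
        **overrides,
    )


@dataclass
class SweepSpec:
    """A 2-D parameter sweep (random draws, as in the large heatmap scans,
    or a deterministic lattice).

    ``x_range``/``y_range`` are inclusive (low, high) bounds of the two swept
    parameters, identified by name in ``x_param``/``y_param`` (any keyword of
    :func:`build_default_invasion`, e.g. ``"x"`` and ``"para_percent"``).
    """

    x_param: str
    x_range: tuple[float, float]
    y_param: str
    y_range: tuple[float, float]
    n_draws: int = 100
    mode: str = "random"  # "random" | "lattice"
    log_x: bool = False
    base_kwargs: dict | None = None

    def draw(self, rng: np.random.Generator):
        """Yield ``(x_value, y_value, SimulationConfig)`` for each cell."""
        if self.mode == "random":
            xs = rng.uniform(self.x_range[0], self.x_range[1], size=self.n_draws)
            if self.log_x:
                lo, hi = np.log10(self.x_range[0]), np.log10(self.x_range[1])
                xs = 10 ** rng.uniform(lo, hi, size=self.n_draws)
            ys = rng.uniform(self.y_range[0], self.y_range[1], size=self.n_draws)
        elif self.mode == "lattice":
            side = max(2, int(round(np.sqrt(self.n_draws))))
            xg = np.linspace(self.x_range[0], self.x_range[1], side)
            yg = np.linspace(self.y_range[0], self.y_range[1], side)
            xs, ys = (a.ravel() for a in np.meshgrid(xg, yg))
        else:
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        base = dict(self.base_kwargs or {})
        for xv, yv in zip(xs, ys):
            kwargs = dict(base)
            kwargs[self.x_param] = float(xv)
            kwargs[self.y_param] = float(yv)
            yield float(xv), float(yv), build_default_invasion(**kwargs)


# ---------------------------------------------------------------------------
# Statistical validation of the population-genetic forces
# ---------------------------------------------------------------------------


def _neutral_drift_config(N: int, generations: int, f0: float, arch=None, **kw):
    """A population with one neutral segregating insertion at frequency f0 and
    all host-defence machinery disabled."""
    arch = arch or GenomeArchitecture(
        chrom_lengths=(1_000_000,),
        cluster_lengths=(0,),
        recomb_rates=(4.0,),
        para_count=0,
    )
    site = 500_000
    carriers = int(round(f0 * 2 * N))

    def basepop(a, n, rng):
        haps = rng.permutation(2 * n)[:carriers]
        arrays = [np.asarray([site] if h in set(haps) else [], dtype=np.int64) for h in range(2 * n)]
        offsets = np.zeros(2 * n + 1, dtype=np.int64)
        np.cumsum([x.size for x in arrays], out=offsets[1:])
        positions = np.concatenate(arrays) if carriers else np.empty(0, np.int64)
        sex = rng.integers(0, 2, size=n).astype(np.uint8)
        return Population(positions, offsets, sex, np.zeros(n, np.uint8))

    return SimulationConfig(
        arch=arch, u=0.0, x=0.0, N=N, generations=generations, basepop=basepop,
        cluster_neutral=False, sample_every=max(1, generations), **kw,
    ), site


def validation_oracles(seed: int = 1, fast: bool = True) -> dict:
    """Check drift, selection, recombination and transposition against theory.

    Runs five independent checks and returns, per check, the observed value,
    the theoretical expectation and a boolean ``ok`` (within the stated
    confidence band).  ``fast`` uses the smaller problem sizes.
    """
    from .population import Individual
    from .reproduction import make_gamete

    rng = np.random.default_rng(seed)
    out = {}

    # (a) neutral fixation probability equals the starting frequency
    n_rep = 400 if fast else 2000
    N, f0 = 50, 0.1
    fixed = 0
    resolved = 0
    for r in range(n_rep):
        cfg, site = _neutral_drift_config(N, 20 * N, f0)
        cfg.seed = int(rng.integers(2**31 - 1))
        res, _ = run_replicate(cfg, seed=cfg.seed)
        # a neutral allele is resolved when lost (status 'lost') or fixed
        if res.final_mean_n == 0:
            resolved += 1
        elif res.final_mean_n == 2.0:
            fixed += 1
            resolved += 1
    p_hat = fixed / max(resolved, 1)
    lo, hi = sps.binom.interval(0.99, resolved, f0)
    out["fixation_probability"] = {
        "observed": p_hat, "expected": f0, "n": resolved,
        "ok": lo / resolved <= p_hat <= hi / resolved,
    }

    # (b) one-generation drift variance ~= f(1-f)/2N
    N, f0, reps = 100, 0.3, 400 if fast else 2000
    deltas = []
    for r in range(reps):
        cfg, site = _neutral_drift_config(N, 1, f0)
        cfg.seed = int(rng.integers(2**31 - 1))
        res, summ = run_replicate(cfg, seed=cfg.seed)
        deltas.append(res.final_mean_n / 2 - f0)
    var_obs = float(np.var(deltas, ddof=1))
    var_exp = f0 * (1 - f0) / (2 * N)
    # chi-square band for a sample variance
    chi_lo, chi_hi = sps.chi2.interval(0.999, reps - 1)
    out["drift_variance"] = {
        "observed": var_obs, "expected": var_exp, "n": reps,
        "ok": chi_lo / (reps - 1) <= var_obs / var_exp <= chi_hi / (reps - 1),
    }

    # (c) purge of a deleterious insertion matches the discrete-time
    # expectation for additive (linear) fitness under fecundity selection:
    # f' = f (1 - x - f x) / (1 - 2 f x)
    N, f0, x, gens = 1000, 0.5, 0.2, 15
    cfg, site = _neutral_drift_config(N, gens, f0)
    cfg.x = x
    reps = 30 if fast else 100
    freqs = []
    for r in range(reps):
        res, _ = run_replicate(cfg, seed=int(rng.integers(2**31 - 1)))
        freqs.append(res.final_mean_n / 2)
    f_exp = f0
    for _ in range(gens):
        f_exp = f_exp * (1 - x - f_exp * x) / (1 - 2 * f_exp * x)
    obs = float(np.mean(freqs))
    se = float(np.std(freqs, ddof=1) / np.sqrt(reps))
    out["selection_trajectory"] = {
        "observed": obs, "expected": f_exp, "n": reps, "ok": abs(obs - f_exp) < 4 * se + 1e-9,
    }

    # (d) recombinant fraction between markers 1 Mbp apart at 4 cM/Mbp
    # matches Haldane: rf = (1 - exp(-2d))/2 with d = 0.04 Morgan
    arch = GenomeArchitecture(
        chrom_lengths=(10_000_000,), cluster_lengths=(0,), recomb_rates=(4.0,), para_count=0
    )
    a, b = 4_000_000, 5_000_000
    parent = Individual(hap1=np.asarray([a, b]), hap2=np.asarray([], dtype=np.int64))
    meioses = 20_000 if fast else 100_000
    grng = np.random.default_rng(int(rng.integers(2**31 - 1)))
    rec = 0
    for _ in range(meioses):
        gam = make_gamete(parent, arch, grng)
        has_a, has_b = a in gam, b in gam
        rec += has_a != has_b
    rf_obs = rec / meioses
    d = 4.0 * 1.0 / 100
    rf_exp = 0.5 * (1 - np.exp(-2 * d))
    se = np.sqrt(rf_exp * (1 - rf_exp) / meioses)
    out["haldane_recombination"] = {
        "observed": rf_obs, "expected": float(rf_exp), "n": meioses,
        "ok": abs(rf_obs - rf_exp) < 4 * se,
    }

    # (e) copy numbers grow as n0 (1+u)^t with silencing and selection off
    arch = GenomeArchitecture(
        chrom_lengths=(10_000_000,) * 5, cluster_lengths=(0,) * 5,
        recomb_rates=(4.0,) * 5, para_count=0,
    )
    N, u, t, n0 = 250, 0.1, 20, 100
    cfg = SimulationConfig(
        arch=arch, u=u, x=0.0, N=N, generations=t, basepop=n0,
        cluster_neutral=False, sample_every=t,
    )
    reps = 20 if fast else 60
    finals = []
    for r in range(reps):
        res, _ = run_replicate(cfg, seed=int(rng.integers(2**31 - 1)))
        finals.append(res.final_mean_n * N)  # total copies in the population
    exp_total = n0 * (1 + u) ** t
    obs = float(np.mean(finals))
    se = float(np.std(finals, ddof=1) / np.sqrt(reps))
    out["transposition_growth"] = {
        "observed": obs, "expected": float(exp_total), "n": reps,
        "ok": abs(obs - exp_total) < 4 * se,
    }
    return out
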