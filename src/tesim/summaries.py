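"""Per-generation summaries and tab-separated result files.

Two granularities are written: one row per sampled generation
(``*.summary.tsv``) and one row per replicate (``*.replicates.tsv``).
Floats are serialized at 6 significant digits; files are bit-identical for
identical (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenerationSummary",
    "build_summary",
    "summarize_generation",
    "write_summary_tsv",
    "read_summary_tsv",
    "write_replicates_tsv",
    "read_replicates_tsv",
]


@dataclass
class GenerationSummary:
    """Population aggregates for one generation of one replicate."""

    replicate: int
    generation: int
    mean_n: float  # diploid TE copies per individual
    mean_fitness: float
    mean_cluster: float  # cluster insertions per diploid
    mean_para_site: float  # paramutable-site insertions per diploid
    mean_paramutated: float  # paramutable-site insertions in m=1 individuals
    frac_cluster_ind: float  # fraction with >=1 cluster insertion
    frac_paramutated_ind: float  # fraction with >=1 paramutated TE
    frac_producers: float
    fixed_producing_loci: int
    phase: str
    status: str


def build_summary(replicate, generation, pop, stats, phase, status) -> GenerationSummary:
    """Assemble a summary row from precomputed :class:`~tesim.engine.PopStats`."""
    m = stats.m.astype(bool)
    return GenerationSummary(
        replicate=int(replicate),
        generation=int(generation),
        mean_n=float(stats.n_total.mean()),
        mean_fitness=float(stats.fitness.mean()),
        mean_cluster=float(stats.n_cluster.mean()),
        mean_para_site=float(stats.n_para_site.mean()),
        mean_paramutated=float(stats.n_paramutated.mean()),
        frac_cluster_ind=float((stats.n_cluster >= 1).mean()),
        frac_paramutated_ind=float((m & (stats.n_para_site >= 1)).mean()),
        frac_producers=float(stats.producer.mean()),
        fixed_producing_loci=int(stats.fixed_producing),
        phase=str(phase),
        status=str(status),
    )


def summarize_generation(pop, arch, cfg, replicate: int = 0) -> GenerationSummary:
    """Compute all aggregates of the current population in a single scan."""
    from .engine import detect_phase, population_stats

    stats = population_stats(pop, arch, cfg)
    phase = detect_phase(stats.producer_fraction, stats.inactive, None, None)
    return build_summary(replicate, pop.generation, pop, stats, phase, "ongoing")


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        return format(float(value), ".6g")
    return str(value)


SUMMARY_COLUMNS = [f.name for f in fields(GenerationSummary)]


def write_summary_tsv(summaries, path) -> None:
    """Write summary rows ordered by (replicate, generation)."""
    rows = sorted(summaries, key=lambda s: (s.replicate, s.generation))
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
            for s in rows:
                fh.write("\t".join(_fmt(getattr(s, c)) for c in SUMMARY_COLUMNS) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write summary TSV to {path}: {exc}") from exc


def read_summary_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"cannot read summary TSV from {path}: {exc}") from exc


REPLICATE_COLUMNS = [
    "replicate",
    "status",
    "shotgun_onset",
    "inactive_onset",
    "minimum_fitness",
    "fitness_cost",
    "final_generation",
    "final_mean_n",
    "mean_n_at_shotgun",
    "mean_cluster_at_shotgun",
    "mean_paramutated_at_shotgun",
    "mean_n_at_inactive",
    "mean_cluster_at_inactive",
    "mean_paramutated_at_inactive",
    "mean_n_at_removal",
    "reactivated",
    "halted_runaway",
    "pdpp_outcome",
    "extinction_proxy",
]


def write_replicates_tsv(results, path) -> None:
    """One row per replicate with phase onsets, minimum fitness and outcome."""
    rows = sorted(results, key=lambda r: r.replicate)
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(REPLICATE_COLUMNS) + "\n")
            for r in rows:
                fh.write("\t".join(_fmt(getattr(r, c)) for c in REPLICATE_COLUMNS) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write replicate TSV to {path}: {exc}") from exc


def read_replicates_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"])
    except OSError as exc:
        raise OSError(f"cannot read replicate TSV from {path}: {exc}") from exc
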