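"""Genomic landscape of a simulated TE invasion.

The genome is a half-open integer interval ``[0, g)`` tiled by chromosomes in
input order.  A piRNA cluster occupies a prefix of each chromosome.  Recurrent
site classes (paramutable loci and siRNA-trigger-sites) are defined by modulo
rules applied to the absolute genomic position, so that every individual in a
population shares the same set of special sites.

Site classification precedence is CLUSTER > TRIGGER > PARAMUTABLE > NEUTRAL,
i.e. a position inside a piRNA cluster is never counted as paramutable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction

import numpy as np

__all__ = [
    "SiteClass",
    "GenomeArchitecture",
    "parse_genome_spec",
    "classify_site",
    "classify_positions",
    "remove_clusters",
    "modulo_rule_for_percent",
]

_UNIT_BP = {"mb": 1_000_000, "kb": 1_000, "bp": 1}


class SiteClass(Enum):
    """Mutually exclusive classes a genomic position can belong to."""

    CLUSTER = "cluster"
    TRIGGER = "trigger"
    PARAMUTABLE = "paramutable"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class GenomeArchitecture:
    """Chromosome layout, piRNA clusters and recurrent-site rules.

    Parameters
    ----------
    chrom_lengths
        Base-pair length of each chromosome; chromosomes tile ``[0, g)``.
    cluster_lengths
        Per-chromosome piRNA-cluster length in bp.  The cluster occupies the
        start of its chromosome; length 0 means no cluster.
    recomb_rates
        Per-chromosome recombination rate in cM/Mbp.
    para_period, para_count
        A non-cluster position ``p`` is paramutable iff
        ``p % para_period < para_count`` (residues ``0 .. count-1``).
        ``para_count == 0`` disables paramutable loci.
    para_all
        Every non-cluster, non-trigger site is paramutable (the 100% case,
        which the period:count encoding cannot express).
    trig_period, trig_count
        A position ``p`` is a siRNA-trigger-site iff
        ``p % trig_period >= trig_period - trig_count`` (the top residue band,
        disjoint from the paramutable band at default settings).
        ``trig_count == 0`` disables trigger sites.
    """

    chrom_lengths: tuple[int, ...]
    cluster_lengths: tuple[int, ...]
    recomb_rates: tuple[float, ...]
    para_period: int = 10
    para_count: int = 0
    para_all: bool = False
    trig_period: int = 100
    trig_count: int = 0

    def __post_init__(self):
        if len(self.chrom_lengths) == 0:
            raise ValueError("at least one chromosome is required")
        if not (len(self.chrom_lengths) == len(self.cluster_lengths) == len(self.recomb_rates)):
            raise ValueError(
                "chromosome-indexed specs disagree in length: "
                f"{len(self.chrom_lengths)} chromosomes, "
                f"{len(self.cluster_lengths)} clusters, {len(self.recomb_rates)} rates"
            )
        for i, (cl, ch) in enumerate(zip(self.cluster_lengths, self.chrom_lengths)):
            if cl < 0 or ch <= 0:
                raise ValueError(f"negative length on chromosome {i + 1}")
            if cl > ch:
                raise ValueError(
                    f"cluster on chromosome {i + 1} ({cl} bp) exceeds the chromosome ({ch} bp)"
                )
        if self.para_count < 0 or (self.para_count >= self.para_period and not self.para_all):
            raise ValueError("paramutation rule requires 0 <= count < period")
        if self.trig_count < 0 or self.trig_count >= self.trig_period:
            raise ValueError("trigger rule requires 0 <= count < period")

    # ---- derived geometry -------------------------------------------------

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)

    @property
    def g(self) -> int:
        """Total genome size in bp."""
        return int(sum(self.chrom_lengths))

    @property
    def chrom_starts(self) -> np.ndarray:
        """Absolute start of each chromosome (length ``n_chrom``)."""
        return np.concatenate(([0], np.cumsum(self.chrom_lengths)[:-1])).astype(np.int64)

    @property
    def chrom_ends(self) -> np.ndarray:
        """Absolute (exclusive) end of each chromosome."""
        return np.cumsum(self.chrom_lengths).astype(np.int64)

    @property
    def cluster_ends(self) -> np.ndarray:
        """Absolute (exclusive) end of each cluster region."""
        return self.chrom_starts + np.asarray(self.cluster_lengths, dtype=np.int64)

    @property
    def crossover_means(self) -> np.ndarray:
        """Expected crossovers per meiosis per chromosome (Haldane, no interference)."""
        lens_mb = np.asarray(self.chrom_lengths, dtype=np.float64) / 1e6
        return np.asarray(self.recomb_rates, dtype=np.float64) * lens_mb / 100.0

    @property
    def paramutable_fraction(self) -> float:
        if self.para_all:
            return 1.0
        return self.para_count / self.para_period

    # ---- queries ----------------------------------------------------------

    def chromosome_of(self, pos) -> np.ndarray:
        """0-based chromosome index for absolute position(s)."""
        return np.searchsorted(self.chrom_ends, pos, side="right")


def _parse_length_list(spec: str, flag: str) -> list[int]:
    spec = spec.strip()
    if ":" not in spec:
        raise ValueError(f"{flag}: expected 'unit:len,len,...', got {spec!r}")
    unit, _, rest = spec.partition(":")
    unit = unit.strip().lower()
    if unit not in _UNIT_BP:
        raise ValueError(f"{flag}: unknown unit prefix {unit!r} (use mb/kb/bp)")
    try:
        values = [int(round(float(v) * _UNIT_BP[unit])) for v in rest.split(",")]
    except ValueError as exc:
        raise ValueError(f"{flag}: malformed length list {rest!r}") from exc
    return values


def _parse_modulo(spec: str, flag: str) -> tuple[int, int, bool]:
    spec = spec.strip().lower()
    if spec == "all":
        return 1, 0, True
    try:
        period_s, _, count_s = spec.partition(":")
        period, count = int(period_s), int(count_s)
    except ValueError as exc:
        raise ValueError(f"{flag}: expected 'period:count' or 'all', got {spec!r}") from exc
    if period <= 0 or count < 0 or count >= period:
        raise ValueError(f"{flag}: require 0 <= count < period, got {spec!r}")
    return period, count, False


def parse_genome_spec(
    genome_spec: str,
    cluster_spec: str,
    rr_spec: str,
    paramutation_spec: str | None = None,
    trigger_spec: str | None = None,
) -> GenomeArchitecture:
    """Build a :class:`GenomeArchitecture` from CLI-style spec strings.

    ``genome_spec`` / ``cluster_spec`` use unit prefixes, e.g.
    ``"mb:10,10,10,10,10"`` and ``"kb:300,300,300,300,300"``; ``rr_spec`` is a
    plain comma list of cM/Mbp rates; ``paramutation_spec`` / ``trigger_spec``
    are ``"period:count"`` (or ``"all"`` for 100% paramutable loci).
    """
    chrom = _parse_length_list(genome_spec, "--genome")
    clusters = _parse_length_list(cluster_spec, "--cluster")
    try:
        rr = [float(v) for v in rr_spec.strip().split(",")]
    except ValueError as exc:
        raise ValueError(f"--rr: malformed rate list {rr_spec!r}") from exc
    pp, pc, pall = (10, 0, False)
    if paramutation_spec is not None:
        pp, pc, pall = _parse_modulo(paramutation_spec, "--paramutation")
    tp, tc = (100, 0)
    if trigger_spec is not None:
        tp, tc, tall = _parse_modulo(trigger_spec, "--trigger")
        if tall:
            raise ValueError("--trigger: 'all' is not a valid trigger spec")
    return GenomeArchitecture(
        chrom_lengths=tuple(chrom),
        cluster_lengths=tuple(clusters),
        recomb_rates=tuple(rr),
        para_period=pp,
        para_count=pc,
        para_all=pall,
        trig_period=tp,
        trig_count=tc,
    )


def modulo_rule_for_percent(percent: float) -> tuple[int, int, bool]:
    """Smallest ``(period, count)`` modulo rule covering ``percent`` of sites.

    Returns ``(period, count, all_flag)``; 100% is only expressible through
    the ``all`` flag because the encoding requires ``count < period``.
    Percentages are resolved to the reduced fraction, e.g. 10% -> ``10:1``,
    3% -> ``100:3``, 2.5% -> ``40:1``.
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percentage out of range: {percent}")
    if percent == 100:
        return 1, 0, True
    frac = Fraction(percent).limit_denominator(10**6) / 100
    return frac.denominator, frac.numerator, False


def classify_positions(positions, arch: GenomeArchitecture) -> np.ndarray:
    """Vectorized site classification.

    Returns an int8 array: 0=CLUSTER, 1=TRIGGER, 2=PARAMUTABLE, 3=NEUTRAL.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= arch.g):
        raise ValueError(f"position outside [0, {arch.g})")
    out = np.full(pos.shape, 3, dtype=np.int8)
    if arch.para_all:
        out[:] = 2
    elif arch.para_count > 0:
        out[pos % arch.para_period < arch.para_count] = 2
    if arch.trig_count > 0:
        out[pos % arch.trig_period >= arch.trig_period - arch.trig_count] = 1
    chrom = arch.chromosome_of(pos)
    out[pos < arch.cluster_ends[chrom]] = 0
    return out


_CLASS_BY_CODE = (SiteClass.CLUSTER, SiteClass.TRIGGER, SiteClass.PARAMUTABLE, SiteClass.NEUTRAL)


def classify_site(pos: int, arch: GenomeArchitecture) -> SiteClass:
    """Classify a single absolute position (precedence cluster > trigger > paramutable)."""
    code = classify_positions(np.asarray([pos]), arch)[0]
    return _CLASS_BY_CODE[code]


def remove_clusters(arch: GenomeArchitecture, k: int) -> GenomeArchitecture:
    """Strip CLUSTER status from the first ``k`` chromosomes.

    The affected regions become ordinary (insertable) sequence; deletion of the
    TE copies previously inside them is the engine's job.  Deterministic:
    always the lowest chromosome indices.
    """
    if not 0 <= k <= arch.n_chrom:
        raise ValueError(f"cannot remove {k} of {arch.n_chrom} clusters")
    new = list(arch.cluster_lengths)
    for i in range(k):
        new[i] = 0
    return replace(arch, cluster_lengths=tuple(new))


def removed_regions(arch: GenomeArchitecture, k: int) -> list[tuple[int, int]]:
    """Absolute ``[start, end)`` intervals of the first ``k`` cluster regions."""
    starts = arch.chrom_starts
    ends = arch.cluster_ends
    return [(int(starts[i]), int(ends[i])) for i in range(k) if ends[i] > starts[i]]
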