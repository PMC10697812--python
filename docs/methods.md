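# Methods

## Model

`tesim` simulates the invasion of a single TE family in a panmictic
population of `N` diploid individuals with discrete, non-overlapping
generations and two sexes.  The genome is the half-open integer interval
`[0, g)`; chromosomes tile it in input order, and every insertion is a bare
position (no sequence, no family attributes, no insertion bias).  Site
classes partition the genome with precedence cluster > trigger >
paramutable > neutral:

* **piRNA clusters** occupy a prefix of each chromosome (length per
  chromosome in the architecture; the default 300 kb per 10-Mbp chromosome
  makes clusters 3% of the genome, as in the *D. melanogaster* germline).
* **Paramutable loci** recur by a modulo rule: position `p` is paramutable
  iff `p % period < count`, i.e. residues `0..count−1`.  The model only
  requires *some* fixed residue set shared by all individuals; we use the
  lowest residues for determinism.  10% paramutable loci = `10:1`.  100%
  cannot be written as `count < period` and has a dedicated `all` encoding.
* **siRNA-trigger-sites** use the top residue band of their own period
  (`p % period ≥ period − count`), which keeps them disjoint from
  paramutable loci at the default settings; residual overlaps would resolve
  by the precedence rule.

**Host defence.**  An individual produces piRNAs against the family iff it
carries ≥1 cluster insertion, or has maternal piRNAs (`m=1`) and ≥1
insertion at a paramutable locus (a *paramutated TE*).  Under the siRNA
model the de-novo route is instead ≥1 trigger-site insertion together with
≥1 paramutable-site insertion; trigger insertions never produce piRNAs
themselves, and cluster insertions play no role.  Paramutation state is
*not* stored per insertion: it is re-derived every generation from
`(m, genotype)`.  This is the only reading consistent with reactivation
when the chromosomal component is lost — an individual that inherits
maternal piRNAs but neither a cluster insertion nor a paramutable TE hosts
an active TE again.

**Reproduction.**  Fitness is `w = max(0, 1 − x·n)` (linear; clamped at 0,
and a zero-fitness individual can never be drawn as a parent) or
`w = (1−x)^n` (multiplicative), with `n` the diploid copy number, minus the
cluster insertions when they are declared selectively neutral (the default
in scenarios with `x > 0`, which avoids a transposition–selection–cluster
balance in which invasions are never fully silenced).  Each offspring draws
its mother from the females and its father from the males, independently,
with replacement, with probability ∝ `w`.  Each parent contributes one
gamete: per chromosome, a Poisson number of crossovers with mean
`rr[cM/Mbp]·length[Mbp]/100` at uniform positions (Haldane model, no
interference) and a uniformly chosen starting haplotype (free assortment).
Transposition happens after recombination, into the finished gamete:
`Poisson(u_eff·n_parent/2)` candidate positions uniform on `[0, g)`, where
`u_eff = 0` for piRNA-producing parents of either sex and `n_parent` counts
*all* of the parent's insertions (including cluster and paramutable sites);
a candidate that hits a site already occupied in the receiving gamete is
dropped.  Offspring sex is uniform; offspring `m` is 1 iff the mother
produces piRNAs at reproduction time — the father's status never matters,
which is why males are dead ends for the epigenetic trait.

**Phases and outcomes.**  Phase onsets latch: *shotgun* starts when ≥99% of
individuals first carry a producing locus; *inactive* starts at the first
generation with a fixed producing locus — a fixed cluster insertion, or a
fixed paramutable-site insertion in a generation where every individual is
a producer.  The all-producer conjunct makes the paramutation route
self-perpetuating (every mother deposits piRNAs, every offspring carries
the fixed paramutable copy), so the silencing is irrevocable in both cases.
A replicate ends `stopped` (inactive reached), `lost` (all copies purged),
`extinct` (no viable mating pair), or `ongoing`.  The minimum of the
per-generation mean fitness is recorded; `fitness cost = 1 − minimum
fitness`, and minimum fitness < 0.1 is additionally flagged as the
extinction proxy used in the heat-map experiments.

**Interventions.**  Cluster removal at a scheduled generation is applied at
the start of that generation, before reproduction: the first `k`
chromosomes lose their cluster annotation and every insertion inside the
removed regions is deleted from every haplotype (a genomic deletion); the
removed sequence remains insertable (the regions are 0.6% of the genome
each, so this choice is inconsequential).  A replicate counts as
*reactivated* when the mean diploid copy number at the final generation
exceeds 1.5× its value right after removal; unsuppressed growth at u=0.1
overshoots any small constant within dozens of generations, so the
classifier is insensitive to the exact threshold (ties count as not
reactivated).

## Scenario generator

All experiments are built programmatically; there are no data files.  The
default invasion is 5 × 10 Mbp chromosomes, 4 cM/Mbp, 3% clusters, 10%
paramutable loci, u=0.1, x=0, N=1000, and 100 founder insertions placed at
distinct uniform positions on random haplotypes, i.e. each at population
frequency 1/2N — large enough to sidestep early stochastic loss of the
family, as in the original experiments.  The PDPP scenario has no clusters,
a single paramutable locus (period `g`, count 1 ⇒ position 0 only) carrying
a homozygous fixed insertion in everyone, and maternal piRNAs in exactly
half the founders (alternating individuals, irrespective of sex; odd `N`
splits ceil/floor).  The siRNA scenario takes the trigger percentage as an
argument (the plausible band is broad, roughly 3–30%).

What the generator does *not* emulate: insertion-site bias, TE families
with distinct properties, per-insertion selection coefficients, residual
activity of silenced TEs, dominance/epistasis, sex chromosomes, overlapping
generations, or real piRNA-cluster geometry (clusters sit at chromosome
starts with equal sizes).  Passing tests therefore demonstrate the
population-genetic mechanics of the trap/paramutation/siRNA models, not
agreement with any particular empirical TE family.

## Numerical and implementation choices

* The generation step runs in compiled (numba) kernels over flat arrays;
  site classes are cached per insertion and travel with the positions
  through meiosis, so per-generation classification is a tally.  The same
  model is implemented per-individual in `reproduction.py`; both paths are
  validated against closed-form oracles (below) rather than against each
  other.
* All randomness derives from a single integer seed per replicate
  (replicate `r` of a batch uses `seed + r`); runs are bitwise reproducible
  including the output TSVs.
* Fixed insertions are found by progressive sorted intersection across
  haplotypes, which is cheap because the candidate set collapses after a
  few haplotypes.
* Runaway growth (e.g. after removing the whole defence) is halted once the
  mean diploid copy number exceeds `copy_number_cap` (default 2,000,
  several-fold above any silenced plateau); the final value is carried
  forward, which is conservative for the reactivation classifier since the
  expected copy number can only grow once no producing loci remain.
* `early_stop="inactive"` is available for plateau measurements: once a
  producing locus is fixed, transposition is zero population-wide, and with
  `x=0` the mean copy number is a martingale, so the value at the onset is
  an unbiased estimate of the value at any later generation.  Runs default
  to the full configured horizon; with a scheduled cluster removal the stop
  re-evaluates the *current* fixation state after the removal.
* Crossover counts share the Poisson/uniform model with transposition;
  duplicate crossover positions cancel naturally as zero-length segments.
  Collisions of new insertions are checked only within the receiving
  gamete.

## Validation oracles

`scenarios.validation_oracles()` checks every population-genetic force
against independent theory on small problems: neutral fixation probability
equals the starting frequency (binomial CI); one-generation drift variance
equals `f(1−f)/2N` (χ² band); the purge of an additive deleterious
insertion follows `f' = f(1−x−fx)/(1−2fx)`; two-point recombinant fractions
follow Haldane's map function (`rf = (1−e^(−2d))/2`, e.g. 0.0385 at 1 Mbp
and 4 cM/Mbp); and with the defence and selection disabled the expected
total copy number grows as `n₀(1+u)^t`.  The test suite runs the full set.

## Problem sizes

The bundled tests and the acceptance script scale the original experiments
to a single CPU: stopping probabilities use N=250 with 5 replicates per
paramutable fraction (smaller populations fix producing loci faster, so
stopping bounds remain conservative); silencing-composition and
plateau-abundance runs keep N=1000 with 20 replicates.  Cluster-removal
runs use 25 replicates; the arm without paramutable loci runs at N=500
(after removing the whole defence, reactivation happens at any population
size), but the 10%-paramutable arm keeps N=1000 because the escape
probability depends on how far paramutated loci have fixed by the removal
generation, which scales with population size (~6% at N=500 versus ~16-20%
at N=1000).  Each quantity is recomputed from scratch at run time from the
scenario builders.

## Known limitations

The 1%-cluster/10%-paramutable composition point is sensitive to the exact
silencing time; across seeds the mean cluster-insertion count at shotgun
onset is ≈0.4–0.5 per diploid, at the upper edge of the coarse literature
figure of ~0.3 for this corner of parameter space, while the adjacent
quantities (classic-trap ≈4, large-cluster paramutated ≈0.35, plateau
ranges) agree closely.  PDPP outcomes are reported as `segregating` when a
population is not absorbed by the horizon rather than forced to a binary
call.
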