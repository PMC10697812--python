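"""A standard TE invasion: 3% piRNA clusters, 10% paramutable loci.

Runs one small invasion and prints the three phases and the copy-number
plateau.  The invasion is 'stopped' once a piRNA-producing locus (cluster
insertion or paramutated TE) is fixed: from then on no individual can ever
host an active TE again.
"""

from tesim import build_default_invasion, run_replicate

cfg = build_default_invasion(para_percent=10, N=250, generations=2000)
cfg.early_stop = "inactive"
cfg.sample_every = 100

result, summaries = run_replicate(cfg, seed=42)

print(f"{'gen':>5} {'TEs/ind':>8} {'cluster':>8} {'paramut':>8} {'producers':>9} phase")
for s in summaries:
    print(
        f"{s.generation:>5} {s.mean_n:>8.1f} {s.mean_cluster:>8.2f} "
        f"{s.mean_paramutated:>8.2f} {s.frac_producers:>9.2f} {s.phase}"
    )
print()
print(f"status:          {result.status}")
print(f"shotgun onset:   generation {result.shotgun_onset} "
      "(99% of individuals carry a producing locus)")
print(f"inactive onset:  generation {result.inactive_onset} "
      "(first producing locus fixed; invasion stopped)")
print(f"plateau size:    {result.final_mean_n / 2:.1f} insertions per haploid genome")
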