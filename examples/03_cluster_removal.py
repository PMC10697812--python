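"""Are piRNA clusters dispensable once the host defence is established?

Runs the cluster-removal intervention: invade normally, then at a set
generation delete all five piRNA clusters (annotation plus the insertions
inside them) from every individual.  Without paramutable loci the TE is
immediately reactivated and copy numbers explode; with 10% paramutable loci
the fixed paramutated TEs keep the family silenced.
"""

from tesim import build_remove_cluster_experiment, run_replicate

for para in (0, 10):
    # remove the clusters only after the defence is well established
    cfg = build_remove_cluster_experiment(
        k_removed=5, para_percent=para, N=250,
        removal_generation=1500, generations=3000,
    )
    cfg.early_stop = "inactive"
    cfg.sample_every = 500
    res, summaries = run_replicate(cfg, seed=7)
    print(f"--- {para}% paramutable loci ---")
    for s in summaries:
        marker = "  <- clusters removed" if s.generation == 1500 else ""
        print(f"  gen {s.generation:>5}: {s.mean_n:>8.1f} TEs/ind{marker}")
    verdict = "reactivated" if res.reactivated else "still silenced"
    print(f"  after removal: {verdict} "
          f"(final/removal ratio {res.final_mean_n / res.mean_n_at_removal:.2f}, "
          "reactivation = ratio > 1.5)\n")
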