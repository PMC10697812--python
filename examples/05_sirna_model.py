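"""The siRNA-trigger alternative to the trap model.

No piRNA clusters at all: the first piRNAs emerge in individuals that carry
both a TE insertion in an siRNA-trigger-site (a source of antisense
transcripts) and an insertion in a paramutable locus.  Trigger-site
insertions never produce piRNAs themselves; silencing is maintained through
the maternal channel once started.
"""

from tesim import build_sirna_scenario, run_replicate

cfg = build_sirna_scenario(trigger_percent=3, para_percent=10, N=250, generations=5000)
cfg.early_stop = "inactive"
cfg.sample_every = 200

res, summaries = run_replicate(cfg, seed=9)
for s in summaries[:10]:
    print(f"gen {s.generation:>5}: {s.mean_n:>7.1f} TEs/ind, "
          f"{s.frac_producers:.2f} producers, phase {s.phase}")
print("...")
print(f"status: {res.status}; silenced at generation {res.inactive_onset} by a "
      "fixed paramutated TE")
print(f"plateau: {res.final_mean_n / 2:.1f} insertions per haploid genome")
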