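"""Positive selection on an epigenetically inherited trait (PDPP).

Every individual carries a fixed TE insertion at a single paramutable locus;
half the founders have maternally deposited piRNAs (and therefore silence
the TE), half do not.  The maternal trait is transmitted only by piRNA-
producing mothers.  With neutral TEs the trait just drifts (fixed:lost about
1:1); with deleterious, transposing TEs the piRNA-producing matrilines
accumulate fewer copies and PDPP is driven to fixation.
"""

from collections import Counter

from tesim import build_pdpp_scenario, run_replicate

for label, u, x in (("neutral (u=0, x=0)", 0.0, 0.0), ("selected (u=0.1, x=0.01)", 0.1, 0.01)):
    cfg = build_pdpp_scenario(u=u, x=x, N=200, generations=5000)
    outcomes = Counter()
    for rep in range(20):
        res, _ = run_replicate(cfg, seed=300 + rep)
        outcomes[res.pdpp_outcome] += 1
    print(f"{label:>25}: {dict(outcomes)}")

print()
print("'fixed' means every individual produces piRNAs (the silencing trait")
print("swept the population); 'lost' means no maternal piRNAs remain and the")
print("TE is active in everyone, although the insertion itself never moved.")
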