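"""How many heuristic search replicates does a large ML analysis need?

If a fraction p of independent search replicates lands within a relative
log-likelihood threshold of the best topology, then
n = ln(1 - c) / ln(1 - p) searches give confidence c of at least one hit.
Reproduces the worked values for a 4608-replicate search effort and checks
one of them by Monte-Carlo simulation.
"""

from degenphy import replicates_needed, sim_search_replicates

for hits, thr in ((1827, "1e-2 %"), (19, "1e-3 %")):
    p = hits / 4608
    n = replicates_needed(p, confidence=0.95)
    print(f"{hits:>4} of 4608 replicates within {thr}: "
          f"p = {p:.5f}, searches needed for 95% confidence = {n}")

# empirical check of the second value
p = 19 / 4608
n = replicates_needed(p, 0.95)
outcomes = sim_search_replicates(p, n * 5000, seed=0).reshape(5000, n)
print(f"Monte-Carlo: fraction of {n}-search batches with >= 1 hit: "
      f"{outcomes.any(axis=1).mean():.3f} (target 0.95)")
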