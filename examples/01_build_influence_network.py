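"""Build a miRNA-target influence network and extract top modules.

Simulates a matched miRNA/mRNA cohort with five planted driver miRNAs,
scores every sequence-predicted pair by the product of its three
evidence channels, and keeps the pairs above the upper quartile.
"""

from mirti import (
    SimulationConfig,
    build_mirti,
    extract_modules,
    retention_threshold,
    simulate,
)

sim = simulate(SimulationConfig(seed=42))
net = build_mirti(sim.mirna, sim.mrna, sim.fpi, sim.seq)

thr = retention_threshold(net)
kept = net[net["mirti"] > thr]
kept_pairs = set(zip(kept["miRNA"], kept["target"]))
recovered = len(kept_pairs & sim.truth.planted_pairs)

print(f"candidate Seq pairs scored : {len(net)}")
print(f"pairs with positive miRTI  : {(net['mirti'] > 0).sum()}")
print(f"upper-quartile threshold   : {thr:.3f}")
print(f"retained high-influence    : {len(kept)}")
print(f"planted pairs recovered    : {recovered}/{len(sim.truth.planted_pairs)}")

modules = extract_modules(net, sim.fpi)
print(f"modules (connected components of retained pairs + FPI edges):")
for i, mod in enumerate(modules[:5]):
    print(f"  module {i}: {len(mod.mirnas)} miRNAs, {len(mod.targets)} targets")

# A high retained/planted overlap means the influence score separates
# functional repression from sequence-only decoy pairs; each module is
# one miRNA-regulated protein neighborhood.
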