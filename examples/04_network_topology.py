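"""Protein connectivity vs miRNA targeting, with a randomized null.

Highly connected proteins need more miRNAs to control them; the
correlation should vanish when target genes are redrawn at random with
all degrees preserved.
"""

from mirti import (
    SimulationConfig,
    randomize_for_null,
    simulate,
    topology_mirna_correlation,
)

sim = simulate(SimulationConfig(seed=42))

report = topology_mirna_correlation(sim.fpi, sim.seq)
print("observed networks :", report.summary())
print("degree trend (mean #targeting miRNAs per degree bin):")
for _, row in report.degree_trend.head(8).iterrows():
    print(f"  degree ~{row.x:4.1f}: {row.mean_n_mirnas:.2f} miRNAs "
          f"({int(row.n_proteins)} proteins)")

fpi_null, seq_null = randomize_for_null(sim.fpi, sim.seq, seed=0, mode="mirna_degree")
null_report = topology_mirna_correlation(fpi_null, seq_null)
print("randomized null   :", null_report.summary())

# The observed degree correlation is strongly positive because decoy
# targeting is degree-coupled (kappa = 1); after rewiring, r collapses
# toward 0 with a non-significant p, showing the trend is structural.
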