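# mirti — miRNA-target influence on protein interaction networks

`mirti` scores the influence of microRNAs on their targets *through* a
functional protein interaction (FPI) network, and turns those scores
into patient-level and gene-level estimates of miRNA activity. It is
aimed at systems-biology analyses of matched miRNA/mRNA tumor cohorts
(the motivating setting is prostate cancer progression), where the
question is not merely *which genes does this miRNA bind*, but *which
miRNAs actually move the expression of whole protein neighborhoods*,
and whether that influence carries diagnostic or prognostic signal.

## The model

Sequence predictions define a candidate relation `Seq(miR, t) ∈ {0, 1}`.
For every candidate pair the package combines three evidence channels
computed on matched expression profiles, with pairwise dependence
measured by mutual information

```
MI(x, y) = Σ_d Σ_r p(d, r) · log [ p(d, r) / (p(d) p(r)) ]
```

estimated by equal-frequency discretization (8 bins by default):

* **Corrmir(miR, t)** = `MI(miR, t)` if `Seq(miR, t) = 1` *and* the
  Pearson correlation of the pair is negative (repression evidence),
  else 0;
* **W(miR, t)** = `Σ_k MI(miR, k) · MI(k, t)` over the FPI partners
  `k` of `t` — the miRNA's indirect influence through the target's
  neighborhood;
* **MAX CorrFPI(t)** = `max_k MI(t, k)` — the target's strongest
  partner co-expression.

The influence score is their product,

```
miRTI(miR, t) = Corrmir(miR, t) · W(miR, t) · max_k CorrFPI(t, k),
```

so it vanishes whenever sequence support, repression evidence, or
network context is absent. Pairs above the upper quartile of the
positive scores form high-influence **miRNA-target modules** (connected
components together with the FPI edges among retained targets).

Three downstream applications are built in:

1. **Patient influence** — each patient's expression profile is
   regressed on the miRTI columns with an elastic net
   (`α = 0.5`, 100-value λ path, 10-fold CV), giving a miRNA × patient
   coefficient matrix.
2. **Activity centers** — per gene,
   `ActivityScore(i) = [mean_d CorrFPI(i,d)·R(d)] · max_d CorrFPI(i,d)·R(d)`
   with `R = −log10(p)` from a two-sample t-test; high-scoring genes are
   principal regulators, and the same elastic net identifies the miRNAs
   explaining the activity profile.
3. **Validation battery** — degree/clustering vs targeting-count
   correlations with degree-preserving randomized nulls, hierarchical
   two-group risk stratification with log-rank test and Cox hazard
   ratio, and cross-validated linear-SVM classification.

A fully specified synthetic-cohort generator (`mirti.simulate`) plants
driver miRNAs, repressed co-expression modules, degree-coupled decoy
targeting, and risk-linked exponential survival, so every stage is
testable end to end without external data.

## Worked example

```python
from mirti import (SimulationConfig, simulate, build_mirti,
                   extract_modules, retention_threshold)

sim = simulate(SimulationConfig(seed=42))
net = build_mirti(sim.mirna, sim.mrna, sim.fpi, sim.seq)
thr = retention_threshold(net)
kept = net[net["mirti"] > thr]
```

Running `python examples/01_build_influence_network.py` (which is this
code plus reporting) prints:

```
candidate Seq pairs scored : 675
pairs with positive miRTI  : 375
upper-quartile threshold   : 1.872
retained high-influence    : 94
planted pairs recovered    : 75/75
```

675 sequence-predicted pairs were scored; 375 pass the
negative-correlation filter with network support; the 94 pairs above
the upper-quartile threshold contain all 75 planted functional pairs,
i.e. the score cleanly separates genuine repression from
sequence-only decoys. The other scripts in `examples/` walk through
the per-patient regression, activity centers, topology analysis and
survival/classification validation, each printing the quantities it
computes with a note on how to read them.

A thin CLI mirrors the library (`mirti simulate`, `mirti build`,
`mirti influence`, `mirti activity`, `mirti topology`,
`mirti evaluate`); run `mirti --help` for options.

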