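# plinet

Phase-lag-index (PLI) brain-network analysis of interictal scalp EEG,
for researchers who study how functional-network reorganisation relates
to disease severity in focal epilepsy — and for anyone who needs a
fully tested, reproducible implementation of the standard EEG
graph-theory toolchain on the 25-channel IFCN montage.

Temporal lobe epilepsy reshapes interictal brain networks: phase
synchronisation between frontal and temporal electrodes rises,
particularly in the theta band (4–7 Hz), and the more severe the
seizures the stronger the effect.  Quantifying that requires a chain of
steps, each with well-known pitfalls: re-referencing, zero-phase
band-pass filtering, analytic-signal phase estimation, a
volume-conduction-robust connectivity statistic, and graph summaries
that do not depend on an arbitrary edge threshold.  `plinet` implements
that chain end to end, with every numeric step validated against an
independent brute-force oracle.

## The statistics at its core

For channels *i, j* with instantaneous phases φᵢ, φⱼ (Hilbert
transform of the band-filtered signal):

```
PLI = | ⟨ sign(Δφ) ⟩ |,   Δφ = wrap(φᵢ − φⱼ) ∈ (−π, π],  sign(0) = 0
```

PLI ∈ [0, 1] is blind to zero-lag (volume-conducted) coupling and
grows with consistent nonzero phase lag.  On the PLI graph (weights =
PLI, edge distance = 1/PLI) the package computes:

* weighted clustering coefficient **CC** and characteristic path
  length **PL** (local segregation / global integration);
* minimum-spanning-tree metrics — diameter **D**, leaf fraction
  **LF**, betweenness centrality **BC**, tree hierarchy
  **TH = LN/(2·m·BC_max)**, and **kappa = ⟨k²⟩/⟨k⟩** — the
  threshold-free network backbone;
* modularity **Q** and participation coefficient
  **Pᵢ = 1 − Σₛ(κᵢₛ/kᵢ)²** of the community partition;
* spectral mean frequency **MF = ΣP(f)·f / ΣP(f)** and frontal
  laterality index **LI = (P_left − P_right)/(P_left + P_right)**.

A cohort stage runs ANOVA/Tukey group comparisons, Spearman
severity correlations and SPSS-style stepwise regression of severity on
network and clinical covariates.  A seeded synthetic-EEG generator
produces cohorts with planted, severity-linked frontotemporal theta
coupling so the whole chain can be validated by parameter recovery;
see `docs/methods.md` for the model and its limits.

## Worked example

```python
from plinet import band_pli, build_graph, make_epochs, network_metrics
from plinet.mst import kruskal_mst, tree_metrics
from plinet.montage import FRONTOTEMPORAL
from plinet.synthetic import SimChannelModel, frontotemporal_oscillator, simulate_recording

# 90 s of synthetic resting EEG with a left frontotemporal theta
# oscillator at 25% coupling strength
rec = simulate_recording(SimChannelModel(),
                         [frontotemporal_oscillator("L", 0.25)],
                         duration_s=90, fs=500, seed=42)

epochs = make_epochs(rec, epoch_length_s=10.0, total_s=90.0)
cm = band_pli(epochs["theta"])                       # epoch-averaged PLI matrix
wm = network_metrics(cm, list(FRONTOTEMPORAL))
tm = tree_metrics(kruskal_mst(build_graph(cm, list(FRONTOTEMPORAL))))
print(f"frontotemporal theta: mean PLI = {wm.mean_pli:.3f}, CC = {wm.cc:.3f}, PL = {wm.pl:.2f}")
print(f"MST: diameter = {tm.diameter} hops, leaf fraction = {tm.leaf_fraction:.2f}, "
      f"TH = {tm.tree_hierarchy:.2f}, kappa = {tm.kappa:.2f}")
```

prints

```
frontotemporal theta: mean PLI = 0.310, CC = 0.294, PL = 3.32
MST: diameter = 7 hops, leaf fraction = 0.56, TH = 0.45, kappa = 2.53
```

An uncoupled recording gives mean theta PLI ≈ 0.13 (the chance level of
the 10-s-epoch scheme) and PL ≈ 7.5: the planted coupling raises mean
PLI and clustering and makes the network more integrated (lower PL),
the pattern these metrics are designed to detect.

The same analysis is scriptable from the shell:

```
plinet simulate --out cohort/ --seed 0 --n-patients 60 --n-controls 20
plinet cohort cohort/ --out results/
plinet run-all --out results/ --seed 0        # both steps in one go
```

`results/` then holds the per-subject feature table, group tests,
severity correlations, the stepwise-regression report and a provenance
log (config hash + package version).

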