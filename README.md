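# graphreplay

Analysis of **memory reactivation during cued recall of a graph-structured
task**, from multivariate sensor-level neural time series: stimulus decoding,
sequential-replay detection with temporally delayed linear modeling (TDLM),
and clustered (simultaneous) reactivation analyses organized by graph
distance — together with a synthetic MEG-like data generator that injects
known replay/reactivation structure so every stage can be validated against
ground truth without any external data.

It is written for cognitive/computational neuroscientists who study memory
replay with MEG/EEG decoding and want a tested, seedable reference
implementation of the full chain.

## The task and the analyses

Ten stimuli occupy the nodes of a directed, cyclic graph (12 edges, two hub
nodes with two predecessors and successors each).  Recall is cued with an
edge (predecessor, current) and requires the context-valid successor.
Given decoded per-stimulus probability time courses Y (time × state), the
package implements:

* **Decoding** — one-vs-all L1-logistic decoders per stimulus (inverse
  regularization C = 6), trained at one latency on localizer epochs with a
  pre-stimulus null class; cross-validated accuracy time courses, temporal
  generalization, and the peak-accuracy/retrieval-performance exclusion
  rules.
* **TDLM sequenceness** — for each lag Δt, the lagged multiple regression
  Y_i(t) = Σ_j β_{j→i}(Δt) · Y_j(t−Δt) yields an empirical transition matrix
  Te(Δt); sequenceness is the Frobenius inner product Z(Δt) = ⟨Te(Δt), T⟩
  with the forward task matrix Tf or its transpose Tb.  Inference is by
  identity-based permutation of T: lag-resolved max-statistic thresholds and
  a lag-unspecific mean-over-lags two-sided permutation test, plus the
  correlation of mean sequenceness with retrieval performance.
* **Clustered reactivation** — Gaussian-smoothed (σ = 1 sample) probability
  contrasts between the two items *ahead* of the cue and all distant items,
  with a label-shuffle permutation test; and the distance-resolved profile
  at the group peak latency, tested with a one-way repeated-measures ANOVA
  over distance levels 1–5.
* **Statistics** — within-subject ANOVA decomposition, Pearson/paired-t,
  add-one permutation p-values, and a cluster-based permutation test for
  1-D/2-D accuracy maps.

## Worked example

`examples/03_sequential_replay.py` simulates six participants whose
retrieval epochs contain forward replay at a 50 ms state-to-state lag,
decodes them, and runs the sequenceness analysis:

```text
group forward sequenceness peaks at 50 ms (injected lag: 50 ms)
peak Zf = 1.621 vs 95th-percentile max-statistic threshold 0.983
backward peak Zb = 0.173 vs 0.946
lag-unspecific mean-lag test: stat=0.229, two-sided p=0.0050
Forward (but not backward) sequenceness exceeding its permutation
threshold at the injected lag is the signature of sequential replay.
```

The recovered lag equals the injected one; forward sequenceness clears its
permutation threshold while backward does not, and the lag-unspecific test
rejects.  The other examples cover the task graph
(`01_task_graph.py`), decoder training and calibration
(`02_simulate_and_decode.py`), distance-graded clustered reactivation
(`04_clustered_reactivation.py`) and the full pipeline with TSV/HDF5/manifest
outputs (`05_full_pipeline.py`).  A thin CLI wraps the pipeline stages:
`graphreplay run-all --seed 1 --out out/`, plus `simulate`, `decode`,
`sequenceness`, `reactivation`, and `report`.

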