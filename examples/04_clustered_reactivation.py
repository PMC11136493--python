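"""Detect clustered, distance-graded reactivation.

Simulates a cohort whose retrieval epochs contain simultaneous reactivation
of all off-screen items at 240 ms, with amplitude decreasing in graph
distance, then runs the differential (near-vs-distant) permutation test and
the distance-profile rm-ANOVA.
"""

import numpy as np

from graphreplay import decoding, reactivation, synthetic_data as sd
from graphreplay.task_graph import build_task_graph

graph = build_task_graph()
cfg = sd.SimulationConfig(n_participants=8, localizer_runs=1,
                          replay_mode="clustered", seed=3)
_, cohort = sd.simulate_cohort(cfg, graph)

rng = np.random.default_rng(0)
probs, metas = [], []
for part in cohort:
    dec = decoding.train_final_decoders(part.localizer, rng=rng)
    probs.append(decoding.apply_decoders(dec, part.retrieval))
    metas.append(part.retrieval.meta)

smoothed = [reactivation.smooth_probabilities(p, sigma=1.0) for p in probs]

obs, pvals, sig = reactivation.reactivation_permutation_test(
    smoothed, graph, metas, n_shuffles=2000, rng=rng)
times = smoothed[0].times
peak_idx = int(np.argmax(obs))
print(f"near-vs-distant differential peaks at {times[peak_idx] * 1000:.0f} ms "
      f"(injected onset: {cfg.cluster_onset * 1000:.0f} ms); "
      f"{int(sig.sum())}/{len(sig)} time points significant at alpha=0.05")

peak = reactivation.global_peak_time(smoothed, metas)
prof = reactivation.distance_profile(smoothed, graph, metas, peak)
print(f"reactivation peak at {peak * 1000:.0f} ms; "
      f"per-distance means: {np.round(prof.anova.level_means, 3)}")
print(f"rm-ANOVA over distance levels 1..5: "
      f"F({prof.anova.df_effect},{prof.anova.df_error}) = {prof.anova.F:.2f}, "
      f"p = {prof.anova.p:.4f}")
print("Decreasing means with distance, plus a significant near-vs-distant "
      "window, reproduce the clustered-reactivation signature.")
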