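"""Detect injected sequential replay with TDLM sequenceness.

Simulates a small cohort whose retrieval epochs contain forward replay at a
50 ms state-to-state lag, decodes the epochs, and runs the lag-resolved
sequenceness analysis with identity-based permutation thresholds.
"""

import numpy as np

from graphreplay import decoding, synthetic_data as sd, tdlm
from graphreplay.task_graph import build_task_graph

graph = build_task_graph()
cfg = sd.SimulationConfig(n_participants=6, localizer_runs=1,
                          replay_mode="sequential", replay_lag_ms=50, seed=7)
_, cohort = sd.simulate_cohort(cfg, graph)

rng = np.random.default_rng(0)
probs = []
for part in cohort:
    dec = decoding.train_final_decoders(part.localizer, rng=rng)
    probs.append(decoding.apply_decoders(dec, part.retrieval))

tmats = tdlm.build_transition_matrices(graph)
res = tdlm.sequenceness_analysis(probs, tmats, n_perm=200, rng=rng)

best = res.lags_ms[int(np.argmax(res.group_zf))]
print(f"group forward sequenceness peaks at {best:.0f} ms "
      f"(injected lag: {cfg.replay_lag_ms:.0f} ms)")
print(f"peak Zf = {res.group_zf.max():.3f} vs 95th-percentile max-statistic "
      f"threshold {res.pct95_threshold_f:.3f}")
print(f"backward peak Zb = {res.group_zb.max():.3f} vs {res.pct95_threshold_b:.3f}")
print(f"lag-unspecific mean-lag test: stat={res.mean_lag_stat_f:.3f}, "
      f"two-sided p={res.mean_lag_p_f:.4f}")
print("Forward (but not backward) sequenceness exceeding its permutation "
      "threshold at the injected lag is the signature of sequential replay.")
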