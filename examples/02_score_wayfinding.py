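"""Compute the WF composite, the training-performance control, and
per-level difficulty.

WF is the first principal component of the tutorial-normalized trajectory
lengths of wayfinding levels 6, 7, 8 and 11, oriented so higher = better.
Training performance (tutorial lengths over cohort minima) captures motor
skill only and should be nearly uncorrelated with WF.
"""

import numpy as np

import wayfind as w

cfg = w.GeneratorConfig(n_participants=10_000, seed=11)
participants, trajectories, levels = w.simulate_dataset(cfg, n_wayfinding=10)

matrix = w.normalize_lengths(trajectories, levels)
wf = w.compute_wf(matrix)
tp = w.training_performance(trajectories, levels)
scores = wf.merge(tp, on="participant_id")

print(f"scored {len(scores)} participants")
print(f"SD(WF) = {scores['wf'].std(ddof=1):.3f}")
print(f"corr(WF, mean normalized length) = "
      f"{np.corrcoef(scores['wf'], matrix.mean(axis=1))[0, 1]:.3f}  (< 0 by construction)")
print(f"corr(WF, training performance)   = "
      f"{np.corrcoef(scores['wf'], scores['tp'])[0, 1]:.3f}  (motor skill cancels)")

diff = w.difficulty_table(trajectories, levels)
print("\nper-level difficulty (median excess path over the shortest):")
print(diff.round(2).to_string(index=False))
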