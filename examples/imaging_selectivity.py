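"""From raw fluorescence to per-ROI choice selectivity.

Simulates an imaging session with choice-selective delay and response
activity, runs the ΔF/F pipeline (rolling 8th-percentile drift correction,
mode-based F0, pre-sound baseline subtraction, epoch averaging), and flags
side-selective ROIs against a 1000-shuffle permutation null.
"""

import numpy as np

from delaylick import imaging, selectivity, synth

trials = synth.gen_behavior(n_trials=250, seed=11)
fm = synth.gen_population(trials, n_rois=30,
                          epoch_auc_targets={"delay": 0.75, "response": 0.85},
                          seed=12)
er = imaging.preprocess_session(fm, trials)
sel = selectivity.permutation_significance(er, n_shuffles=1000, seed=13)

print(f"{er.dff.shape[0]} scored trials, {er.dff.shape[1]} ROIs")
for j, ep in enumerate(sel.epochs):
    print(f"  {ep:9s} mean AUC {np.nanmean(sel.auc[:, j]):.3f}  "
          f"significant ROIs {int(sel.significant[:, j].sum())}/30")
print(f"side-selective ROIs (any epoch): {int(sel.selective.sum())}/30")

comp = selectivity.epoch_distribution_compare(sel.auc, sel.epochs, seed=14)
for (ea, eb), t in comp["tests"].items():
    print(f"  {ea} vs {eb}: mean AUC diff {t.statistic:+.3f}, p = {t.p_value:.4f}")
# AUC is oriented right-vs-left; values above 0.5 mean larger delay/response
# activity before rightward licks, and the epoch comparison shows how
# selectivity builds from sound to response.
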