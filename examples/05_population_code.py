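"""Cross-validated population tuning matrices and the sorted linear
difference: does every combination have dedicated neurons, and is
supra-linearity selective for each neuron's preferred stimulus?

Trials are split into balanced halves; neurons are gated on split-half
reliability (r > 0.5); rows are sorted by training-half preference and the
held-out half is displayed — so the structure cannot come from selecting on
noise.
"""

import numpy as np

import combicode as cc
from combicode.responses import ResponseMatrix

space = cc.enumerate_conditions(5)
cfg = cc.SessionConfig(n_neurons=120, trials_per_condition=20, seed=6, trial_noise_sd=0.12)
pop = cc.sample_population(cfg, mixture=(0.35, 0.65, 0.0), seed=6)
table, amps = cc.simulate_trials(pop, cfg, seed=7)
resp = ResponseMatrix(values=amps, condition_ids=table.condition_ids(space), space=space)

labels = cc.partition_trials(table, 2, balance_keys=("pupil_diameter",), seed=8)
pm_t, pm_ld = cc.population_matrices(resp, labels, scheme="halves", r_thresh=0.5, seed=8)
covered = len(set(pm_t.row_pref.tolist()))
print(f"{pm_t.matrix.shape[0]} of {resp.n_neurons} neurons pass the reliability gate; "
      f"their preferred stimuli cover {covered} of 31 conditions")
print(f"diagonal enrichment of the held-out LD matrix: "
      f"{cc.diagonal_enrichment(pm_ld):+.3f} (0 = no selective supra-linearity)")

rank_means, n = cc.sorted_linear_difference(resp, labels)
print(f"sorted LD over {n} multi-preferring neurons: "
      f"rank 1 = {rank_means[0]:+.3f}, middle ranks mean = {np.mean(rank_means[10:16]):+.3f}, "
      f"last rank = {rank_means[-1]:+.3f}")
print("-> supra-linearity concentrates at each neuron's top-ranked stimuli and "
      "falls off toward the bottom ranks")

train, test = labels == 0, labels == 1
# pick a row whose training-half preference is a multi-element stimulus
row = next(
    r for r in range(pm_ld.matrix.shape[0])
    if space.non_catch[pm_ld.row_pref[r]].is_multi
)
res = cc.supralinearity_test(resp, int(pm_ld.row_neurons[row]), train, test, n_boot=2000, seed=9)
print(f"example neuron bootstrap test: label={res.label}, "
      f"LD(top)={res.ld_top:+.3f}, mean LD(non-top)={res.ld_nontop_mean:+.3f}, "
      f"p_supra={res.p_supra:.4f}")
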