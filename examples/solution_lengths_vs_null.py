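"""Goal-directed solution lengths diverge from what random typing predicts.

Counts, per virtual patient, the interventions needed to reach the
physiologic goals; estimates the effective 'space' frequency (probability
of a completion event in the keystroke stream); and compares the observed
solution-length rank-frequency curve with the intermittent-silence model
parameterized by the same data.
"""

from carelex import (
    NullModelSpec, VentSimConfig, count_intervention_space,
    effective_space_frequency, filter_solutions, gen_vent_sessions,
    length_rank_table, observed_vs_null, solution_lengths,
)

rows = gen_vent_sessions(VentSimConfig(n_subjects=29, n_patients_per_subject=25,
                                       seed=7))
recs = solution_lengths(rows)
q_hat = effective_space_frequency(recs)
kept = filter_solutions(recs)
print(f"{len(recs)} virtual patients; effective space frequency q_hat = {q_hat:.3f}")
print(f"{len(kept)} solutions kept after the length >= 1 / appearance > 1 filters")

_, n_keys = count_intervention_space()
table = length_rank_table([r.n_interventions for r in kept])
cmp_ = observed_vs_null(table, NullModelSpec(n_keys=n_keys, q_space=q_hat))
print(f"observed solution-length rank slope: {cmp_.observed_slope:.2f}")
print(f"intermittent-silence prediction ({n_keys} keys, q={q_hat:.2f}): "
      f"block slope {cmp_.null_block_slope:.2f} "
      f"(closed form {cmp_.null_asymptotic_slope:.2f})")
print(f"total variation between observed and null length shares: "
      f"{cmp_.tv_distance:.3f}")
print("The observed curve falls off far more steeply than the typist model:")
print("problem-solving is not random keystrokes punctuated by silences.")
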