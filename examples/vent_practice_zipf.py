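"""The core analysis: ventilation practice patterns display Zipf-like word usage.

Simulates 29 subjects each managing 25 virtual mechanical-ventilation
patients, encodes every (derangement, intervention) dyad as a word,
and fits the population and per-subject rank-frequency power laws.
"""

from carelex import (
    VentSimConfig, build_vocabulary, encode_vent_words, fit_per_group,
    fit_power_law, gen_vent_sessions, rank_frequency, validate_dyads,
)

cfg = VentSimConfig(n_subjects=29, n_patients_per_subject=25,
                    policy_exponent=0.95, p_complete_per_step=0.2, seed=7)
rows = gen_vent_sessions(cfg)
clean, excluded = validate_dyads(rows)
words = encode_vent_words(clean)
print(f"{len(rows)} log rows -> {len(words)} derangement:intervention dyads "
      f"({excluded} incomplete rows excluded)")
print("example words:", ", ".join(w.canonical for _, w in words[:3]))

table = rank_frequency(build_vocabulary(w for _, w in words))
fit = fit_power_law(table, min_count=5)
print(f"population fit: slope {fit.slope:.3f}, R^2 {fit.r2:.3f} "
      f"({fit.n_points} ranks with count >= 5)")
print(f"the generating policy used exponent {cfg.policy_exponent}; the fitted "
      "slope recovers -a from the encoded stream alone.")

summary = fit_per_group(words, min_count=2).summary()
print(f"per-subject fits: mean slope {summary['slope_mean']:.2f} "
      f"(SD {summary['slope_sd']:.2f}), mean r {summary['r_mean']:.2f}")
print("power-law usage at the population level here reflects the same "
      "behavior in every individual subject's stream.")
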