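"""Can the data tell whether confidence uses extra stimulus information?

Runs a small model-recovery study: datasets are simulated either without
a confidence boost (model 1) or with a random boost (model 2), both
nested models are fitted to each dataset, and a chi-square(1)
likelihood-ratio test selects between them. Run with more reps for
stable rates (the full study uses hundreds).
"""

from cncb.studies import run_study

table, summary = run_study("model_recovery", reps=20, seed=4)
print(table[["true_model", "true_sigma_c", "true_alpha", "lambda_lr",
             "p_value", "chosen_model"]].round(3).to_string(index=False))
print(f"\nno-boost data retained the no-boost model "
      f"{100 * summary['recovery_model1']:.0f}% of the time")
print(f"with-boost data selected the boost "
      f"{100 * summary['recovery_model2']:.0f}% of the time")
print(f"model discrimination d' = {summary['d_prime_models']:.2f}")
print("\nSelection is biased toward the simpler model: a small true boost "
      "is\nindistinguishable from none, so misses concentrate at low alpha.")
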