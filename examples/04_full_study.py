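"""A miniature end-to-end study.

Runs the whole analysis on an in-memory synthetic cohort (3
participants x 2 exercises x 3 trials): preprocessing, per-phase
metrics, two-level aggregation and Bonferroni-corrected rank-sum
comparisons, with TSV tables and overview plots written to
``example_out/``.  At this cohort size few comparisons reach the
corrected threshold — significance needs the full 19 participants.
"""

from limbmanip import GeneratorConfig, RunConfig, run_study

cfg = RunConfig(
    output_dir="example_out",
    generator=GeneratorConfig(seed=0, n_participants=3, n_trials=3),
)
result = run_study(cfg)

print("aggregated RMS (uV) per muscle, exercise 1, elbow-flexion phase:")
sub = result.metrics.query(
    "exercise == 'exercise_1' and metric == 'rms' and phase == 'phase_2'"
)
for _, row in sub.iterrows():
    print(f"  {row['muscle'].upper():4s} {row['mean']:7.1f} +- {row['sd']:5.1f}  (n={row['n']})")

sig = result.comparisons["significant"].sum()
print(f"\n{sig} of {len(result.comparisons)} pairwise comparisons significant "
      f"at the Bonferroni threshold {result.comparisons['threshold'].iloc[0]:.4f}")
print(f"outputs written to {result.output_dir}/")
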