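"""Run the summary layer on the published ablation benchmark tables.

Uses the per-range IoU means published for CVC-EndoSceneStill and Kvasir-SEG
(shipped with the package as reference input) to reproduce the analysis
layer: deltas to baseline in percentage points, the per-family extreme
improvements/decrements, the best range per transformation, and the three
combination strategies.  No training happens here — this demonstrates the
reporting logic on real published numbers.
"""

from polypaug.reference import reference_summary
from polypaug.stats import (
    build_combinations,
    delta_to_baseline,
    select_best_range,
    transform_extremes,
)

for dataset in ("CVC-EndoSceneStill", "Kvasir-SEG"):
    print(f"=== {dataset} ===")
    summary = delta_to_baseline(reference_summary(dataset))
    extremes = transform_extremes(summary)
    print("largest decrement:",
          extremes.loc[extremes["max_decrement"].idxmax(), "transform"],
          f"-{extremes['max_decrement'].max():.2f} points")
    print("largest improvement:",
          extremes.loc[extremes["max_improvement"].idxmax(), "transform"],
          f"+{extremes['max_improvement'].max():.2f} points")

    best = select_best_range(summary)
    print("best range per family:")
    for name, rng in best.items():
        print(f"  {name:<24}{rng}")

    for combo in build_combinations(summary):
        flag = "  [degenerate]" if combo.degenerate else ""
        print(f"combination '{combo.strategy}':{flag}")
        for member in combo.members:
            print(f"  {member[0]} @ {member[1]}")
    print()
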