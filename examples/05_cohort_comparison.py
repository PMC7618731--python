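"""Cohort-level comparison: generate pull-to-rupture cohorts for three
fibrinogen variants, run every trace through the pipeline, and compare
extensibility across variants with the normality-gated test plus a
ratio-over-wild-type table."""

import pandas as pd

from fibremech import (
    PRESETS,
    compare_groups,
    detect_rupture,
    extract_pull_parameters,
    fold_change_table,
    generate_cohort,
    Instrument,
    trace_to_curve,
)

instrument = Instrument()
# cohort sizes default to the crosslinked study sizes (WT 26, a390 20, a220 23)
traces, truth = generate_cohort(list(PRESETS.values()), seed=5,
                                instrument=instrument, mode="pull")
print(f"generated {len(traces)} pull traces across {truth['label'].nunique()} variants")

rows = []
for trace in traces:
    curve = trace_to_curve(trace.y_um, trace.lateral_V, instrument.ke,
                           instrument.cross_section, instrument.well)
    curve.rupture_index = detect_rupture(curve)
    p = extract_pull_parameters(curve)
    rows.append({"variant": trace.metadata["label"],
                 "crosslinked": trace.metadata["crosslinked"],
                 "extensibility": p.extensibility,
                 "rupture_stress": p.rupture_stress,
                 "toughness": p.toughness})
results = pd.DataFrame(rows)

gc = compare_groups(
    {k: v["extensibility"].to_numpy() for k, v in results.groupby("variant")},
    metric="extensibility", reference="WT",
)
print(f"\nnormality p-values: { {k: round(v, 3) for k, v in gc.normality_p.items()} }")
print(f"chosen test: {gc.chosen_test} (Kruskal-Wallis iff any group fails normality)")
print(f"omnibus p = {gc.p_value:.4g}")

table = fold_change_table(results, ["rupture_stress", "toughness", "extensibility"],
                          extra_pairs=[("a220", "a390")])
print("\nratios of group means over WT (crosslinked only):")
print(table.round(3).to_string())
print("\nthe a220X/WTX extensibility cell recovers the planted 0.882 ratio "
      "up to sampling error")
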