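"""Find a substrate-affinity position by comparing two selection conditions.

Simulates matched selections of the same library under kcat-biased
(saturating substrate, short time) and KM-biased (sub-saturating substrate,
longer time) conditions, with a planted base at position 5 that lowers KM
only. Partitioning shared sequences by the base at each position and
fitting per-base log-log CPM lines flags the planted position: its base
groups follow genuinely different lines.
"""

from motifspace import (
    SelectionCondition,
    build_design,
    make_km_contrast_pair,
    make_toy_landscape,
    scan_position_slopes,
    toy_motif_spec,
)

spec = toy_motif_spec()
design = build_design(spec)
landscape = make_toy_landscape(spec, km_positions=(5,), seed=0)
(((km_pos, km_base), shift),) = landscape.km_mod.items()
print(f"planted: base {km_base} at position {km_pos} shifts log KM by {shift}")

ds_km, ds_kcat = make_km_contrast_pair(
    design,
    landscape,
    SelectionCondition(20.0, 10.0, 200_000, seed=1000, label="km"),
    SelectionCondition(100.0, 100 / 60, 200_000, seed=2000, label="kcat"),
)
table = scan_position_slopes(
    ds_kcat, ds_km, spec.variable_positions, n_boot=200, seed=0
)
print(table.to_string(index=False))
top = int(table.iloc[0]["position"])
print(f"top-ranked position: {top} ({'recovered' if top == km_pos else 'missed'})")
# Divergence is the largest pairwise slope difference between base groups,
# in bootstrap standard errors; only a base that changes one kinetic
# parameter specifically separates the groups onto different lines.
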