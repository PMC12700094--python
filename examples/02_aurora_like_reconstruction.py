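"""Exact combinatorics of the bundled Aurora-like library reconstruction.

The package ships a synthetic 46-nt reconstruction of a deoxyribozyme
secondary-structure library (11 base pairs, three of them unconstrained and
split over R-Y / Y-R sub-pools) plus a random-mutagenesis control. This
prints the library statistics computed exactly by inclusion-exclusion -
no enumeration of the ~2.8e7 sequences is ever performed.
"""

from motifspace import aurora
from motifspace.design import (
    count_unique,
    intersection_count,
    mutation_census,
    pair_satisfaction_fraction,
)

lib = aurora.secondary_library()
control = aurora.random_control_design()

print(f"sub-pools in the structured library: {len(lib.subpools)}")
print(f"unique sequences: {count_unique(lib):,}")
frac = pair_satisfaction_fraction(lib, aurora.pairing_constraints())
print(f"able to form all 11 base pairs: {100 * frac:.1f}%")
census = mutation_census(lib, aurora.REFERENCE)
print(f"substitutions: {census.n_substitutions} at {census.n_positions} positions")
ctrl = mutation_census(control, aurora.REFERENCE)
print(f"control substitutions: {ctrl.n_substitutions} at {ctrl.n_positions} positions")
print(f"control unique sequences: {count_unique(control):,}")
print(f"sequences common to both libraries: {intersection_count(lib, control)}")
# The shared sequences are the calibration anchors that let CPM values from
# selections of the two libraries be compared quantitatively.
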