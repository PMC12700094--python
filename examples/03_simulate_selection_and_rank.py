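"""Simulate a single-step selection and rank variants by CPM and enrichment.

Draws a ground-truth landscape over the 4096-sequence toy library, reacts
it for 100 s at saturating substrate, samples one million reads, and shows
that CPM (reads per million) faithfully ranks the true catalytic activity.
"""

import numpy as np
from scipy import stats

from motifspace import (
    SelectionCondition,
    SelectionDataset,
    build_design,
    compute_cpm,
    compute_enrichment,
    enumerate_design,
    make_toy_landscape,
    simulate_selection,
    toy_motif_spec,
)

spec = toy_motif_spec()
design = build_design(spec)
landscape = make_toy_landscape(spec, seed=1)
condition = SelectionCondition(
    substrate_conc=100.0, incubation_time=100 / 60, n_reads=1_000_000, seed=2
)

pre, post = simulate_selection(design, landscape, condition)
cpm = compute_cpm(post)
print(f"observed sequences after selection: {len(cpm)}")

seqs = enumerate_design(design)
k_obs = dict(zip(seqs, landscape.k_obs(seqs, condition.substrate_conc)))
shared = sorted(cpm)
rho = stats.spearmanr([cpm[s] for s in shared], [k_obs[s] for s in shared]).statistic
print(f"Spearman(CPM, true k_obs) = {rho:.3f}")

enrich, _ = compute_enrichment(SelectionDataset(counts=post), design)
best = max(cpm, key=cpm.get)
print(f"top sequence {best}: CPM {cpm[best]:.0f}, enrichment {enrich[best]:.1f}x")
print(f"reference {landscape.reference}: CPM {cpm.get(landscape.reference, 0):.1f}")
# A high rank correlation means one round of selection plus deep sequencing
# already measures relative activity across several orders of magnitude.
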