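"""Extract the 20-dimensional feature vector from cohort windows.

Featurizes a small EHG cohort with and without LSDL decomposition and
shows per-class means for a few features.
"""

import pretermsig as ps

params = ps.CohortParams(n_term=6, n_preterm=5, duration=1200.0, seed=3)
cohort = ps.generate_cohort(params)
window_sets = [ps.window_disjoint(r, 10) for r in cohort]
model = ps.search_optimal(window_sets)

raw = ps.featurize_cohort(window_sets)
dec = ps.featurize_cohort(window_sets, lsdl=model)

print(f"{len(raw)} windows x {len(ps.FEATURE_NAMES)} features per arm")
show = ["MAV", "RMS", "WL", "SampEN", "VAR"]
for name, table in (("raw", raw), ("LSDL", dec)):
    means = table.groupby("label")[show].mean()
    print(f"\nper-class feature means ({name} arm):")
    print(means.round(3).to_string())
# The preterm class shows larger amplitude features (MAV, RMS, VAR) because
# its contraction bursts are more frequent and stronger; the decomposed arm
# removes artifact-driven spread in the same features.
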