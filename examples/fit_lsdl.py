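"""Fit the LSDL threshold decomposition on a synthetic EHG cohort.

Evaluates the separability cost J for all eight dyadic amplitude-band
candidates and prints the candidate table in the threshold-search layout.
"""

import pretermsig as ps

params = ps.CohortParams(n_term=10, n_preterm=8, seed=7)
cohort = ps.generate_cohort(params)
window_sets = [ps.window_disjoint(r, 10) for r in cohort]

model = ps.search_optimal(window_sets)

print("candidate J values (higher = better class separation):")
for region in ("upper", "lower"):
    cells = []
    for it in range(1, 5):
        c = next(c for c in model.candidates
                 if c.region == region and c.iteration == it)
        cells.append(f"{c.cost:7.3f}" if c.valid else "    n/a")
    print(f"  {region:5s} threshold: " + "  ".join(cells))

b = model.best
print(f"selected band: {b.region} region, iteration {b.iteration} "
      f"(|x| {'<=' if b.region == 'lower' else '>='} "
      f"{b.threshold:.4f} x A, A = {model.reference_amp:.1f} uV), J = {b.cost:.3f}")
# A lower-region selection at iteration 1-2 means the informative signal is
# the mid-amplitude contraction activity, and the top of the amplitude
# range (motion artifacts) is excised before feature extraction.
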