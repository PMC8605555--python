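"""Detect a gene-conversion tract between LTRs and correct the divergence.

Gene conversion copies one LTR over part of its partner, erasing the
divergence signal inside the tract and making the element look younger.
This script evolves an LTR pair to ~8% divergence, homogenizes columns
200-400 (the simulated conversion), finds the tract with the Sawyer-style
maximal-segment scan (seeded permutation null), and re-estimates the
divergence from the columns outside the tract.  The corrected distance
recovers the true age; the raw one underestimates it.
"""

import numpy as np

from te_prospector.evodynamics import corrected_divergence, detect_pair_tracts
from te_prospector.hky import evolve

rng = np.random.default_rng(10)
anc = "".join(rng.choice(list("ACGT"), size=600))
pi = [0.25] * 4
ltr5 = evolve(anc, 0.04, 2.0, pi, rng)
ltr3 = evolve(anc, 0.04, 2.0, pi, rng)
ltr3 = ltr3[:200] + ltr5[200:400] + ltr3[400:]  # conversion tract
context = [evolve(anc, 0.12, 2.0, pi, rng) for _ in range(3)]

scan = detect_pair_tracts(ltr5, ltr3, context, n_permutations=2000, seed=10)
for t in scan.tracts:
    print(
        f"tract columns {t.start_col}-{t.end_col}, "
        f"{t.supporting_sites} supporting sites, p = {t.p_value:.4f}"
    )
res = corrected_divergence(ltr5, ltr3, scan.tracts)
print(f"raw divergence       d = {res.d_raw:.4f}  (biased low by the tract)")
print(f"corrected divergence d = {res.d_corrected:.4f}  (planted: 0.08)")
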