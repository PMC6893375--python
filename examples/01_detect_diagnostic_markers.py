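"""Detect introgression diagnostic markers from reference panels.

Simulates a small wild (M. glaziovii-like) panel and a cultivated pool
with known fixed differences, then runs the per-window detection: Hamming
distances to the wild panel pick each window's non-introgressed
cultivated reference, and sites fixed in that reference are classified as
strict (wild panel fixed for the other allele) or glazpoly (wild panel
segregating) diagnostics.
"""

import numpy as np

import wildintro as wi
from wildintro.studies import combine_panels, detect_idms

cfg = wi.SimConfig(n_sites=5000, fixed_difference_fraction=0.02,
                   mg_private_poly_fraction=0.02, seed=7)
mg, me, site_class, mg_allele, *_ = wi.simulate_founders(cfg)

idm = detect_idms(combine_panels(mg, me), mg.samples)
n_strict = (idm["idm_class"] == "strict").sum()
n_glaz = (idm["idm_class"] == "glazpoly").sum()
true_fd = set(np.flatnonzero((site_class == "fixed_diff").to_numpy()))
hit = len(set(idm.loc[idm["idm_class"] == "strict", "site_index"]) & true_fd)

print(f"sites scanned:        {cfg.n_sites}")
print(f"strict diagnostics:   {n_strict} (true fixed differences: {len(true_fd)}, recovered: {hit})")
print(f"glazpoly diagnostics: {n_glaz}")
print()
print("Strict markers are fixed for opposite alleles in the two panels;")
print("finding the wild allele at one in a cultivated genome flags an")
print("introgressed segment. On noiseless panels recovery is exact.")
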