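"""Isotopic-niche size and directional overlap: perch vs the catfish.

Computes SEA/SEAc/SEAb for each group and the asymmetric probability
that a random individual of one group falls inside the other's 95%
niche region.
"""

import numpy as np

import isocast as ic

iznik = ic.load_fixture("iznik_community")
perch = ic.load_fixture("perch_sites")

apex = iznik.summary("Silurus glanis")
groups = {
    "S. glanis": ic.generate_group(
        ic.SyntheticGroupSpec(
            "S. glanis", n=apex.n, mean13C=apex.mean13C, mean15N=apex.mean15N,
            sd13C=apex.sd13C, sd15N=apex.sd15N,
        ),
        seed=1,
        match_moments=True,
    )
}
for donor in ic.donors_from_perch_sites(perch, assumed_sd=1.0):
    groups[donor.label] = donor.points(seed=1)

for name, pts in groups.items():
    niche = ic.ml_ellipse(pts)
    seab = ic.bayesian_sea(pts, ndraws=4000, seed=3)
    print(
        f"{name:28s} SEA = {niche.sea:5.2f}  SEAc = {niche.seac:5.2f}  "
        f"SEAb median = {np.median(seab.sea_draws):5.2f}  (‰²)"
    )

print()
mat = ic.directional_overlap_matrix(groups, alpha=0.95, nmc=10_000, seed=4)
print("P(row individual inside column group's 95% niche):")
print((100 * mat.prob).round(1).to_string())
print()
print("Overlap is asymmetric: the catfish's wide niche makes perch likely")
print("to fall inside it, signalling potential competition for prey.")
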