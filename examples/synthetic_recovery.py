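"""Generate a consumer with a known diet and recover it by inverse fit.

Consumers are drawn from the mixing-model likelihood at p* = (0.7, 0.2,
0.1) over three well-separated sources; the fitted posterior should
recover the simplex within the Monte-Carlo error of the model.
"""

import numpy as np

import isocast as ic

sources = tuple(
    ic.SyntheticGroupSpec(f"source {i+1}", 10, m13, m15, 0.5, 0.5)
    for i, (m13, m15) in enumerate([(-30, 5), (-20, 10), (-25, 15)])
)
tdf = ic.TDFSpec(3.4, 0.5, 0.39, 0.5)
truth = (0.7, 0.2, 0.1)

consumer = ic.generate_consumer(
    ic.ConsumerGenSpec(
        sources=sources, proportions=truth, tdf=tdf,
        resid_sd13C=0.3, resid_sd15N=0.3, n=50,
    ),
    seed=2,
)
source_set = ic.SourceSet(
    labels=tuple(s.taxon for s in sources),
    mean13C=np.array([s.mean13C for s in sources]),
    mean15N=np.array([s.mean15N for s in sources]),
    sd13C=np.array([s.sd13C for s in sources]),
    sd15N=np.array([s.sd15N for s in sources]),
    n=np.full(3, 10.0),
)
post = ic.fit_mixing_model(consumer, source_set, tdf=tdf, seed=3)

print("true vs recovered diet proportions:")
for label, p_true, p_est in zip(
    source_set.labels, truth, post.mean_proportions
):
    print(f"  {label}: p* = {p_true:.2f}   posterior mean = {p_est:.3f}")
print()
print("Each posterior mean lies within ±0.1 of the generating value —")
print("the forward generator and the fitted likelihood share one model.")
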