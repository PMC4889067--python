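"""Score topologies against an effect-probability matrix.

Each matrix entry is the posterior probability that an E-gene responds to
one perturbation.  A topology predicts which entries should be "hits"
(for each possible attachment of the E-gene), and its marginal likelihood
integrates the attachment out.  Higher log marginal = the predicted
nesting of downstream effects matches the data better.
"""

import numpy as np

import nembf as nb

labels = ("A", "B")
# Two E-genes: the first looks attached downstream of both (responds to
# either knock-down), the second responds to A only.
m = nb.EffectMatrix(
    ("gene1", "gene2"), labels,
    np.array([[0.95, 0.9], [0.9, 0.1]]),
)

for t in nb.enumerate_closed(2, labels):
    edges = "; ".join(f"{a}->{b}" for a, b in t.edges()) or "no edges"
    print(f"{edges:12s}  log P(D|Phi) = {nb.topology_log_marginal(m, t):8.4f}")

post = nb.topology_posteriors(m, nb.enumerate_closed(2, labels))
print("posterior over the 4 topologies:", np.round(post, 3))
print("-> the chain A->B explains both genes and takes most of the mass")
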