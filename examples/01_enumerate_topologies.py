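"""Enumerate the identifiable NEM topology space on a few S-genes.

Only the reflexive-transitive closure of a pathway graph is identifiable
from perturbation data, so the topology space is the set of preorders on
the K perturbed genes.  It grows quickly but stays enumerable for the
focused analyses this package targets.
"""

import nembf as nb

for k in range(1, 6):
    topologies = nb.enumerate_closed(k)
    print(f"K={k}: {len(topologies):5d} transitively closed topologies")

# Each element is a closed adjacency matrix; on two genes the four
# possibilities are: unrelated, A upstream of B, B upstream of A, or
# mutually connected (indistinguishable from a single merged node).
for t in nb.enumerate_closed(2, ("A", "B")):
    edges = "; ".join(f"{a}->{b}" for a, b in t.edges()) or "no edges"
    print("  K=2 topology:", edges)
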