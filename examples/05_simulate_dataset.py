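"""Generate a reproducible synthetic screen and write it to disk.

The generator runs the NEM data model forward: every E-gene attaches to
one S-gene (or is unattached noise) and its effect probabilities follow
bimodal Beta distributions — near 1 where the ground truth predicts an
effect, near 0 elsewhere — mimicking the output of a moderated
differential-expression pipeline on a K=4 knock-down screen.
"""

import tempfile
from pathlib import Path

import nembf as nb
from nembf.io import write_synthetic_dataset

labels = nb.case_study_labels()
truth = nb.sample_topology(
    4, nb.case_study_feature(), require_in_class=True, seed=11, labels=labels
)
print("ground truth edges:", truth.edges())

ds = nb.simulate_effect_matrix(truth, n_genes=100, seed=11)
n_noise = ds.attachments.count("null")
print(f"generated {ds.matrix.n_genes} E-genes ({n_noise} unattached noise genes)")
print("first rows (probabilities of responding to each knock-down):")
for gid, row in list(zip(ds.matrix.gene_ids, ds.matrix.probs))[:3]:
    print(" ", gid, [f"{v:.2f}" for v in row])

out = Path(tempfile.mkdtemp()) / "dataset"
paths = write_synthetic_dataset(ds, out)
print("files written:", ", ".join(p.name for p in paths.values()))
print("-> the TSV matrix feeds straight back into the bf / stability commands")
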