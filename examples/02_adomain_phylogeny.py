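"""Build a bootstrap-annotated A-domain tree and root it on the outgroup.

Two synthetic subfamilies of adenylation domains plus a distant outgroup:
WAG+gamma ML distances, neighbor joining, 50 bootstrap replicates, then
rooting.  Prints the tree and the support of each subfamily clade.
"""

import numpy as np

from npsphylome import (
    Alignment,
    SequenceRecord,
    bootstrap_support,
    root_with_outgroup,
    tree_to_newick,
)
from npsphylome.phylogeny import EvolModel
from npsphylome.residues import AMINO

rng = np.random.default_rng(0)

def mutate(seq, p):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = AMINO[(AMINO.index(out[i]) + rng.integers(1, 20)) % 20]
    return "".join(out)

base = "".join(rng.choice(list(AMINO), 250))
sf1, sf2 = mutate(base, 0.3), mutate(base, 0.3)
og = "".join(rng.choice(list(AMINO), 250))

records = (
    [SequenceRecord(f"sf1_{i}|m1", mutate(sf1, 0.05)) for i in range(4)]
    + [SequenceRecord(f"sf2_{i}|m1", mutate(sf2, 0.05)) for i in range(4)]
    + [SequenceRecord(f"OG{i}", mutate(og, 0.05)) for i in range(3)]
)

tree = bootstrap_support(Alignment(records), n_replicates=50, seed=1,
                         model=EvolModel(alpha=1.0))
rooted = root_with_outgroup(tree, {"OG0", "OG1", "OG2"})
print(tree_to_newick(rooted))

for node in rooted.preorder_node_iter():
    if node.is_leaf() or node.parent_node is None or node.support is None:
        continue
    labels = sorted(l.taxon.label for l in node.leaf_iter())
    if all(l.startswith("sf1") for l in labels) and len(labels) == 4:
        print("subfamily-1 clade support:", node.support)
    if all(l.startswith("sf2") for l in labels) and len(labels) == 4:
        print("subfamily-2 clade support:", node.support)

# Support is the percentage of 50 column-resampled replicates whose NJ tree
# contains the same leaf-set bipartition; well-separated clades reach ~100.
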