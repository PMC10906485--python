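"""Parse a phylogeny, prune it, and build the Brownian covariance matrix.

Under Brownian trait evolution, two species covary in proportion to the
branch length their root-to-tip paths share; that matrix is the error
structure for every phylogenetic regression downstream.
"""
import numpy as np

from birdacuity import parse_newick

tree = parse_newick("((Falco_berigora:1,Tyto_alba:1):0.5,Calypte_anna:1.5);")
C = tree.vcv()
print("taxa:", C.taxa)
print("Brownian covariance (shared path lengths):")
print(C.matrix)
# The falcon and owl share 0.5 units of history, the hummingbird none:
# their traits are expected to correlate accordingly.

half = C.lambda_transform(0.5)
print("\nafter lambda = 0.5 (off-diagonals halved):")
print(half.matrix)

pruned = tree.prune({"Falco_berigora", "Calypte_anna"})
print("\npruned to 2 taxa, depths preserved:", pruned.depths())
print("pruned covariance equals the 2x2 submatrix:",
      np.allclose(pruned.vcv().matrix, C.subset(pruned.tip_labels).matrix))
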