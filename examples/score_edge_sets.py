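"""The evaluation statistics on small hand-built inputs.

Shows the overlap coefficient on gene sets, the normalized enrichment score
of a motif AUC, and EPR / AUPRC ratio for a toy ranked edge list against a
tiny ground-truth network.
"""

import hypergrn as hg
from hypergrn.data import GroundTruthNetwork
from hypergrn.grn import RankedEdgeList

print("overlap({a,b,c}, {b,c,d}) =",
      round(hg.overlap_coefficient({"a", "b", "c"}, {"b", "c", "d"}), 3),
      "(intersection over the smaller set)")

aucs = [0.10, 0.20, 0.30]
print("NES of AUC 0.30 among", aucs, "=", round(hg.nes(0.30, aucs), 3),
      "(z-score against all motifs, sample sd)")

truth = GroundTruthNetwork(edges={("tf1", "g1"), ("tf1", "g2")},
                           gene_universe={"tf1", "g1", "g2", "g3"},
                           tf_universe={"tf1"})
ranked = RankedEdgeList([("tf1", "g1", 0.9), ("tf1", "g3", 0.5),
                         ("tf1", "g2", 0.4)])
print("EPR =", round(hg.epr(ranked, truth), 3),
      "| AUPRC ratio =", round(hg.auprc_ratio(ranked, truth), 3))
print("K = 2 true edges among P = 3 candidate TF->gene pairs; EPR counts"
      " hits in the top-K, the AUPRC ratio integrates the whole ranking.")
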