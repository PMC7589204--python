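"""Cluster a distance matrix with PAM and validate internally and externally.

Runs the full pipeline on an easy, well-separated dataset: PAM over K = 2..6,
Dunn-index selection of K, then matched accuracy and Jaccard against the
known labels.
"""

import numpy as np

from microclust.io import OtuCountTable
from microclust.pipeline import PipelineOptions, run_clustering
from microclust.validation import matched_accuracy

rng = np.random.default_rng(0)
# two groups with disjoint OTU signatures
counts = np.zeros((40, 6), dtype=int)
counts[:20, :3] = rng.poisson(60, size=(20, 3))
counts[20:, 3:] = rng.poisson(60, size=(20, 3))
table = OtuCountTable([f"s{i}" for i in range(40)], [f"o{j}" for j in range(6)], counts)
truth = np.repeat([1, 2], 20)

out = run_clustering(table, PipelineOptions(metric="l2-d-pdf", n_bootstrap=5,
                                            k_range=(2, 6), seed=0))
print(f"Dunn-selected K = {out.result.K}")
print("Dunn scores by K:", {k: round(v, 3) for k, v in out.index_scores.items()})
ext = matched_accuracy(out.result.assignment, truth)
print(f"matched accuracy = {ext.accuracy:.3f}, matched-set Jaccard = {ext.jaccard:.3f}")
# On clearly separated groups the Dunn index peaks at the true K = 2 and the
# matched accuracy is 1.0 (labels recovered exactly up to renaming).
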