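"""Score clusterings with ARI, silhouette width and cluster-count deviation.

Metrics are themselves a method list: applying them to a table of
clustering results multiplies rows by the number of metrics, keeping
everything in the same tidy structure.
"""

import numpy as np

from pipebench import (
    adjusted_rand_index,
    cluster_count_deviation,
    silhouette_width,
)

truth = ["A", "A", "A", "B", "B", "B"]
perfect = [1, 1, 1, 2, 2, 2]
merged = [1, 1, 1, 1, 1, 2]

print("ARI perfect vs truth:", adjusted_rand_index(perfect, truth))   # 1.0
print("ARI merged  vs truth:", round(adjusted_rand_index(merged, truth), 3))
print("cluster-count deviation (merged):",
      cluster_count_deviation(merged, truth))  # found 2, true 2 -> 0

emb = np.array([[0.0], [1.0], [10.0], [11.0]])
print("silhouette of line clusters {0,1},{10,11}:",
      round(silhouette_width(emb, [0, 0, 1, 1]), 4))
# ~0.9: points sit far from the neighbouring cluster relative to their own.
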