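"""Build deviation graphs for a healthy and a stressed plant and
compare them with the perceptual graph kernel.

Edge weights are perceptual deviations |p_i - p_j|; edges below
epsilon are pruned.  The PGK similarity is a Gaussian on the distance
between the two graphs' edge-weight embeddings.
"""

import numpy as np

from pgk import build_deviation_graph, embed, pgk_pair, write_graph
from pgk.encoding import PerceptualTraitVector

healthy = PerceptualTraitVector(
    owner_id="healthy", intensities=np.array([0.92, 0.88, 0.90, 0.85, 0.87, 0.12])
)
stressed = PerceptualTraitVector(
    owner_id="stressed", intensities=np.array([0.45, 0.41, 0.39, 0.72, 0.36, 0.91])
)

for eps in (0.0, 0.1):
    gh = build_deviation_graph(healthy, epsilon=eps)
    gs = build_deviation_graph(stressed, epsilon=eps)
    print(f"epsilon={eps}: healthy keeps {gh.n_edges} edges, "
          f"stressed keeps {gs.n_edges} edges")

gh = build_deviation_graph(healthy, epsilon=0.0)
gs = build_deviation_graph(stressed, epsilon=0.0)
phi_h, phi_s = embed(gh), embed(gs)
print("healthy LC-WI deviation:", phi_h.coordinates[4])  # |0.92 - 0.12|
sim = pgk_pair(phi_h, phi_s, sigma=1.0)
print(f"PGK(healthy, stressed) = {sim:.4f}  (1.0 would mean identical graphs)")

write_graph(gh, "scratch_healthy.graphml")
print("wrote scratch_healthy.graphml")
# At epsilon=0.1 the healthy graph keeps only the five edges incident
# to the wilting index -- its other traits are uniformly high -- while
# stress breaks trait balance and keeps nine.
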