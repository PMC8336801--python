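"""Why a tour utility: the square-collapse contrast.

Builds a cluster of four points at the corners of a unit square, then the
"collapsed" version with two points on each of two opposite corners, and
prints the two competing cluster values for each: the centroid value
v(S) (sum of distances from the mean to the members) and the tour value
u(S) (shortest closed walk through all members).
"""

import numpy as np

from hungclust import PointSet, kmeans_value, pairwise_distances, tour_value

square = PointSet(coords=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))
collapsed = PointSet(coords=np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]]))

for name, ps in [("unit square", square), ("collapsed square", collapsed)]:
    u = tour_value(pairwise_distances(ps).values)
    v = kmeans_value(ps, range(4))
    print(f"{name:17s}  u(S) = {u:.4f}   v(S) = {v:.4f}")

print()
print("Collapsing the square onto two corners condenses the cluster: the tour")
print("value drops from 4.0000 to 2.8284 (= 2*sqrt(2)), while the centroid")
print("value stays at 2.8284 and cannot tell the two configurations apart.")
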