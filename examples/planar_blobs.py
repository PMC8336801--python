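"""Clustering planar Gaussian blobs with an automatic stop.

Draws 450 points around five fixed centres (noise sd 0.3), runs the
assignment-and-merge loop from 450 singleton clusters, and prints the merge
trace: at every iteration the number of clusters k, the penalty eta (half
the average inter-centroid distance, the price of staying alone), and the
attained assignment objective.  The loop stops by itself when the identity
permutation wins — no number of clusters is supplied anywhere.
"""

from hungclust import BlobSpec, gen_blobs, run

points, truth = gen_blobs(BlobSpec(seed=42))
result = run(points)

print(f"input: {points.n} points, {len(set(truth))} generating centres")
print("iter  k_before -> k_after      eta   objective")
for r in result.trace:
    print(f"{r.iteration:4d}  {r.k_before:8d} -> {r.k_after:7d}  {r.eta:7.4f}  {r.objective:10.4f}")
print(f"final number of clusters: {result.k}")

agree = sum(
    1 for S in result.members
    if len({int(truth[i]) for i in S}) == 1
)
print(f"clusters drawn from a single generating centre: {agree}/{result.k}")
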