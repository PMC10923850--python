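"""Inspect a module's conflict graph and the max-cut that identifies it.

The conflict graph of a first-layer module has one vertex per binary input
configuration of that module; an edge weight counts training-sample pairs
that share every other module's inputs but carry different labels — evidence
that the module's outputs at the two configurations must differ.  The graph's
max-cut is the output bipartition honouring the most evidence.
"""

import numpy as np

from treestrat import (
    FitConfig,
    build_conflict_graph,
    build_label_tensors,
    make_simple_case,
    sample_dataset,
    solve_maxcut,
    MaxCutConfig,
)

truth = make_simple_case(seed=3)
dataset = sample_dataset(truth, s=400, mode="iid", seed=21)
tensors = build_label_tensors(dataset, truth.topology)

graph = build_conflict_graph(tensors, truth.topology, m=1)
print(f"module 1 conflict graph: {graph.n_vertices} vertices "
      f"(2^3 input configurations), total conflicting pairs {graph.total_weight}")
print("weight matrix:")
print(graph.weights)

solution = solve_maxcut(graph, MaxCutConfig(seed=0))
print(f"max-cut ({solution.method}): value {solution.cut_value:g}, "
      f"partition {solution.assignment.tolist()}")
side0 = np.flatnonzero(solution.assignment == 0) + 1
side1 = np.flatnonzero(solution.assignment == 1) + 1
print(f"configurations mapped to output 0: {side0.tolist()}, "
      f"to output 1: {side1.tolist()}")
print("Conflicting pairs across the cut are satisfied; the cut value over "
      "the total weight is the fraction of evidence the Boolean function "
      "can honour.")
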