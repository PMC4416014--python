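"""Score partitions of a small 2-class heterogeneous network.

Builds a 12-node chemical-gene network with three obvious mixed modules
and compares the mixed modularity of the planted grouping against the
trivial all-in-one partition (which always scores exactly 0).
"""

from mixmod import HetNet, Partition, mixed_modularity, subnetwork_stats

nodes = {f"a{i}": "A" for i in range(6)}
nodes.update({f"b{i}": "B" for i in range(6)})
edges = [
    ("a0", "a1", 1.0), ("a0", "b0", 1.0), ("a1", "b1", 1.0), ("b0", "b1", 1.0),
    ("a2", "a3", 1.0), ("a2", "b2", 1.0), ("a3", "b3", 1.0), ("b2", "b3", 1.0),
    ("a4", "a5", 1.0), ("a4", "b4", 1.0), ("a5", "b5", 1.0), ("b4", "b5", 1.0),
    ("a1", "a2", 1.0), ("b3", "b4", 1.0), ("a5", "b0", 1.0),
]
net = HetNet(nodes, edges)

st = subnetwork_stats(net)
print(f"network: {net!r}")
print(f"channel weights: AA={st.mA}, AB={st.mPi}, BB={st.mB}")

three = Partition({n: i // 4 for i, n in enumerate(sorted(net.nodes))})
grouped = Partition({
    "a0": 0, "a1": 0, "b0": 0, "b1": 0,
    "a2": 1, "a3": 1, "b2": 1, "b3": 1,
    "a4": 2, "a5": 2, "b4": 2, "b5": 2,
})
one = Partition({n: 0 for n in net.nodes})

print(f"mQ of the planted 3-module grouping: {mixed_modularity(net, grouped):.4f}")
print(f"mQ of an arbitrary 3-way split:      {mixed_modularity(net, three):.4f}")
print(f"mQ of the all-in-one partition:      {mixed_modularity(net, one):.4f}")
print("Higher mQ means the grouping concentrates all three link types "
      "inside its modules; 0 is the no-structure baseline.")
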