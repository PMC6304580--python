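"""Summary statistics of interaction matrices.

Prints the derivable summary cells (sparsity, average interactions per
drug and per target) for the five standard benchmark datasets from
their published counts, then the full statistics of a generated
synthetic dataset at the same scale as the smallest benchmark.
"""

from dlgrmc import SyntheticSpec, dataset_stats, generate, stats_from_counts

benchmarks = {
    "NRs": (54, 26, 90),
    "GPCRs": (223, 95, 635),
    "ICs": (210, 204, 1476),
    "Es": (445, 664, 2926),
    "DB": (1936, 1609, 7019),
}
print(f"{'dataset':>8s} {'sparsity %':>11s} {'drugs/target':>13s} {'targets/drug':>13s}")
for name, (d, t, e) in benchmarks.items():
    st = stats_from_counts(d, t, e)
    print(f"{name:>8s} {st['sparsity_pct']:>11.2f} "
          f"{st['avg_drugs_per_target']:>13.2f} {st['avg_targets_per_drug']:>13.2f}")

data = generate(SyntheticSpec(seed=0))
st = dataset_stats(data.ds)
print(f"\nsynthetic dataset (seed 0), mirroring the NRs scale:")
for key, val in st.items():
    print(f"  {key}: {val}")
print("\nSparsity above 93% is the regime these methods target: almost "
      "all\ndrug-target pairs are unobserved, and ranking them is the task.")
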