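"""Compare the three client split strategies on one training set.

uniform_stratified keeps silo sizes and case fractions homogeneous;
uniform_random keeps sizes homogeneous but lets labels drift;
linear_random makes silo sizes grow linearly with the client index.
"""

from fedomics import CohortSpec, generate_cohort, split_clients

fm, _ = generate_cohort(CohortSpec(n_cases=60, n_controls=120, seed=5))
print(f"training set: {fm.n_samples} samples, {fm.n_cases} cases\n")

for strategy in ("uniform_stratified", "uniform_random", "linear_random"):
    part = split_clients(fm, N=4, strategy=strategy, seed=1)
    rows = []
    for silo in part.members:
        labels = fm.subset_by_ids(list(silo)).labels
        rows.append(f"{len(labels):3d} samples / {int(labels.sum()):2d} cases")
    print(f"{strategy:20s} " + " | ".join(rows))
# Every partition is validated: silos are disjoint, cover the training set
# exactly, and each holds at least one case and one control.
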