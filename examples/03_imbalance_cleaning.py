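"""KNN undersampling of the negative class with k escalation.

Candidate lysines are overwhelmingly non-modified (~1:29 here).  Cleaning
removes each negative that has a positive among its k nearest neighbors in
feature space, escalating k from floor(n_neg / n_pos) until the negative
set is about twice the positive set.  Positives are never removed.
"""

import phoglysite as pg

dataset = pg.simulate_dataset(
    pg.SimulationConfig(length_range=(100, 800), seed=5)
)
table = pg.featurize_dataset(dataset.sites, dataset.pssms, dataset.structs)
print(f"before cleaning: {table.n_pos} positives, {table.n_neg} negatives "
      f"(1:{table.n_neg // table.n_pos})")
print(f"starting k = floor({table.n_neg}/{table.n_pos}) = "
      f"{pg.initial_k(table.n_neg, table.n_pos)}")

cleaned, report = pg.escalate_k(table)

print(f"\nk escalated {report.k_initial} -> {report.k_final}")
print(f"after cleaning:  {cleaned.n_pos} positives, {cleaned.n_neg} negatives "
      f"(ratio {report.ratio_after:.3f}, target <= {report.target_ratio})")
print(f"positives conserved: {cleaned.n_pos == table.n_pos}")

removed_total = sum(report.removed_per_k.values())
print(f"negatives removed: {removed_total} "
      f"({report.removed_per_k[report.k_initial]} already at the initial k)")
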