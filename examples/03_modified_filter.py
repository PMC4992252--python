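"""Reorder a chi-squared ranking with the pair table.

On redundancy-heavy data a univariate filter fills its head with near
copies of the same strong signals.  Complementary pairs (two distinct
signals) outscore parent-copy pairs in the table, so the reordering pulls
distinct signals together and the head of the ranking covers more of them.
"""

from pairfs import (
    EvalConfig,
    SyntheticSpec,
    build_pair_table,
    chi_squared_rank,
    generate,
    loocv_accuracy,
    pairwise_reorder,
)

spec = SyntheticSpec(n_samples=100, n_univariate=25, effect_size=0.6,
                     n_redundant=50, redundant_noise_sd=0.3, n_noise=25,
                     seed=5)
ds, roles = generate(spec)


def distinct_signals(order, k):
    """How many distinct planted signals the first k features cover."""
    seen = set()
    for f in order[:k]:
        role = roles[ds.feature_names[f]]
        if role == "univariate":
            seen.add(ds.feature_names[f])
        elif role.startswith("redundant:"):
            seen.add(role.split(":", 1)[1])
    return len(seen)


base = chi_squared_rank(ds)
pt = build_pair_table(ds, EvalConfig(classifier="knn", params={"k": 3}))
mod = pairwise_reorder(base, pt, t=50)   # consult only the top 1% of rows

svm = EvalConfig(classifier="svm_linear")
accs = {}
for label, rk in [("original chi2", base), ("pair-reordered", mod)]:
    accs[label] = loocv_accuracy(ds, rk.order[:25], svm)
    print(f"{label:<15} top-25: {distinct_signals(rk.order, 25):2d} of 25 "
          f"distinct signals, LOOCV SVM accuracy {accs[label]:.3f}")

print("\nThe reordering keeps each placed feature's best-classifying "
      "partners next to it, so the top 25 covers feature combinations "
      "that complement each other rather than copies ranked by marginal "
      "score alone "
      f"({accs['original chi2']:.3f} -> {accs['pair-reordered']:.3f} here).")
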