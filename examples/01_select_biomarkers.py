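"""Select biomarkers on synthetic data with a known planted truth.

Generates a study-sized two-group dataset (400 chemical-shift bins, 10 vs 10
samples, four markers shifted by 4 noise-sd), scans the lambda trade-off,
and prints the chosen selection next to the planted ground truth.
"""

from lpfs import generate, lambda_path, planted_spec, recovery_metrics

spec = planted_spec(seed=1, n_features=400, m1=10, m2=10, n_planted=4, shift=4.0)
ds, truth = generate(spec)

path = lambda_path(ds)
sol = path.chosen_solution

print(f"lambda grid: {len(path.lambdas)} points in [{path.lambdas[0]:g}, {path.lambdas[-1]:g}]")
print(f"chosen lambda: {path.chosen_lambda:.4g}")
print(f"selected bins (score): "
      + ", ".join(f"{ds.feature_ids[i]} ({sol.x[i]:.4f})" for i in sol.selected))
print(f"posthoc leave-one-out accuracy: {path.chosen_accuracy:.0%}")

m = recovery_metrics(sol.selected, truth.planted)
print(f"planted bins: {sorted(truth.planted)}")
print(f"precision {m.precision:.2f}, recall {m.recall:.2f}")
print()
print("Every selected bin is a true planted marker (precision 1 is typical);")
print("the LP stops as soon as the leave-one-out constraints are covered, so")
print("it may use fewer markers than were planted — parsimony by design.")
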