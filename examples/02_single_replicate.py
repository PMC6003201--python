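"""One simulated profiling exercise: generate data, apply all six methods.

Simulates the baseline design at K=10 providers of 1000 patients (10% average
mortality, two true outliers shifted by H=2 random-intercept SDs), applies
fixed- and random-effects logistic regression and the four generalized
propensity score methods, and prints each method's observed classifications
against the truth.
"""

import warnings

warnings.filterwarnings("ignore")

import profilesim as ps

spec = ps.ScenarioSpec(K=10)
result = ps.run_replicate(spec, seed=12345)

print(f"calibrated overall intercept gamma00 = {result.gamma00:.3f}")
print(f"realized overall mortality = {result.incidence:.3f} (target {spec.p_bar})\n")

truth = result.truth
print("true status: ", ", ".join(
    f"{k + 1}:{c}" for k, c in enumerate(truth.classes) if c != "normal"
))
print("(all other providers are truly normal)\n")

print(f"{'method':>8}  flagged providers (direction)        sens  spec")
for name, res in result.results.items():
    flags = [
        f"{k + 1}({lab.split('-')[1]})"
        for k, lab in enumerate(res.labels) if lab != "normal"
    ]
    m = result.measures().set_index("method").loc[name]
    print(f"{name:>8}  {', '.join(flags) if flags else '-':<35}"
          f"  {m.sensitivity:.2f}  {m.specificity:.2f}")

print(
    "\n'low' = below-average performance (excess mortality).  The fixed-\n"
    "effects method flags aggressively; the shrinkage-based methods are\n"
    "conservative and flag only clear-cut outliers."
)
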