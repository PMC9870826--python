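"""The headline experiment: trend bias from informative data reduction.

Simulates a quarter-scale trial system with zero true trends, applies
BLUP-based selection, and fits the analysis model to the complete dataset
(C) and to reductions dropping candidates tested in at most one (C-1) or
two (C-2) years.  With all data the trends are estimated without bias; the
reduced datasets show a spurious positive genetic trend mirrored by a
negative non-genetic trend.  Takes a few minutes.
"""

from vcusim import ExperimentConfig, run_experiment

config = ExperimentConfig(scenario="selection", runs=20, scale=0.25, seed=1)
result = run_experiment(config, progress=True)

print("\nsimulated truth: genetic trend = 0, non-genetic trend = 0\n")
print(f"{'variant':8s} {'genetic trend':>24s} {'non-genetic trend':>24s}")
for v, s in result.summaries.items():
    b = s.params.loc["genetic_trend"]
    g = s.params.loc["nongenetic_trend"]
    print(
        f"{v:8s} {b['mean']:+.3f} ({b['lo']:+.3f}; {b['hi']:+.3f})"
        f"   {g['mean']:+.3f} ({g['lo']:+.3f}; {g['hi']:+.3f})"
    )
print("\nAny interval excluding zero is pure artefact of the data reduction:")
print("selection rode on lucky genotype-by-year effects, and restricting the")
print("data to multi-year survivors books that luck as genetic progress.")
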