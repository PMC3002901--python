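"""End-to-end pipeline run on a small synthetic dataset.

Chains every stage — intensity generation, normalization, ANOVA prefilter,
all four selectors, consensus, overlap accounting, PCA/GGM — and writes all
artifacts plus a manifest to ./crhnet_demo_run/.  The overlap table mirrors
the method-comparison accounting (pairwise intersections of top lists).
"""

from crhnet import annealing, baselines, ga
from crhnet.pipeline import PipelineConfig, run_pipeline
from crhnet.synthetic import SyntheticConfig

config = PipelineConfig(
    synthetic=SyntheticConfig(
        n_spots=200, n_print_tips=2, n_de_genes=15, n_interaction_genes=5,
        seed=0,
    ),
    out_dir="crhnet_demo_run",
    seed=1,
    ga_params=ga.GaParams(max_solutions=10, max_generations=50),
    sa_params=annealing.SaParams(max_solutions=10, maxit=200,
                                 n_calibration=100),
    rf_params=baselines.RfParams(n_trees=200),
    n_repetitions=3,
    consensus_top=20,
    consensus_min_runs=2,
)
results = run_pipeline(config)

print("stages run:", ", ".join(results["manifest"]["stages"]))
print(f"preselected genes: {len(results['prefilter'].preselected)}")
print(f"GA consensus: {results['ga_consensus']}")
print(f"greedy LOOCV error: {100 * results['greedy'].error:.0f}%")
print(f"RF OOB error: {100 * results['rf'].error:.0f}%")
print("\noverlap accounting:")
print(results["overlap"].to_string(index=False))
print("\nartifacts in ./crhnet_demo_run/")
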