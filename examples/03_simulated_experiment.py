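"""Simulate a full MA experiment and compare losses with the analytic model.

Runs 40 lines for 21 bottlenecks with a mildly deleterious mutation
supply, then checks the realised sampling-loss rate against the
closed-form per-transfer loss probability.
"""

from picoma import (
    DFE,
    ExperimentDesign,
    SamplingScheme,
    SimulationParams,
    loss_prob_poisson,
    relative_fitness_table,
    simulate_ma_experiment,
)

params = SimulationParams(
    design=ExperimentDesign(
        n_lines=40, n_bottlenecks=21,
        scheme=SamplingScheme(mean_cells_sampled=10, discard_fraction=0.4),
    ),
    base_divisions_per_day=1.0,          # 14 generations per 14-day interval
    mutation_rate=0.004,                 # mutations/genome/generation
    dfe=DFE(fraction_lethal=0.02, fraction_deleterious=0.5,
            mean_effect_deleterious=0.05),
    count_noise_cv=0.02,
    seed=42,
)
experiment = simulate_ma_experiment(params)

counts = experiment.loss_counts()
print(f"surviving lines : {len(experiment.surviving_lines)}/40")
print(f"losses          : {counts['sampling']} sampling, {counts['lethal']} lethal")
print(f"analytic p_loss : {loss_prob_poisson(10, 0.4):.4f} per transfer "
      f"({experiment.n_transfer_trials} transfer trials)")

rel = relative_fitness_table(experiment.to_bottleneck_table())
final = rel[rel["bottleneck"] == rel["bottleneck"].max()]["g_r"].dropna()
print(f"final G_r       : mean {final.mean():.4f} (1.0 = control fitness); "
      "values below 1 reflect accumulated deleterious mutations")
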