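"""Design a single-cell transfer protocol: how often will a line be lost?

Builds the loss-design table for a protocol that samples a volume
expected to hold 10 cells, discards 40% of it, and runs 40 lines over
27 or 21 bottlenecks, across increasing levels of pipetting error.
"""

from picoma import SamplingScheme, design_table, loss_prob_poisson

scheme = SamplingScheme(mean_cells_sampled=10, discard_fraction=0.4)
table = design_table(
    scheme,
    cv_values=[0.0, 0.05, 0.4, 0.5],
    designs=[("27_transfers", 40, 27), ("21_transfers", 40, 21)],
)
print(table.round({"p_loss": 4, "L_exp_27_transfers": 1, "L_exp_21_transfers": 1}))
print()
print(f"naive single-cell transfer loses a line with p = "
      f"{loss_prob_poisson(1, 0):.2f} per bottleneck")
print("p_loss is the per-line per-bottleneck loss probability; L_exp the")
print("expected number of losses in each experiment layout. With careful")
print("pipetting (CV <= 0.05) fewer than 3 of 40 lines should be lost, so a")
print("much larger observed loss implicates biology, not sampling.")
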