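"""Minimum mutation-rate bounds from significant-line counts.

Every line whose fitness differs significantly from the control in at
least one environment must carry at least one mutation, so the count of
such lines over the generations elapsed is a lower bound on the
per-genome mutation rate.
"""

from picoma import lethal_rate_bound, min_mutation_rate

experiments = [
    ("9 of 9 lines, 272 generations", 9, 9, 272, 13_500_000),
    ("7 of 7 lines, 272 generations", 7, 7, 272, 21_000_000),
    ("8 of 8 lines, 265 generations", 8, 8, 265, 15_000_000),
]
for label, n_sig, n_tested, gens, genome_bp in experiments:
    est = min_mutation_rate(n_sig, n_tested, gens, genome_size_bp=genome_bp)
    print(f"{label}: U >= {est.u_genome:.4f} /genome/generation"
          f"  ({est.u_site:.2e} /site/generation at {genome_bp / 1e6:.0f} Mb)")

print()
bound = lethal_rate_bound(n_lines_lost=20, n_lines_started=40,
                          generations_per_line=100)
print(f"If 20 of 40 lines were lost over 100 generations and every loss were a")
print(f"lethal mutation, the lethal rate would be at most {bound:.4f} per")
print("genome per generation — an upper-bound screen, since sampling error and")
print("division failure also cause losses.")
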