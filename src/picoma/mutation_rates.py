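"""Lower-bound mutation-rate inference from MA fitness phenotypes.

A line whose fitness differs significantly from the control in at least
one environment must carry at least one mutation, so counting such lines
gives a *minimum* per-genome mutation rate

    U_min = n_implied_mutations / (n_lines_tested × generations_per_line)

with n_implied_mutations = the number of significantly different lines
(one mutation credited per line; several mutations in one line collapse
to one, which is why the estimate is a lower bound).  A per-site rate is
attached when the genome size is supplied.

Similarly, if line losses at bottlenecks are attributed entirely to
lethal mutations, (lines lost / lines started) / generations is an
upper-bound screening statistic for the lethal mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MutationRateEstimate", "min_mutation_rate", "lethal_rate_bound"]


@dataclass(frozen=True)
class MutationRateEstimate:
    """A minimum per-genome (and optional per-site) mutation rate.

    ``is_lower_bound`` is always True for estimates from significant-line
    counts: each significant line is credited exactly one mutation.
    """

    u_genome: float
    n_implied_mutations: int
    n_lines: int
    generations_per_line: float
    genome_size_bp: int | None = None
    u_site: float | None = None
    is_lower_bound: bool = True


def min_mutation_rate(
    n_significant_lines: int,
    n_lines_tested: int,
    generations_per_line: float,
    genome_size_bp: int | None = None,
) -> MutationRateEstimate:
    """Minimum mutations/genome/generation from significant-line counts.

    >>> min_mutation_rate(9, 9, 272).u_genome  # doctest: +ELLIPSIS
    0.003676...
    """
    if n_lines_tested < 1:
        raise ValueError("n_lines_tested must be >= 1")
    if generations_per_line <= 0:
        raise ValueError("generations_per_line must be > 0")
    if not 0 <= n_significant_lines <= n_lines_tested:
        raise ValueError("n_significant_lines must be in [0, n_lines_tested]")
    if genome_size_bp is not None and genome_size_bp < 1:
        raise ValueError("genome_size_bp must be >= 1")
    u_genome = n_significant_lines / (n_lines_tested * generations_per_line)
    u_site = u_genome / genome_size_bp if genome_size_bp else None
    return MutationRateEstimate(
        u_genome=u_genome,
        n_implied_mutations=n_significant_lines,
        n_lines=n_lines_tested,
        generations_per_line=generations_per_line,
        genome_size_bp=genome_size_bp,
        u_site=u_site,
    )


def lethal_rate_bound(
    n_lines_lost: int, n_lines_started: int, generations_per_line: float
) -> float:
    """Upper-bound lethal-mutation rate per genome per generation.

    The literal accounting (lines lost / lines started) / generations;
    it attributes every loss to a lethal mutation, so losses from
    sampling error or division failure inflate it — treat it as a
    screening statistic, not an estimate.
    """
    if n_lines_started < 1:
        raise ValueError("n_lines_started must be >= 1")
    if generations_per_line <= 0:
        raise ValueError("generations_per_line must be > 0")
    if not 0 <= n_lines_lost <= n_lines_started:
        raise ValueError("n_lines_lost must be in [0, n_lines_started]")
    return (n_lines_lost / n_lines_started) / generations_per_line
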