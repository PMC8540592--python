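"""Simulated-annealing minimization of the RDS opening energy.

The optimizer walks the space of synonymous coding sequences by random
single-nucleotide swaps in a bounded codon region (the start codon is
immutable), scoring each candidate by the opening energy of the RDS window
at the canonical SD offset, and accepting moves with the Metropolis rule
under a geometric cooling schedule. The 5'UTR is never touched and every
accepted state encodes the input protein by construction.

The best-ever state (not the last-visited one) is returned, which makes
the outcome robust to the tail of the schedule. ``brute_force_optimum``
enumerates all synonymous codon combinations on small instances and serves
as the optimizer's exact oracle.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .energy import EnergyBackend
from .errors import ConstraintError, NoMoveError, SearchSpaceError
from .score import (
    InitiationScore,
    ScoreParameters,
    default_backend,
    delta_score,
    rds_window,
)
from .sequence import (
    CodingSequence,
    Construct,
    synonymous_single_nt_variants,
    translate,
)

#: guard on brute-force search-space size
MAX_BRUTE_FORCE = 100_000


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling schedule for the Metropolis walk.

    Temperatures are dimensionless (energies in kcal/mol divided by a
    kcal/mol-scale temperature); defaults anneal from 1.0 to 1e-3 with
    multiplicative cooling 0.95, 20 proposals per temperature, capped at
    ``max_iterations`` proposals overall.
    """

    t_start: float = 1.0
    t_end: float = 1e-3
    cooling: float = 0.95
    steps_per_temperature: int = 20
    max_iterations: int = 2000
    seed: int = 20210741

    def __post_init__(self) -> None:
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.steps_per_temperature < 1:
            raise ValueError("steps_per_temperature must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")

    def temperatures(self):
        """Yield one SA temperature per proposal, up to max_iterations."""
        t = self.t_start
        emitted = 0
        while t >= self.t_end and emitted < self.max_iterations:
            for _ in range(self.steps_per_temperature):
                if emitted >= self.max_iterations:
                    return
                yield t
                emitted += 1
            t *= self.cooling


@dataclass(frozen=True)
class Mutation:
    """A single-nucleotide synonymous substitution."""

    codon_index: int
    position_in_codon: int
    from_nt: str
    to_nt: str

    @property
    def c_notation(self) -> str:
        """HGVS-like coding notation, 1-based (e.g. ``c.9U>C``)."""
        pos = 3 * self.codon_index + self.position_in_codon + 1
        return f"c.{pos}{self.from_nt}>{self.to_nt}"


@dataclass(frozen=True)
class TrajectoryPoint:
    iteration: int
    proposed_dE_open: float
    accepted: bool


@dataclass(frozen=True)
class OptimizationResult:
    optimized: Construct
    initial_dE_open: float
    final_dE_open: float
    mutations: tuple[Mutation, ...]
    trajectory: tuple[TrajectoryPoint, ...]
    seed_used: int
    region: tuple[int, int]
    no_feasible_move: bool = False
    final_score: InitiationScore | None = None


def propose_move(
    cds: CodingSequence, region: tuple[int, int], rng: random.Random
) -> CodingSequence:
    """Uniform draw from the synonymous single-nt variants inside ``region``."""
    variants = synonymous_single_nt_variants(cds, region)
    if not variants:
        raise NoMoveError(
            f"no synonymous single-nucleotide move exists in codons "
            f"[{region[0]}, {region[1]})"
        )
    return rng.choice(variants)


def accept(
    current_E: float, proposed_E: float, sa_temperature: float, rng: random.Random
) -> bool:
    """Metropolis criterion: downhill always, uphill with exp(-dE/t)."""
    if sa_temperature <= 0:
        raise ValueError("SA temperature must be positive")
    if proposed_E <= current_E:
        return True
    return rng.random() < math.exp(-(proposed_E - current_E) / sa_temperature)


def diff_mutations(
    original: CodingSequence, mutated: CodingSequence
) -> tuple[Mutation, ...]:
    """Per-nucleotide differences between two equal-length coding sequences."""
    if len(original.rna) != len(mutated.rna):
        raise ConstraintError("coding sequences differ in length")
    out = []
    for pos, (a, b) in enumerate(zip(original.rna, mutated.rna)):
        if a != b:
            out.append(Mutation(pos // 3, pos % 3, a, b))
    return tuple(out)


def _default_region(cds: CodingSequence) -> tuple[int, int]:
    # codons 1..10: the 30-nt RDS window at i = -11 reaches ~19 nt (7 codons)
    # into the coding region; 10 gives headroom
    return (1, min(11, cds.codon_count))


def optimize(
    c: Construct,
    region: tuple[int, int] | None = None,
    p: ScoreParameters | None = None,
    sched: AnnealingSchedule | None = None,
    backend: EnergyBackend | None = None,
    keep_trajectory: bool = True,
) -> OptimizationResult:
    """Anneal the proximal coding region to minimize the RDS opening energy.

    The objective is dE_open of the window anchored at the construct's SD
    offset; the 5'UTR, SD and start codon are untouched. Identical inputs
    and seed yield an identical result. When the region admits no
    synonymous single-nt move at all, the input is returned unchanged with
    an empty mutation list and ``no_feasible_move`` set.
    """
    p = p or ScoreParameters()
    sched = sched or AnnealingSchedule()
    backend = backend or default_backend()
    region = region or _default_region(c.cds)
    # validate the region eagerly (raises on start-codon inclusion)
    if region[0] < 1 or region[1] > c.cds.codon_count or region[0] >= region[1]:
        raise ConstraintError(
            f"codon region [{region[0]}, {region[1]}) invalid for "
            f"{c.cds.codon_count} codons (codon 0 is immutable)"
        )
    window = rds_window(c, p)
    target_protein = translate(c.cds).residues

    def objective(cds: CodingSequence) -> float:
        return backend.opening_energy(c.utr5 + cds.rna, window)

    rng = random.Random(sched.seed)
    initial_E = objective(c.cds)
    current, current_E = c.cds, initial_E
    best, best_E = c.cds, initial_E
    trajectory: list[TrajectoryPoint] = []
    no_feasible = False
    for iteration, t in enumerate(sched.temperatures()):
        try:
            proposal = propose_move(current, region, rng)
        except NoMoveError:
            no_feasible = True
            break
        proposed_E = objective(proposal)
        ok = accept(current_E, proposed_E, t, rng)
        if keep_trajectory:
            trajectory.append(TrajectoryPoint(iteration, proposed_E, ok))
        if ok:
            current, current_E = proposal, proposed_E
            if current_E < best_E:
                best, best_E = current, current_E
            assert translate(current).residues == target_protein
    optimized = c.with_cds(best)
    return OptimizationResult(
        optimized=optimized,
        initial_dE_open=initial_E,
        final_dE_open=best_E,
        mutations=diff_mutations(c.cds, best),
        trajectory=tuple(trajectory),
        seed_used=sched.seed,
        region=region,
        no_feasible_move=no_feasible,
        final_score=delta_score(optimized, p, backend),
    )


def _synonym_family(codon: str, table_id: int) -> list[str]:
    table = CodonTable.unambiguous_rna_by_id[table_id]
    if codon in table.stop_codons:
        return sorted(table.stop_codons)
    aa = table.forward_table[codon]
    return sorted(k for k, v in table.forward_table.items() if v == aa)


def brute_force_optimum(
    c: Construct,
    region: tuple[int, int] | None = None,
    p: ScoreParameters | None = None,
    backend: EnergyBackend | None = None,
) -> tuple[CodingSequence, float]:
    """Exact global minimum of dE_open over all synonymous codon combinations.

    Enumerates the full synonym family of every codon in ``region`` (a
    superset of what single-swap walks can reach for split codon families),
    guards the product of family sizes at ``MAX_BRUTE_FORCE``, and breaks
    exact ties toward the lexicographically smallest sequence.
    """
    p = p or ScoreParameters()
    backend = backend or default_backend()
    region = region or _default_region(c.cds)
    if region[0] < 1 or region[1] > c.cds.codon_count or region[0] >= region[1]:
        raise ConstraintError(f"codon region [{region[0]}, {region[1]}) invalid")
    window = rds_window(c, p)
    families = [
        _synonym_family(c.cds.codon(ci), c.cds.table_id)
        for ci in range(region[0], region[1])
    ]
    size = math.prod(len(f) for f in families)
    if size > MAX_BRUTE_FORCE:
        raise SearchSpaceError(
            f"synonymous search space {size} exceeds guard {MAX_BRUTE_FORCE}"
        )
    rna = c.cds.rna
    prefix = rna[: 3 * region[0]]
    suffix = rna[3 * region[1] :]
    best_seq: str | None = None
    best_E = math.inf
    for combo in itertools.product(*families):
        seq = prefix + "".join(combo) + suffix
        e = backend.opening_energy(c.utr5 + seq, window)
        if e < best_E or (e == best_E and (best_seq is None or seq < best_seq)):
            best_seq, best_E = seq, e
    assert best_seq is not None
    return CodingSequence(best_seq, c.cds.table_id), best_E
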