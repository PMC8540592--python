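"""Exhaustive secondary-structure enumeration — the small-sequence oracle.

Enumerates *every* secondary structure of a short RNA under the package's
structural conventions (nested canonical + G.U pairs, minimum hairpin loop
3, no lonely pairs), evaluates each structure with the shared
nearest-neighbor energy function by explicit loop decomposition, and
Boltzmann-sums the ensemble. Deliberately brute force: it exists to check
the dynamic-programming backend, so it shares the energy *parameters* but
none of the recursions.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from . import nnparams
from .errors import LengthError
from .nnparams import (
    MIN_HAIRPIN,
    ML_BRANCH,
    ML_CLOSE,
    ML_UNPAIRED,
    R_KCAL,
    STACK,
    hairpin_energy,
    internal_energy,
    pair_type,
)

#: combinatorial safety bound for exhaustive enumeration
MAX_ENUM_LENGTH = 25

Structure = tuple[tuple[int, int], ...]


def _canonical(a: str, b: str) -> bool:
    return pair_type(a, b) >= 0


def enumerate_structures(rna: str) -> list[Structure]:
    """All secondary structures of ``rna`` as sorted tuples of (i, j) pairs.

    Includes the open chain (empty tuple). Structures are nested (no
    pseudoknots), use canonical Watson-Crick/G.U pairs with a hairpin loop
    of at least ``MIN_HAIRPIN`` nt, and contain no lonely pairs: every pair
    stacks on a neighbor within its helix.
    """
    n = len(rna)
    if n > MAX_ENUM_LENGTH:
        raise LengthError(
            f"enumeration oracle is bounded to {MAX_ENUM_LENGTH} nt (got {n})"
        )
    memo: dict[tuple[int, int], list[Structure]] = {}

    def enum(i: int, j: int) -> list[Structure]:
        """All nested canonical pairings (lonely pairs still allowed here)."""
        if j - i < MIN_HAIRPIN:  # too short to hold any pair
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out: list[Structure] = list(enum(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if not _canonical(rna[i], rna[k]):
                continue
            for inside in enum(i + 1, k - 1):
                for outside in enum(k + 1, j):
                    out.append(((i, k),) + inside + outside)
        memo[key] = out
        return out

    def no_lonely(st: Structure) -> bool:
        pairs = set(st)
        return all(
            (i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs for i, j in pairs
        )

    return [tuple(sorted(st)) for st in enum(0, n - 1) if no_lonely(st)]


def structure_energy(rna: str, structure: Iterable[tuple[int, int]]) -> float:
    """Loop-decomposition free energy (kcal/mol) of one structure.

    The exterior loop contributes zero; each pair contributes the energy of
    the loop it closes (hairpin, stack, bulge/interior, or multiloop).
    Returns ``inf`` for structures containing a disallowed loop (oversized
    interior loop), which carries zero Boltzmann weight.
    """
    pairs = sorted(structure)
    if not pairs:
        return 0.0
    close = dict(pairs)
    energy = 0.0
    for i, j in pairs:
        # children: pairs directly nested inside (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in close and close[k] < j:
                children.append((k, close[k]))
                k = close[k] + 1
            else:
                k += 1
        if not children:
            energy += hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            if k == i + 1 and l == j - 1:
                energy += STACK[pair_type(rna[i], rna[j]), pair_type(rna[k], rna[l])]
            else:
                energy += internal_energy(k - i - 1, j - l - 1)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            energy += (
                ML_CLOSE + ML_BRANCH * (len(children) + 1) + ML_UNPAIRED * unpaired
            )
    return energy


def _paired_positions(st: Structure) -> set[int]:
    out: set[int] = set()
    for i, j in st:
        out.add(i)
        out.add(j)
    return out


def ensemble_free_energy_oracle(
    rna: str,
    unpaired: Sequence[int] | None = None,
    temperature: float = nnparams.T_KELVIN,
) -> float:
    """Oracle Gibbs ensemble free energy by direct Boltzmann summation.

    ``unpaired``: positions constrained to be single-stranded; structures
    pairing any of them are excluded from the ensemble.
    """
    rt = R_KCAL * temperature
    forbidden = set(unpaired or ())
    z = 0.0
    for st in enumerate_structures(rna):
        if forbidden and (_paired_positions(st) & forbidden):
            continue
        e = structure_energy(rna, st)
        if math.isfinite(e):
            z += math.exp(-e / rt)
    return -rt * math.log(z)


def opening_energy_oracle(
    rna: str,
    window: tuple[int, int],
    temperature: float = nnparams.T_KELVIN,
) -> float:
    """Oracle opening energy of the half-open window ``[start, start+length)``."""
    start, length = window
    positions = range(start, start + length)
    return ensemble_free_energy_oracle(
        rna, unpaired=list(positions), temperature=temperature
    ) - ensemble_free_energy_oracle(rna, temperature=temperature)
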