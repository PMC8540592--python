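"""Simplified nearest-neighbor free-energy parameterization (37 degC).

A compact Turner-style parameter set for RNA secondary structures:

* canonical pairs: Watson-Crick plus the G.U wobble;
* sequence-dependent helix stacking free energies;
* size-dependent hairpin, bulge and interior-loop penalties with a
  Jacobson-Stockmayer logarithmic extrapolation for long loops;
* an affine multiloop model (closing penalty + per-branch term);
* a duplex-initiation penalty for intermolecular hybridization.

Structural conventions, fixed for the whole package (backend, oracle,
duplex): minimum hairpin loop of 3 nt, no pseudoknots, no isolated (lonely)
base pairs - every helix is at least two pairs long - and interior/bulge
loops of at most ``MAX_INTERIOR_LOOP`` unpaired nucleotides. Loop energies
are size-only (no terminal-mismatch or dangling-end terms), which keeps the
model exactly shared between the dynamic-programming backend and the
exhaustive enumeration oracle.

All energies are free energies at 37 degC in kcal/mol; the thermodynamic
temperature enters only through RT in Boltzmann weighting.
"""

from __future__ import annotations

import math

import numpy as np

#: molar gas constant, kcal/(mol K)
R_KCAL = 1.987e-3
#: default temperature, kelvin (37 degC)
T_KELVIN = 310.15

#: nucleotide encoding used by the numeric kernels
NT_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

#: pair-type encoding; -1 = not a canonical pair
PAIR_ORDER = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_INDEX = np.full((4, 4), -1, dtype=np.int64)
for _k, _p in enumerate(PAIR_ORDER):
    PAIR_INDEX[NT_CODE[_p[0]], NT_CODE[_p[1]]] = _k

#: minimum hairpin loop size (unpaired nt between a pair)
MIN_HAIRPIN = 3
#: maximum interior/bulge loop size (n1 + n2); larger loops are disallowed
MAX_INTERIOR_LOOP = 30

# Stacking free energies, kcal/mol. STACK[p, q] is the energy of pair q
# (at i+1, j-1) stacked inside pair p (at i, j), pairs read 5'->3' on the
# top strand. Values follow the familiar Turner-style magnitudes.
STACK = np.array(
    [
        #  AU     UA     CG     GC     GU     UG     (inner pair)
        [-0.93, -1.10, -2.24, -2.08, -0.55, -1.36],  # outer AU
        [-1.33, -0.93, -2.35, -2.11, -1.00, -0.99],  # outer UA
        [-2.11, -2.08, -3.26, -2.36, -1.41, -2.11],  # outer CG
        [-2.35, -2.24, -3.42, -3.26, -1.53, -2.51],  # outer GC
        [-0.99, -1.36, -2.51, -2.11, -0.50, +1.29],  # outer GU
        [-1.00, -0.55, -1.53, -1.41, +0.30, -0.50],  # outer UG
    ],
    dtype=np.float64,
)

# Hairpin-loop penalties by loop size (index = size; sizes < 3 impossible).
_HAIRPIN_BASE = [math.inf, math.inf, math.inf, 5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4]
# Bulge penalties by size.
_BULGE_BASE = [math.inf, 3.8, 2.8, 3.2, 3.6, 4.0, 4.4]
# Interior-loop penalties by total size n1+n2 (>= 2).
_INTERIOR_BASE = [math.inf, math.inf, 1.5, 1.6, 1.7, 2.0, 2.0]

#: Jacobson-Stockmayer extrapolation prefactor (1.75 * R * T at 37 degC)
_LOG_COEF = 1.75 * R_KCAL * T_KELVIN

#: interior-loop asymmetry penalty per unit |n1 - n2|, capped
ASYMMETRY = 0.6
ASYMMETRY_MAX = 3.0

#: multiloop affine model: closing + per-branch (the closing pair counts as
#: a branch) + per-unpaired-nt inside the loop
ML_CLOSE = 3.4
ML_BRANCH = 0.4
ML_UNPAIRED = 0.0

#: intermolecular duplex initiation penalty
DUPLEX_INIT = 4.09


def _extrapolate(base: list[float], n: int) -> float:
    last = len(base) - 1
    if n <= last:
        return base[n]
    return base[last] + _LOG_COEF * math.log(n / last)


def hairpin_energy(size: int) -> float:
    """Free-energy penalty of a hairpin loop of ``size`` unpaired nt."""
    if size < MIN_HAIRPIN:
        return math.inf
    return _extrapolate(_HAIRPIN_BASE, size)


def internal_energy(n1: int, n2: int) -> float:
    """Penalty of the loop between two pairs with n1/n2 unpaired nt per side.

    n1 = n2 = 0 is a helix stack and is *not* handled here (use ``STACK``).
    """
    if n1 == 0 and n2 == 0:
        raise ValueError("stacked pairs are scored with STACK, not internal_energy")
    total = n1 + n2
    if total > MAX_INTERIOR_LOOP:
        return math.inf
    if n1 == 0 or n2 == 0:
        return _extrapolate(_BULGE_BASE, total)
    asym = min(ASYMMETRY * abs(n1 - n2), ASYMMETRY_MAX)
    return _extrapolate(_INTERIOR_BASE, total) + asym


def encode(rna: str) -> np.ndarray:
    """Encode an RNA string into the integer alphabet of the kernels."""
    try:
        return np.array([NT_CODE[c] for c in rna], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - callers normalize first
        raise ValueError(f"non-RNA character {exc.args[0]!r}") from exc


def pair_type(a: str, b: str) -> int:
    """Pair-type index of nucleotides a, b (5' partner first), or -1."""
    return int(PAIR_INDEX[NT_CODE[a], NT_CODE[b]])


# Precomputed penalty tables for the numba kernels (indexed by size).
_TABLE_LEN = 1024


def _penalty_table(fn, max_len: int = _TABLE_LEN) -> np.ndarray:
    out = np.empty(max_len, dtype=np.float64)
    for n in range(max_len):
        try:
            out[n] = fn(n)
        except ValueError:
            out[n] = math.inf
    return out


HAIRPIN_TABLE = _penalty_table(hairpin_energy)
BULGE_TABLE = _penalty_table(lambda n: _extrapolate(_BULGE_BASE, n) if n >= 1 else math.inf)
INTERIOR_TABLE = _penalty_table(
    lambda n: _extrapolate(_INTERIOR_BASE, n) if n >= 2 else math.inf
)
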