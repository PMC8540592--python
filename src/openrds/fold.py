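"""McCaskill-style partition function over the shared nearest-neighbor model.

Exact dynamic programming (numba-compiled) for the equilibrium ensemble of
secondary structures under the package's structural conventions (canonical
+ G.U pairs, min hairpin loop 3, interior loops capped, *no lonely pairs*),
with optional hard single-strandedness constraints — the quantity pair
(unconstrained vs constrained ensemble free energy) behind opening
energies.

The no-lonely-pair rule is handled exactly by splitting the paired-interval
quantity in two: ``qb[i, j]`` assumes the pair (i, j) is already supported
by an enclosing stack, while ``qs[i, j]`` requires (i, j) to stack inward
on (i+1, j-1). Helices therefore always contain at least two pairs.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import nnparams
from .errors import LengthError, WindowError
from .nnparams import (
    ASYMMETRY,
    ASYMMETRY_MAX,
    BULGE_TABLE,
    HAIRPIN_TABLE,
    INTERIOR_TABLE,
    MAX_INTERIOR_LOOP,
    MIN_HAIRPIN,
    ML_BRANCH,
    ML_CLOSE,
    ML_UNPAIRED,
    PAIR_INDEX,
    R_KCAL,
    STACK,
    encode,
)

#: guard against float64 overflow of the unscaled partition function
MAX_FOLD_LENGTH = 250


@njit(cache=True)
def _partition(seq, mask, beta):  # pragma: no cover - exercised via wrapper
    n = seq.shape[0]
    qb = np.zeros((n, n))
    qs = np.zeros((n, n))
    qm = np.zeros((n, n))
    qm1 = np.zeros((n, n))

    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - d):
            j = i + d
            pt = PAIR_INDEX[seq[i], seq[j]]
            if pt >= 0 and not mask[i] and not mask[j]:
                # hairpin
                z = math.exp(-beta * HAIRPIN_TABLE[j - i - 1])
                # helix continuation (stack)
                if j - i - 2 > MIN_HAIRPIN:
                    pt_in = PAIR_INDEX[seq[i + 1], seq[j - 1]]
                    if pt_in >= 0 and not mask[i + 1] and not mask[j - 1]:
                        z += math.exp(-beta * STACK[pt, pt_in]) * qb[i + 1, j - 1]
                # bulge / interior loops (inner helix starts fresh -> qs)
                for k in range(i + 1, j - MIN_HAIRPIN - 1):
                    n1 = k - i - 1
                    if n1 > MAX_INTERIOR_LOOP:
                        break
                    for l in range(j - 1, k + MIN_HAIRPIN, -1):
                        n2 = j - l - 1
                        if n1 + n2 > MAX_INTERIOR_LOOP:
                            break
                        if n1 == 0 and n2 == 0:
                            continue
                        if qs[k, l] == 0.0:
                            continue
                        if n1 == 0 or n2 == 0:
                            e = BULGE_TABLE[n1 + n2]
                        else:
                            asym = ASYMMETRY * abs(n1 - n2)
                            if asym > ASYMMETRY_MAX:
                                asym = ASYMMETRY_MAX
                            e = INTERIOR_TABLE[n1 + n2] + asym
                        z += math.exp(-beta * e) * qs[k, l]
                # multiloop: >= 2 branches inside [i+1, j-1]
                zm = 0.0
                for k in range(i + 2, j - 1):
                    if qm1[k, j - 1] > 0.0 and qm[i + 1, k - 1] > 0.0:
                        zm += qm[i + 1, k - 1] * qm1[k, j - 1]
                z += math.exp(-beta * (ML_CLOSE + ML_BRANCH)) * zm
                qb[i, j] = z
                # helix start: (i, j) must stack inward
                if j - i - 2 > MIN_HAIRPIN:
                    pt_in = PAIR_INDEX[seq[i + 1], seq[j - 1]]
                    if pt_in >= 0 and not mask[i + 1] and not mask[j - 1]:
                        qs[i, j] = (
                            math.exp(-beta * STACK[pt, pt_in]) * qb[i + 1, j - 1]
                        )
            # qm1: exactly one branch starting at i, trailing unpaired to j
            z1 = 0.0
            for l in range(i + MIN_HAIRPIN + 1, j + 1):
                if qs[i, l] > 0.0:
                    z1 += qs[i, l] * math.exp(
                        -beta * (ML_BRANCH + ML_UNPAIRED * (j - l))
                    )
            qm1[i, j] = z1
            # qm: >= 1 branch on [i, j]
            zm2 = 0.0
            for k in range(i, j + 1):
                if qm1[k, j] > 0.0:
                    lead = math.exp(-beta * ML_UNPAIRED * (k - i))
                    if k > i:
                        lead += qm[i, k - 1]
                    zm2 += lead * qm1[k, j]
            qm[i, j] = zm2

    # exterior loop
    q = np.zeros(n + 1)
    q[0] = 1.0
    for j in range(1, n + 1):
        z = q[j - 1]
        for i in range(0, j - 1):
            if qs[i, j - 1] > 0.0:
                z += q[i] * qs[i, j - 1]
        q[j] = z
    return q[n]


def ensemble_free_energy(
    rna: str,
    unpaired_mask: np.ndarray | None = None,
    temperature: float = nnparams.T_KELVIN,
) -> float:
    """Gibbs ensemble free energy (kcal/mol) of all secondary structures.

    ``unpaired_mask``: boolean array marking bases constrained to be
    single-stranded; the constrained ensemble contains exactly the
    structures leaving those bases unpaired.
    """
    n = len(rna)
    if n < 1:
        raise LengthError("empty sequence")
    if n > MAX_FOLD_LENGTH:
        raise LengthError(
            f"partition function is unscaled; sequences are bounded to "
            f"{MAX_FOLD_LENGTH} nt (got {n})"
        )
    seq = encode(rna)
    if unpaired_mask is None:
        mask = np.zeros(n, dtype=np.bool_)
    else:
        mask = np.asarray(unpaired_mask, dtype=np.bool_)
        if mask.shape != (n,):
            raise WindowError("constraint mask length does not match the sequence")
    rt = R_KCAL * temperature
    z = _partition(seq, mask, 1.0 / rt)
    if not math.isfinite(z):
        raise LengthError("partition function overflow; sequence too structured/long")
    return -rt * math.log(z)
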