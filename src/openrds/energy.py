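"""Thermodynamics backend contract.

An :class:`EnergyBackend` supplies three quantities, all in kcal/mol at the
backend's temperature:

* ``duplex_energy(a, b)`` — most favorable intermolecular hybridization
  free energy of two short strands (``None`` when no canonical pairing is
  possible; distinct from 0.0, which is a meaningful energy);
* ``ensemble_free_energy(s, window=None)`` — Gibbs ensemble free energy,
  optionally constraining a window of bases to stay unpaired;
* ``opening_energy(s, window)`` — the constrained-minus-unconstrained
  difference: the free-energy cost of forcing the window single-stranded.

The default :class:`NearestNeighborBackend` is an exact partition function
over the package's simplified nearest-neighbor model (see
:mod:`openrds.nnparams`); :class:`ViennaRNABackend` delegates to ViennaRNA
when its Python bindings are installed and exists for cross-checks and
users who want the full Turner model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from . import fold, nnparams
from .errors import LengthError, WindowError
from .nnparams import DUPLEX_INIT, MAX_INTERIOR_LOOP, STACK, internal_energy, pair_type

#: length bound that keeps duplex_energy a short-motif operation
MAX_DUPLEX_LENGTH = 60


@dataclass(frozen=True)
class Window:
    """A half-open run of transcript positions ``[start, start+length)``."""

    start: int
    length: int = 30

    def __post_init__(self) -> None:
        if self.length < 1:
            raise WindowError(f"window length must be >= 1 (got {self.length})")

    @property
    def stop(self) -> int:
        return self.start + self.length

    def check(self, sequence_length: int) -> None:
        if self.start < 0 or self.stop > sequence_length:
            raise WindowError(
                f"window [{self.start}, {self.stop}) does not fit a "
                f"{sequence_length}-nt sequence"
            )

    def mask(self, sequence_length: int) -> np.ndarray:
        self.check(sequence_length)
        m = np.zeros(sequence_length, dtype=bool)
        m[self.start : self.stop] = True
        return m


def duplex_energy_nn(a: str, b: str) -> Optional[float]:
    """Minimum intermolecular hybridization free energy (RNAduplex-like).

    Considers every antiparallel duplex alignment of *a* (5'->3') against
    *b*, with stacking, bulge and interior loops from the shared
    nearest-neighbor tables plus a duplex-initiation penalty. Intramolecular
    structure is ignored (short motifs). Returns ``None`` when the two
    strands admit no canonical pair at all.
    """
    if not a or not b:
        raise LengthError("duplex strands must be nonempty")
    if len(a) > MAX_DUPLEX_LENGTH or len(b) > MAX_DUPLEX_LENGTH:
        raise LengthError(
            f"duplex strands are bounded to {MAX_DUPLEX_LENGTH} nt"
        )
    la, lb = len(a), len(b)
    # best[i][j]: lowest energy of a duplex whose 3'-most pair on a is (i, j)
    best = np.full((la, lb), math.inf)
    any_pair = False
    for i in range(la):
        for j in range(lb):
            pt = pair_type(a[i], b[j])
            if pt < 0:
                continue
            any_pair = True
            e = DUPLEX_INIT  # duplex starts here
            for p in range(max(0, i - MAX_INTERIOR_LOOP - 1), i):
                for q in range(j + 1, min(lb, j + MAX_INTERIOR_LOOP + 2)):
                    if not math.isfinite(best[p, q]):
                        continue
                    n1 = i - p - 1
                    n2 = q - j - 1
                    if n1 == 0 and n2 == 0:
                        pt_prev = pair_type(a[p], b[q])
                        loop = STACK[pt_prev, pt]
                    elif n1 + n2 <= MAX_INTERIOR_LOOP:
                        loop = internal_energy(n1, n2)
                    else:
                        continue
                    if best[p, q] + loop < e:
                        e = best[p, q] + loop
            best[i, j] = e
    if not any_pair:
        return None
    return float(best.min())


class NearestNeighborBackend:
    """Exact partition-function backend over the simplified NN model.

    Deterministic and memoized: ensemble free energies are cached per
    (sequence, constraint) so optimization loops that revisit sequences pay
    for each fold once.
    """

    name = "simplified-nn"
    capabilities = frozenset({"duplex", "ensemble", "constrained-ensemble"})

    def __init__(self, temperature: float = nnparams.T_KELVIN) -> None:
        if temperature <= 0:
            raise ValueError("temperature must be positive kelvin")
        self.temperature = temperature
        self._cache: dict[tuple[str, tuple[int, int] | None], float] = {}

    def ensemble_free_energy(
        self, rna: str, window: Window | None = None
    ) -> float:
        key = (rna, (window.start, window.length) if window else None)
        if key not in self._cache:
            mask = window.mask(len(rna)) if window is not None else None
            self._cache[key] = fold.ensemble_free_energy(
                rna, mask, temperature=self.temperature
            )
        return self._cache[key]

    def opening_energy(self, rna: str, window: Window) -> float:
        window.check(len(rna))
        value = self.ensemble_free_energy(rna, window) - self.ensemble_free_energy(rna)
        if value < -1e-9:
            raise AssertionError(
                f"opening energy {value} < 0: backend invariant violated"
            )
        return max(value, 0.0)

    def duplex_energy(self, a: str, b: str) -> Optional[float]:
        return duplex_energy_nn(a, b)


class ViennaRNABackend:
    """Reference-engine backend delegating to ViennaRNA's Python bindings.

    Uses hard constraints on a ``fold_compound`` for constrained ensembles
    and ``RNA.duplexfold`` for hybridization. Energies follow ViennaRNA's
    full Turner model, so they differ numerically from the simplified-nn
    backend; the contract (signs, ordering, nonnegativity of opening
    energies) is shared.
    """

    name = "reference-engine"
    capabilities = frozenset({"duplex", "ensemble", "constrained-ensemble"})

    def __init__(self, temperature: float = nnparams.T_KELVIN) -> None:
        import RNA  # deferred: optional engine

        self._rna = RNA
        self.temperature = temperature
        self._md = RNA.md()
        self._md.temperature = temperature - 273.15
        self._cache: dict[tuple[str, tuple[int, int] | None], float] = {}

    def ensemble_free_energy(self, rna: str, window: Window | None = None) -> float:
        key = (rna, (window.start, window.length) if window else None)
        if key not in self._cache:
            fc = self._rna.fold_compound(rna, self._md)
            if window is not None:
                window.check(len(rna))
                for pos in range(window.start, window.stop):  # 1-based API
                    fc.hc_add_up(pos + 1)
            _, energy = fc.pf()
            self._cache[key] = float(energy)
        return self._cache[key]

    def opening_energy(self, rna: str, window: Window) -> float:
        window.check(len(rna))
        value = self.ensemble_free_energy(rna, window) - self.ensemble_free_energy(rna)
        return max(value, 0.0)

    def duplex_energy(self, a: str, b: str) -> Optional[float]:
        if not a or not b:
            raise LengthError("duplex strands must be nonempty")
        if len(a) > MAX_DUPLEX_LENGTH or len(b) > MAX_DUPLEX_LENGTH:
            raise LengthError(f"duplex strands are bounded to {MAX_DUPLEX_LENGTH} nt")
        result = self._rna.duplexfold(a, b)
        if result.structure.count("(") == 0:
            return None
        return float(result.energy)


@runtime_checkable
class EnergyBackend(Protocol):
    name: str
    temperature: float

    def ensemble_free_energy(self, rna: str, window: Window | None = None) -> float: ...

    def opening_energy(self, rna: str, window: Window) -> float: ...

    def duplex_energy(self, a: str, b: str) -> Optional[float]: ...


_BACKENDS = {
    "simplified-nn": NearestNeighborBackend,
    "reference-engine": ViennaRNABackend,
}


def get_backend(name: str = "simplified-nn", temperature: float = nnparams.T_KELVIN):
    """Instantiate a backend by config name."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown energy backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return cls(temperature=temperature)
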