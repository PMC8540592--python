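"""The translation-initiation potential.

Initiation of a prokaryotic 30S complex on an mRNA is modeled by three
energies: the SD/anti-SD hybridization energy dE_SD, the start-codon /
initiator-tRNA stabilization dE_tRNA (a per-start-codon constant), and the
opening energy dE_open of the ~30-nt ribosome docking site (RDS) that must
be single-stranded for the ribosome to dock. The potential is the
Boltzmann-type score

    delta = exp(-(dE_SD + dE_tRNA + dE_open) / (R T))

so delta = 1 when the energies cancel and grows as initiation becomes more
favorable. Across constructs that share SD and start codon, ranking by
delta is exactly ranking by dE_open (descending delta = ascending dE_open).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .energy import EnergyBackend, NearestNeighborBackend, Window
from .errors import EmptyInputError, UnsupportedStartCodonError, WindowError
from .nnparams import R_KCAL, T_KELVIN
from .sequence import Construct, build_transcript

#: default anti-SD motif: 3'-tail of E. coli 16S rRNA read 5'->3'
DEFAULT_ANTI_SD = "ACCUCCUUA"


@dataclass(frozen=True)
class ScoreParameters:
    """All constants of the delta model.

    ``dE_tRNA_table`` keys are exactly the recognized start codons, values
    in kcal/mol. ``canonical_sd_offset`` is where a well-placed SD anchor
    sits relative to the start codon; ``scan_range`` is the inclusive
    interval of SD placements scanned by profiles.
    """

    R: float = R_KCAL
    T: float = T_KELVIN
    dE_tRNA_table: dict[str, float] = field(
        default_factory=lambda: {"AUG": -1.19, "GUG": -0.075}
    )
    rds_length: int = 30
    canonical_sd_offset: int = -11
    scan_range: tuple[int, int] = (-13, -5)
    anti_sd: str = DEFAULT_ANTI_SD

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")
        if self.rds_length < 1:
            raise ValueError("rds_length must be >= 1")
        if self.scan_range[0] > self.scan_range[1]:
            raise ValueError("scan_range must be (i_min, i_max) with i_min <= i_max")

    @property
    def rt(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class InitiationScore:
    """The delta score of one construct with its component energies."""

    construct_name: str
    dE_SD: float
    dE_tRNA: float
    dE_open: float
    delta: float
    sd_offset_used: int
    anti_sd: str
    sd_no_duplex: bool = False
    backend_name: str = "simplified-nn"


@dataclass(frozen=True)
class OpeningProfile:
    """dE_open(i) over a range of SD placements i (strictly increasing)."""

    construct_name: str
    offsets: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must have equal length")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("opening energies must be nonnegative")


_default_backend: NearestNeighborBackend | None = None


def default_backend() -> NearestNeighborBackend:
    """Shared memoizing default backend (folds are cached per sequence)."""
    global _default_backend
    if _default_backend is None:
        _default_backend = NearestNeighborBackend()
    return _default_backend


def delta_from_energies(total_energy: float, p: ScoreParameters) -> float:
    """delta = exp(-E/RT) for a total energy in kcal/mol."""
    return math.exp(-total_energy / p.rt)


def rds_window(c: Construct, p: ScoreParameters, sd_offset: int | None = None) -> Window:
    """The RDS window [i, i + rds_length) in transcript coordinates.

    Anchored at the SD anchor (5' end of the SD motif) and running
    ``rds_length`` nt downstream, covering SD, spacer, start codon and the
    proximal coding region.
    """
    i = c.sd_offset if sd_offset is None else sd_offset
    start = c.start_index + i
    window = Window(start, p.rds_length)
    try:
        window.check(len(c.transcript))
    except WindowError as exc:
        raise WindowError(f"RDS window at offset i={i}: {exc}") from exc
    return window


def delta_score(
    c: Construct,
    p: ScoreParameters | None = None,
    backend: EnergyBackend | None = None,
) -> InitiationScore:
    """Score one construct: components dE_SD, dE_tRNA, dE_open and delta.

    dE_SD comes from duplex hybridization of the construct's SD motif with
    the configured anti-SD (no possible duplex contributes 0 and is
    flagged); dE_tRNA from the start-codon table; dE_open from the opening
    energy of the RDS window anchored at the construct's SD offset.
    """
    p = p or ScoreParameters()
    backend = backend or default_backend()
    start_codon = c.cds.start_codon
    if start_codon not in p.dE_tRNA_table:
        raise UnsupportedStartCodonError(
            f"start codon {start_codon} has no dE_tRNA entry "
            f"(known: {sorted(p.dE_tRNA_table)})"
        )
    de_trna = p.dE_tRNA_table[start_codon]
    de_sd = backend.duplex_energy(c.sd_sequence, p.anti_sd)
    no_duplex = de_sd is None
    de_sd_val = 0.0 if no_duplex else float(de_sd)
    window = rds_window(c, p)
    de_open = backend.opening_energy(c.transcript, window)
    delta = delta_from_energies(de_sd_val + de_trna + de_open, p)
    return InitiationScore(
        construct_name=c.name,
        dE_SD=de_sd_val,
        dE_tRNA=de_trna,
        dE_open=de_open,
        delta=delta,
        sd_offset_used=c.sd_offset,
        anti_sd=p.anti_sd,
        sd_no_duplex=no_duplex,
        backend_name=backend.name,
    )


def open_energy_profile(
    c: Construct,
    i_min: int | None = None,
    i_max: int | None = None,
    p: ScoreParameters | None = None,
    backend: EnergyBackend | None = None,
) -> OpeningProfile:
    """dE_open(i) for every integer SD placement i in [i_min, i_max].

    Each value is computed on the full transcript, so both upstream and
    downstream context shape every window. Windows that do not fit raise a
    :class:`WindowError` naming the offending offset.
    """
    p = p or ScoreParameters()
    backend = backend or default_backend()
    if i_min is None:
        i_min = p.scan_range[0]
    if i_max is None:
        i_max = p.scan_range[1]
    if i_min > i_max:
        raise ValueError(f"i_min {i_min} > i_max {i_max}")
    transcript = c.transcript
    offsets = tuple(range(i_min, i_max + 1))
    values = []
    for i in offsets:
        window = rds_window(c, p, sd_offset=i)
        values.append(backend.opening_energy(transcript, window))
    return OpeningProfile(
        construct_name=c.name, offsets=offsets, values=tuple(values)
    )


def locate_minimum(
    profile: OpeningProfile, p: ScoreParameters | None = None
) -> tuple[int, float]:
    """Offset of the smallest dE_open(i) and its value.

    Exact ties break toward the offset closest to the canonical SD
    placement, then toward the more upstream (smaller) offset.
    """
    if not profile.offsets:
        raise EmptyInputError("empty opening profile")
    p = p or ScoreParameters()
    best = min(profile.values)
    candidates = [
        i for i, v in zip(profile.offsets, profile.values) if v == best
    ]
    i_star = min(candidates, key=lambda i: (abs(i - p.canonical_sd_offset), i))
    return i_star, best


@dataclass(frozen=True)
class RankEntry:
    """One row of a construct ranking; ``error`` set when scoring failed."""

    name: str
    score: InitiationScore | None = None
    error: str | None = None


def rank_constructs(
    constructs: list[Construct],
    p: ScoreParameters | None = None,
    backend: EnergyBackend | None = None,
) -> list[RankEntry]:
    """Rank constructs by descending delta (stable for exact ties).

    Constructs that fail to score are annotated and sorted last, preserving
    input order among themselves.
    """
    p = p or ScoreParameters()
    backend = backend or default_backend()
    entries: list[RankEntry] = []
    for c in constructs:
        try:
            entries.append(RankEntry(name=c.name, score=delta_score(c, p, backend)))
        except Exception as exc:  # noqa: BLE001 - annotated per construct
            entries.append(RankEntry(name=c.name, error=f"{type(exc).__name__}: {exc}"))
    scored = [e for e in entries if e.score is not None]
    failed = [e for e in entries if e.score is None]
    scored.sort(key=lambda e: -e.score.delta)  # stable: ties keep input order
    return scored + failed
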