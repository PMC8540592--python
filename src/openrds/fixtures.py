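"""Programmatic test fixtures with self-verifying manifests.

Every fixture that the test-suite and the examples rely on is generated
here from first principles — no downloads, no stored data files. Each
generator returns the construct(s) plus a *manifest* of machine-checkable
expectations; :func:`verify_fixture` recomputes and checks them all.

Fixture geometries (all frozen; offsets are relative to the start codon):

* ``unstructured`` — purine-only filler around an AUG start: the alphabet
  {A, G} plus the start codon's single U admits no helix of length >= 2,
  so the whole opening-energy profile is identically zero.
* ``hairpin-over-rds`` — a strong stem occluding the RDS plus two
  two-pair "marker" helices whose arms end exactly at the window edges of
  the engineered offset, making dE_open(i) peak strictly there.
* ``stem-ladder`` — constructs sharing UTR and SD whose only difference
  is a hairpin stem of increasing length inside the RDS window.
* ``toy-gene`` — a gene whose first six codons (all two-fold, wobble
  U<->C families; 64 synonymous combinations) base-pair with a 5'UTR
  segment: the annealer's standard small instance with an exact oracle.
* ``mini-genome`` — FASTA + GFF3 text for a two-contig genome carrying
  structured and unstructured start contexts on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .anneal import brute_force_optimum
from .energy import EnergyBackend
from .score import (
    OpeningProfile,
    ScoreParameters,
    default_backend,
    delta_score,
    open_energy_profile,
    rds_window,
)
from .sequence import CodingSequence, Construct, reverse_complement, translate

FIXTURE_KINDS = (
    "unstructured",
    "hairpin-over-rds",
    "stem-ladder",
    "toy-gene",
    "mini-genome",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    stem: int = 8
    stems: tuple[int, ...] = (0, 4, 8)
    utr_length: int = 20
    codon_count: int = 12
    seed: int = 20210741

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; one of {FIXTURE_KINDS}")


@dataclass(frozen=True)
class Fixture:
    spec: FixtureSpec
    constructs: tuple[Construct, ...]
    manifest: dict[str, Any] = field(default_factory=dict)
    genome_fasta: str | None = None
    genome_gff3: str | None = None


def unstructured_construct(
    utr_length: int = 20, codon_count: int = 12, name: str = "unstructured"
) -> Construct:
    """A construct with no possible helix: all-zero opening profile."""
    if utr_length < 15:
        raise ValueError("unstructured fixture needs a UTR of >= 15 nt")
    sd = "AGGAGG"
    # SD anchored at -11; purine filler elsewhere
    utr = "A" * (utr_length - 11) + sd + "A" * 5
    cds = "AUG" + "AAA" * (codon_count - 1)
    return Construct(name, utr, CodingSequence(cds), sd_sequence=sd, sd_offset=-11)


#: arm sequence of the strong RDS hairpin (5'->3' on the coding side)
_HAIRPIN_ARM = "GCGGCUGC"


def hairpin_construct(stem: int = 8, name: str = "hairpin-over-rds") -> Construct:
    """A construct whose dE_open(i) peaks strictly at i = -11.

    A stem of ``stem`` pairs (arms at [-stem, -1] and [+3, +3+stem)) loops
    over the start codon and is opened by every scanned window; two 2-pair
    marker helices with arms ending at [-12, -11] and [+18, +19] (partners
    outside every scanned window) are opened only by windows with
    i <= -11 and i >= -11 respectively, so the profile maximum sits
    exactly at the canonical offset.
    """
    if not 4 <= stem <= len(_HAIRPIN_ARM):
        raise ValueError(f"stem must be in [4, {len(_HAIRPIN_ARM)}]")
    arm2 = _HAIRPIN_ARM[:stem]
    arm1 = reverse_complement(arm2)
    utr = {pos: "A" for pos in range(-22, 0)}
    utr[-18], utr[-17] = "G", "C"  # marker L partner
    utr[-12], utr[-11] = "G", "C"  # marker L arm (pairs (-18,-11), (-17,-12))
    for k, pos in enumerate(range(-stem, 0)):
        utr[pos] = arm1[k]
    utr_s = "".join(utr[pos] for pos in range(-22, 0))
    cds = list("AUG" + arm2 + "A" * (33 - 3 - stem))
    cds[18], cds[19] = "G", "C"  # marker R arm (pairs (18,26), (19,25))
    cds[25], cds[26] = "G", "C"  # marker R partner
    cds_s = "".join(cds)
    c = Construct(
        name, utr_s, CodingSequence(cds_s), sd_sequence=utr_s[11:17], sd_offset=-11
    )
    translate(c.cds)  # no internal stop by construction; assert anyway
    return c


def stem_ladder(stems: tuple[int, ...] = (0, 4, 8)) -> tuple[Construct, ...]:
    """Constructs sharing UTR filler and SD, differing only in stem length."""
    out = []
    for s in stems:
        if not 0 <= s <= len(_HAIRPIN_ARM):
            raise ValueError(f"stem {s} outside [0, {len(_HAIRPIN_ARM)}]")
        arm2 = _HAIRPIN_ARM[:s]
        arm1 = reverse_complement(arm2)
        utr = ["A"] * 20
        for k, pos in enumerate(range(-s, 0)):
            utr[20 + pos] = arm1[k]
        utr_s = "".join(utr)
        cds = "AUG" + arm2 + "A" * (30 - 3 - s)
        out.append(
            Construct(
                f"stem-{s}",
                utr_s,
                CodingSequence(cds),
                sd_sequence="AAAAAA",
                sd_offset=-16,
            )
        )
    return tuple(out)


#: wild-type mutable codons of the toy gene: two-fold wobble families only
_TOY_CODONS = ("GAU", "AAU", "UAU", "CAU", "GAU", "UUU")


def toy_gene() -> Construct:
    """A small optimizer instance: 64 synonymous combinations, known oracle.

    The first six coding codons pair with a complementary 5'UTR segment
    (partner placed upstream of every scanned window), so the wild type is
    strongly occluded and wobble choices control the opening energy.
    """
    cds = "AUG" + "".join(_TOY_CODONS) + "AAA" * 3
    partner = reverse_complement(cds[3:21])
    utr = ["A"] * 30
    for k in range(len(partner)):
        utr[1 + k] = partner[k]  # rel positions [-29, -12]
    utr_s = "".join(utr)
    return Construct(
        "toy-gene", utr_s, CodingSequence(cds), sd_sequence=utr_s[:6], sd_offset=-30
    )


def _structured_context(flank_up: int, flank_down: int) -> str:
    """A start context with a strong hairpin looping over the start codon."""
    c = hairpin_construct(stem=8)
    pad_up = flank_up - len(c.utr5)
    pad_down = flank_down - len(c.cds.rna)
    if pad_up < 0 or pad_down < 0:
        raise ValueError("flanks too short for the structured context")
    return "A" * pad_up + c.transcript + "A" * pad_down


def _unstructured_context(flank_up: int, flank_down: int) -> str:
    c = unstructured_construct()
    pad_up = flank_up - len(c.utr5)
    pad_down = flank_down - len(c.cds.rna)
    if pad_up < 0 or pad_down < 0:
        raise ValueError("flanks too short for the unstructured context")
    return "A" * pad_up + c.transcript + "A" * pad_down


def mini_genome(
    flank_up: int = 30, flank_down: int = 40, spacer: int = 12
) -> tuple[str, str, dict[str, Any]]:
    """Synthetic genome FASTA + GFF3 with known start contexts.

    Contig ``chrA`` carries an unstructured gene on the plus strand and the
    *same* gene reverse-complemented on the minus strand (strand-correctness
    oracle); contig ``chrB`` carries a structured (hairpin) start context on
    each strand. Returns ``(fasta_text, gff3_text, expectations)``.
    """
    ctx_u = _unstructured_context(flank_up, flank_down)[: flank_up + flank_down]
    ctx_s = _structured_context(flank_up, flank_down)[: flank_up + flank_down]
    pad = "A" * spacer

    def contig(ctx: str) -> tuple[str, int, int]:
        """[pad][ctx][pad][revcomp(ctx)][pad]; returns seq + the two start positions."""
        seq = pad + ctx + pad + reverse_complement(ctx) + pad
        plus_start0 = spacer + flank_up  # 0-based first nt of start codon
        # minus-strand gene: start codon's first nt maps to the *last* base of
        # the revcomp of the codon within the second block
        block2 = spacer + len(ctx) + spacer
        minus_start0 = block2 + (len(ctx) - flank_up) - 1
        return seq, plus_start0, minus_start0

    seq_a, a_plus, a_minus = contig(ctx_u)
    seq_b, b_plus, b_minus = contig(ctx_s)

    def fasta_wrap(name: str, seq: str) -> str:
        lines = [f">{name}"]
        for k in range(0, len(seq), 60):
            lines.append(seq[k : k + 60])
        return "\n".join(lines) + "\n"

    fasta = fasta_wrap("chrA", seq_a) + fasta_wrap("chrB", seq_b)
    cds_len = 30

    def gff_line(seqid, fid, start0, strand):
        if strand == "+":
            start, end = start0 + 1, start0 + cds_len
        else:
            start, end = start0 + 1 - cds_len + 1, start0 + 1
        return (
            f"{seqid}\tsynthetic\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
            f"ID=cds-{fid};Parent={fid}\n"
        )

    gff = "##gff-version 3\n"
    gff += gff_line("chrA", "geneU-plus", a_plus, "+")
    gff += gff_line("chrA", "geneU-minus", a_minus, "-")
    gff += gff_line("chrB", "geneS-plus", b_plus, "+")
    gff += gff_line("chrB", "geneS-minus", b_minus, "-")
    expectations = {
        "n_records": 4,
        "strand_pairs": [["geneU-plus", "geneU-minus"], ["geneS-plus", "geneS-minus"]],
        "structured_genes": ["geneS-plus", "geneS-minus"],
        "unstructured_genes": ["geneU-plus", "geneU-minus"],
    }
    return fasta, gff, expectations


def generate_fixture(
    spec: FixtureSpec,
    p: ScoreParameters | None = None,
    backend: EnergyBackend | None = None,
) -> Fixture:
    """Build a fixture and its expected-property manifest.

    Manifest entries are machine-checkable: expected numbers are computed
    at generation time with the energy backend (and, for the toy gene, the
    brute-force oracle), never hard-coded.
    """
    p = p or ScoreParameters()
    backend = backend or default_backend()
    if spec.kind == "unstructured":
        c = unstructured_construct(spec.utr_length, spec.codon_count)
        manifest = {"profile_all_zero": True, "scan_range": list(p.scan_range)}
        return Fixture(spec, (c,), manifest)
    if spec.kind == "hairpin-over-rds":
        c = hairpin_construct(spec.stem)
        prof = open_energy_profile(c, p=p, backend=backend)
        manifest = {
            "engineered_offset": -11,
            "argmax_offset": int(prof.offsets[prof.values.index(max(prof.values))]),
            "dE_open_at_engineered": prof.values[prof.offsets.index(-11)],
        }
        return Fixture(spec, (c,), manifest)
    if spec.kind == "stem-ladder":
        cs = stem_ladder(spec.stems)
        values = [
            backend.opening_energy(c.transcript, rds_window(c, p)) for c in cs
        ]
        manifest = {
            "stems": list(spec.stems),
            "dE_open_values": values,
            "strictly_increasing": all(a < b for a, b in zip(values, values[1:])),
        }
        return Fixture(spec, cs, manifest)
    if spec.kind == "toy-gene":
        c = toy_gene()
        best_cds, best_e = brute_force_optimum(c, (1, 7), p, backend)
        initial = backend.opening_energy(c.transcript, rds_window(c, p))
        manifest = {
            "region": [1, 7],
            "search_space": 64,
            "initial_dE_open": initial,
            "optimum_dE_open": best_e,
            "optimum_cds": best_cds.rna,
        }
        return Fixture(spec, (c,), manifest)
    # mini-genome
    fasta, gff, expectations = mini_genome()
    return Fixture(spec, (), expectations, genome_fasta=fasta, genome_gff3=gff)


def verify_fixture(
    fix: Fixture,
    p: ScoreParameters | None = None,
    backend: EnergyBackend | None = None,
) -> dict[str, bool]:
    """Recompute every manifest expectation; True per satisfied check."""
    p = p or ScoreParameters()
    backend = backend or default_backend()
    checks: dict[str, bool] = {}
    kind = fix.spec.kind
    if kind == "unstructured":
        prof = open_energy_profile(fix.constructs[0], p=p, backend=backend)
        checks["profile_all_zero"] = all(v == 0.0 for v in prof.values)
    elif kind == "hairpin-over-rds":
        prof = open_energy_profile(fix.constructs[0], p=p, backend=backend)
        argmax = prof.offsets[prof.values.index(max(prof.values))]
        checks["argmax_at_engineered"] = argmax == fix.manifest["engineered_offset"]
        checks["positive_at_engineered"] = (
            prof.values[prof.offsets.index(fix.manifest["engineered_offset"])] > 0
        )
    elif kind == "stem-ladder":
        values = [
            backend.opening_energy(c.transcript, rds_window(c, p))
            for c in fix.constructs
        ]
        checks["strictly_increasing"] = all(
            a < b for a, b in zip(values, values[1:])
        )
        checks["matches_manifest"] = all(
            abs(a - b) < 1e-9 for a, b in zip(values, fix.manifest["dE_open_values"])
        )
    elif kind == "toy-gene":
        c = fix.constructs[0]
        best_cds, best_e = brute_force_optimum(
            c, tuple(fix.manifest["region"]), p, backend
        )
        checks["optimum_reproducible"] = (
            best_cds.rna == fix.manifest["optimum_cds"]
            and abs(best_e - fix.manifest["optimum_dE_open"]) < 1e-9
        )
        checks["optimum_below_initial"] = best_e < fix.manifest["initial_dE_open"]
        checks["protein_preserved"] = (
            translate(best_cds).residues == translate(c.cds).residues
        )
    elif kind == "mini-genome":
        from .genome import extract_start_windows  # local import: optional path
        import tempfile, os

        with tempfile.TemporaryDirectory() as tmp:
            fa = os.path.join(tmp, "genome.fa")
            gf = os.path.join(tmp, "genes.gff3")
            with open(fa, "w") as fh:
                fh.write(fix.genome_fasta)
            with open(gf, "w") as fh:
                fh.write(fix.genome_gff3)
            sws = extract_start_windows(fa, gf, flank_up=30, flank_down=40)
        checks["n_records"] = len(sws.records) == fix.manifest["n_records"]
        by_id = {r.gene_id: r for r in sws.records}
        checks["strand_pairs_identical"] = all(
            by_id[a].context == by_id[b].context
            for a, b in fix.manifest["strand_pairs"]
        )
        checks["all_aug_starts"] = all(
            r.start_codon == "AUG" for r in sws.records
        )
    return checks
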