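"""File formats: FASTA, construct descriptors, TSV profiles, JSON reports.

FASTA is read and written through Biopython (wrapped at 60 columns, RNA
alphabet on output; both T and U accepted on input). Construct descriptors
are flat ``key = value`` text files; unknown keys are errors, not
warnings. TSV tables carry a header row and use '.' for missing values;
JSON reports are schema-versioned and embed a provenance block.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .anneal import OptimizationResult
from .errors import ConfigError
from .score import InitiationScore, OpeningProfile, ScoreParameters
from .sequence import CodingSequence, Construct, normalize_to_rna

SCHEMA_VERSION = 1


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{id: RNA sequence}`` (normalized)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_to_rna(str(rec.seq))
    return out


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write sequences as 60-column wrapped FASTA (U, not T)."""
    seq_records = [
        SeqRecord(Seq(normalize_to_rna(seq)), id=name, description="")
        for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_CONSTRUCT_KEYS = {
    "name",
    "utr5",
    "cds",
    "transcript",
    "start_index",
    "sd_sequence",
    "sd_offset",
}


def parse_construct_config(text: str) -> Construct:
    """Parse a flat ``key = value`` construct descriptor.

    Either ``utr5`` + ``cds`` or ``transcript`` + ``start_index`` define the
    sequence; ``sd_sequence`` and ``sd_offset`` are always required.
    Unknown keys raise :class:`ConfigError`.
    """
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _CONSTRUCT_KEYS:
            raise ConfigError(f"line {lineno}: unknown construct key {key!r}")
        values[key] = val
    for required in ("name", "sd_sequence", "sd_offset"):
        if required not in values:
            raise ConfigError(f"missing construct key {required!r}")
    if "transcript" in values:
        if "start_index" not in values:
            raise ConfigError("'transcript' requires 'start_index'")
        transcript = normalize_to_rna(values["transcript"])
        start = int(values["start_index"])
        utr5, cds = transcript[:start], transcript[start:]
    elif "utr5" in values and "cds" in values:
        utr5, cds = values["utr5"], values["cds"]
    else:
        raise ConfigError("need either utr5+cds or transcript+start_index")
    return Construct(
        name=values["name"],
        utr5=utr5,
        cds=CodingSequence(cds),
        sd_sequence=values["sd_sequence"],
        sd_offset=int(values["sd_offset"]),
    )


def load_construct(path: str | Path) -> Construct:
    return parse_construct_config(Path(path).read_text())


def write_construct_config(c: Construct, path: str | Path) -> None:
    Path(path).write_text(
        f"name = {c.name}\n"
        f"utr5 = {c.utr5}\n"
        f"cds = {c.cds.rna}\n"
        f"sd_sequence = {c.sd_sequence}\n"
        f"sd_offset = {c.sd_offset}\n"
    )


def provenance(p: ScoreParameters, backend_name: str, seed: int | None = None) -> dict:
    prov: dict[str, Any] = {
        "tool": "openrds",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "backend": backend_name,
        "parameters": {
            "R_kcal_per_mol_K": p.R,
            "T_kelvin": p.T,
            "dE_tRNA_table": p.dE_tRNA_table,
            "rds_length_nt": p.rds_length,
            "canonical_sd_offset": p.canonical_sd_offset,
            "scan_range": list(p.scan_range),
            "anti_sd": p.anti_sd,
        },
    }
    if seed is not None:
        prov["seed"] = seed
    return prov


def profiles_to_frame(profiles: Iterable[OpeningProfile]) -> pd.DataFrame:
    rows = [
        {"construct": prof.construct_name, "i": i, "dE_open_kcal_mol": v}
        for prof in profiles
        for i, v in zip(prof.offsets, prof.values)
    ]
    return pd.DataFrame(rows, columns=["construct", "i", "dE_open_kcal_mol"])


def write_profile_tsv(
    profiles: Iterable[OpeningProfile],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    frame = profiles_to_frame(profiles)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep=".")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."])


def score_report(
    scores: Iterable[InitiationScore],
    p: ScoreParameters,
    backend_name: str,
    seed: int | None = None,
) -> dict:
    return {
        "provenance": provenance(p, backend_name, seed),
        "constructs": [dataclasses.asdict(s) for s in scores],
    }


def optimization_report(
    result: OptimizationResult,
    p: ScoreParameters,
    backend_name: str,
) -> dict:
    return {
        "provenance": provenance(p, backend_name, result.seed_used),
        "construct": result.optimized.name,
        "region_codons": list(result.region),
        "initial_dE_open_kcal_mol": result.initial_dE_open,
        "final_dE_open_kcal_mol": result.final_dE_open,
        "n_mutations": len(result.mutations),
        "mutations": [m.c_notation for m in result.mutations],
        "no_feasible_move": result.no_feasible_move,
        "optimized_cds": result.optimized.cds.rna,
        "final_delta": result.final_score.delta if result.final_score else None,
    }


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
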