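"""File formats and run headers.

FASTA (via Biopython), Vienna dot-bracket blocks, CT files, and the single
tabular dialect used throughout: tab-separated UTF-8 with '.' decimals,
preceded by '#' header lines recording tool version, a digest of the run
configuration, and the seed — so any output file identifies the run that
produced it and reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .sequences import RnaSequence, SequenceError
from .structure import SecondaryStructure


def read_fasta(path) -> list[RnaSequence]:
    """Read a multi-record FASTA; residues normalized (T->U, uppercase).

    Raises on an empty file, duplicate ids, or illegal residues (the error
    names the offending record and position).
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(RnaSequence(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, sequences: list[RnaSequence]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences],
        str(path),
        "fasta",
    )


def format_vienna(seq: RnaSequence, structure: SecondaryStructure, delta_g: float) -> str:
    """Vienna block: '>id', sequence line, structure line with trailing energy."""
    return f">{seq.id}\n{seq.residues}\n{structure.dotbracket} ({delta_g:.2f})\n"


def config_digest(config: dict) -> str:
    """Short stable digest of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_header(config: dict, seed: int | None) -> str:
    lines = [
        f"# rnaplast {__version__}",
        f"# config_digest {config_digest(config)}",
        f"# seed {seed if seed is not None else 'none'}",
    ]
    return "\n".join(lines) + "\n"


def write_tsv(path, frame: pd.DataFrame, config: dict, seed: int | None) -> None:
    """Write a DataFrame as headered TSV ('.' decimals, UTF-8)."""
    buf = _io.StringIO()
    buf.write(run_header(config, seed))
    frame.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
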