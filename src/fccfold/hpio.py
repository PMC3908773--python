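"""Sequence readers and structure/report writers.

HP sequences are read either from plain text (one sequence per line,
``#`` comments allowed) or FASTA records.  Conformations are written as
comma-separated label strings, TSV coordinate tables, or a minimal
xyz-style CA trace (one pseudo-atom per residue: C for H, N for P) that
external molecular viewers can display.
"""

from __future__ import annotations

import io
import json
from typing import TextIO

from Bio import SeqIO

from .conformation import Conformation, validate_hp_sequence


def read_hp_sequences(handle: TextIO) -> list[tuple[str, str]]:
    """(name, sequence) pairs from plain text or FASTA.

    The format is sniffed from the first non-blank character: ``>`` means
    FASTA.  Plain-text sequences are named line1, line2, ...
    """
    text = handle.read()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        records = SeqIO.parse(io.StringIO(text), "fasta")
        return [(rec.id, validate_hp_sequence(str(rec.seq))) for rec in records]
    out = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if line:
            out.append((f"line{i}", validate_hp_sequence(line)))
    return out


def write_label_string(c: Conformation) -> str:
    return c.label_string()


def write_coords_tsv(c: Conformation, s: str | None = None) -> str:
    """TSV with residue index, optional H/P type, and x, y, z."""
    lines = ["index\tresidue\tx\ty\tz"]
    for i, (x, y, z) in enumerate(c.coords):
        res = s[i] if s is not None else "."
        lines.append(f"{i}\t{res}\t{x}\t{y}\t{z}")
    return "\n".join(lines) + "\n"


def write_xyz(c: Conformation, s: str, comment: str = "FCC HP conformation") -> str:
    """xyz-format CA trace: element C for H residues, N for P."""
    lines = [str(len(c.coords)), comment]
    for res, (x, y, z) in zip(s, c.coords):
        element = "C" if res == "H" else "N"
        lines.append(f"{element} {x:.3f} {y:.3f} {z:.3f}")
    return "\n".join(lines) + "\n"


def report_json(
    name: str,
    sequence: str,
    best_contacts: int,
    mean_contacts: float,
    best_labels: str,
    best_coords: list,
    config: dict,
    seeds: list[int],
) -> str:
    return json.dumps(
        {
            "name": name,
            "sequence": sequence,
            "best_contacts": best_contacts,
            "best_energy": -best_contacts,
            "mean_contacts_over_restarts": mean_contacts,
            "best_labels": best_labels,
            "best_coords": best_coords,
            "config": config,
            "seeds": seeds,
        },
        indent=2,
    )
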