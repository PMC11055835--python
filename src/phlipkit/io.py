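"""FASTA input/output for peptide sets.

Peptides travel as single-letter amino-acid FASTA records. The description
line carries modification flags as ``key=value`` tokens, e.g.::

    >YJL-4 c_amide=1 n_mod_mass=0.0
    ACDDQNPWARYADLLFPTDTLLLDL
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import Peptide, parse_peptide

__all__ = ["read_peptides", "write_peptides"]


def _parse_tokens(description: str) -> dict[str, str]:
    tokens: dict[str, str] = {}
    for part in description.split()[1:]:  # first token is the id
        if "=" in part:
            key, _, val = part.partition("=")
            tokens[key] = val
    return tokens


def read_peptides(path: str | Path) -> list[Peptide]:
    """Read a (multi-)FASTA file of peptides with modification tokens."""
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        tokens = _parse_tokens(record.description)
        peptides.append(
            parse_peptide(
                str(record.seq),
                id=record.id,
                c_amide=tokens.get("c_amide", "0") in ("1", "true", "True"),
                n_mod_mass=float(tokens.get("n_mod_mass", "0")),
            )
        )
    return peptides


def write_peptides(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides to FASTA, encoding modification flags as tokens."""
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.id,
            description=f"c_amide={int(p.c_terminal_amide)} n_mod_mass={p.n_terminal_mod_mass}",
        )
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")
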