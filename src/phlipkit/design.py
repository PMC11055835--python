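"""Template-assisted consensus design from an aligned peptide family.

The design procedure that produced YJL-4: tabulate per-position residue
frequencies over a family of equal-length membrane-insertion segments,
take the most frequent residue at each position, then apply a substitution
policy. The default policy replaces every consensus Glu with Asp, because
Glu side chains hydrogen-bond to membrane cholesterol and slow clearance
of unbound tracer, whereas Asp retains the pH-triggered protonation that
drives membrane insertion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .seqcore import AMINO_ACIDS, DescriptorSet, Peptide, PeptideError, describe

__all__ = [
    "AlignedFamily",
    "FrequencyMatrix",
    "DesignPolicy",
    "DesignReport",
    "frequency_matrix",
    "consensus",
    "design_report",
]


@dataclass(frozen=True)
class AlignedFamily:
    """Two or more equal-length, gap-free peptides treated as pre-aligned."""

    members: tuple[Peptide, ...]
    alignment_note: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise PeptideError("an aligned family needs at least 2 members")
        lengths = {len(m) for m in self.members}
        if len(lengths) > 1:
            bad = [m.id for m in self.members if len(m) != len(self.members[0])]
            raise PeptideError(
                f"family members differ in length (offending: {bad}); "
                "families must be pre-aligned equal-length blocks"
            )
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def length(self) -> int:
        return len(self.members[0])

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position residue counts and normalized frequencies."""

    length: int
    counts: tuple[Mapping[str, int], ...]
    n_members: int

    def frequency(self, position: int, residue: str) -> float:
        """Frequency of ``residue`` at 1-based ``position``."""
        return self.counts[position - 1].get(residue, 0) / self.n_members

    def to_frame(self) -> pd.DataFrame:
        """Frequencies as a DataFrame: rows = positions (1-based), cols = residues."""
        data = {
            aa: [col.get(aa, 0) / self.n_members for col in self.counts]
            for aa in AMINO_ACIDS
        }
        return pd.DataFrame(data, index=pd.RangeIndex(1, self.length + 1, name="position"))


@dataclass(frozen=True)
class DesignPolicy:
    """Residue substitutions plus a deterministic tie-break rule.

    The default substitutes Asp for Glu after consensus selection; the only
    tie-break implemented is ``"lexicographic"`` (smallest one-letter code
    wins, applied before substitution).
    """

    substitutions: Mapping[str, str] = field(default_factory=lambda: {"E": "D"})
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        for k, v in self.substitutions.items():
            if k not in AMINO_ACIDS or v not in AMINO_ACIDS:
                raise ValueError(f"non-canonical substitution {k!r} -> {v!r}")
        if self.tie_break != "lexicographic":
            raise ValueError(f"unknown tie-break rule {self.tie_break!r}")
        object.__setattr__(self, "substitutions", dict(self.substitutions))


def frequency_matrix(family: AlignedFamily) -> FrequencyMatrix:
    """Exact per-position residue counts for an aligned family."""
    cols: list[dict[str, int]] = [dict() for _ in range(family.length)]
    for member in family.members:
        for i, res in enumerate(member.sequence):
            cols[i][res] = cols[i].get(res, 0) + 1
    return FrequencyMatrix(
        length=family.length,
        counts=tuple(cols),
        n_members=len(family),
    )


def consensus(matrix: FrequencyMatrix, policy: DesignPolicy | None = None) -> Peptide:
    """Most-frequent residue per position, tie-broken and substituted.

    Ties are resolved lexicographically by one-letter code, then the policy
    substitution map is applied residue-wise — so an E-dominant column
    yields D under the default policy even if D never occurs there.
    """
    if policy is None:
        policy = DesignPolicy()
    residues = []
    for col in matrix.counts:
        best = min(sorted(col), key=lambda r: -col[r])  # max count, lexicographic ties
        residues.append(policy.substitutions.get(best, best))
    return Peptide(id="consensus", sequence="".join(residues))


@dataclass(frozen=True)
class DesignReport:
    """Frequency matrix + consensus peptide + its descriptors."""

    matrix: FrequencyMatrix
    consensus: Peptide
    descriptors: DescriptorSet

    def to_json(self) -> str:
        return json.dumps(
            {
                "consensus": self.consensus.sequence,
                "n_members": self.matrix.n_members,
                "length": self.matrix.length,
                "descriptors": self.descriptors.rounded(),
            },
            indent=2,
        )


def design_report(
    family: AlignedFamily, policy: DesignPolicy | None = None
) -> DesignReport:
    """Run the full design step: matrix, consensus, descriptor bundle."""
    matrix = frequency_matrix(family)
    cons = consensus(matrix, policy)
    return DesignReport(matrix=matrix, consensus=cons, descriptors=describe(cons))
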