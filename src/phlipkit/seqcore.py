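"""Peptide representation, property scales, and whole-sequence descriptors.

The descriptors implemented here are the standard ProtParam-style
quantities used to characterize short peptides such as pH (low) insertion
peptides (pHLIPs): net side-chain charge, grand average of hydropathicity
(GRAVY, Kyte-Doolittle), the Guruprasad instability index, and average
molecular mass with optional terminal modifications (C-terminal amide,
N-terminal adduct such as a radiometal chelator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "AMINO_ACIDS",
    "WATER_MASS",
    "AMIDATION_DELTA",
    "Peptide",
    "PropertyScale",
    "DescriptorSet",
    "load_scale",
    "parse_peptide",
    "net_charge",
    "gravy",
    "instability_index",
    "average_mass",
    "hydropathy_profile",
    "describe",
]

#: The 20 canonical amino-acid one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Average mass of one water molecule (Da), added once per chain.
WATER_MASS: float = 18.0153

#: Mass lost when the C-terminal carboxylic acid is amidated (-OH -> -NH2).
AMIDATION_DELTA: float = 0.98476


class PeptideError(ValueError):
    """Raised for invalid sequences or descriptor preconditions."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with terminal-modification flags.

    Parameters
    ----------
    id : str
        Short label for the peptide.
    sequence : str
        Residues from the 20-letter alphabet, stored upper-case.
    c_terminal_amide : bool
        True if the C-terminus is amidated (``-NH2``) rather than a free acid.
    n_terminal_mod_mass : float
        Average mass (Da, >= 0) of an N-terminal adduct, e.g. a chelator.
        Zero for an unmodified N-terminus.
    """

    id: str
    sequence: str
    c_terminal_amide: bool = False
    n_terminal_mod_mass: float = 0.0

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        if not seq:
            raise PeptideError("empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in AMINO_ACIDS:
                raise PeptideError(
                    f"illegal residue {ch!r} at position {pos} in {self.id!r}"
                )
        if self.n_terminal_mod_mass < 0:
            raise PeptideError("n_terminal_mod_mass must be >= 0")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequence)


@dataclass(frozen=True)
class PropertyScale:
    """An immutable named per-residue or per-dipeptide value table."""

    name: str
    kind: str  # "per-residue" | "per-dipeptide"
    values: Mapping[str, float]
    reference: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("per-residue", "per-dipeptide"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        expected = 20 if self.kind == "per-residue" else 400
        keys = set(self.values)
        if self.kind == "per-residue":
            wanted = set(AMINO_ACIDS)
        else:
            wanted = {a + b for a in AMINO_ACIDS for b in AMINO_ACIDS}
        if keys != wanted:
            raise ValueError(
                f"scale {self.name!r} must define exactly {expected} entries; "
                f"missing {sorted(wanted - keys)[:5]}, extra {sorted(keys - wanted)[:5]}"
            )
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def __getitem__(self, key: str) -> float:
        return self.values[key]


_SCALE_CACHE: dict[str, PropertyScale] = {}


def load_scale(name: str, path: str | Path | None = None) -> PropertyScale:
    """Load a named scale from the packaged ``scales/`` directory.

    Scale files are plain text: ``# name:``, ``# kind:`` and ``# reference:``
    header lines followed by tab-separated ``key<TAB>value`` rows. Loading
    the same name twice returns the identical cached object.
    """
    if path is None and name in _SCALE_CACHE:
        return _SCALE_CACHE[name]
    if path is None:
        ref = resources.files("phlipkit") / "scales" / f"{name}.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    meta: dict[str, str] = {}
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
            continue
        key, val = line.split("\t")
        values[key] = float(val)
    if "reference" not in meta:
        raise ValueError(f"scale file for {name!r} lacks a '# reference:' header")
    scale = PropertyScale(
        name=meta.get("name", name),
        kind=meta.get("kind", "per-residue"),
        values=values,
        reference=meta["reference"],
    )
    if path is None:
        _SCALE_CACHE[name] = scale
    return scale


def parse_peptide(
    raw: str,
    id: str = "peptide",
    c_amide: bool = False,
    n_mod_mass: float = 0.0,
) -> Peptide:
    """Parse a raw string into a validated, case-normalized :class:`Peptide`.

    Whitespace is stripped; residues outside the 20-letter alphabet raise
    :class:`PeptideError` naming the offending position and character.
    """
    return Peptide(
        id=id,
        sequence=raw,
        c_terminal_amide=c_amide,
        n_terminal_mod_mass=n_mod_mass,
    )


def net_charge(p: Peptide) -> int:
    """Formal net side-chain charge at neutral pH.

    Counts Arg/Lys as +1 and Asp/Glu as -1; His and the termini contribute
    nothing. This side-chain-only convention is the one used by helix-design
    tools such as HeliQuest for short peptides.
    """
    scale = load_scale("side_chain_charge")
    return int(sum(scale[r] for r in p))


def gravy(p: Peptide) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value.

    Negative values indicate a polar/hydrophilic peptide. Terminal
    modifications do not enter the computation.
    """
    scale = load_scale("kyte_doolittle")
    return sum(scale[r] for r in p) / len(p)


def instability_index(p: Peptide) -> float:
    """Guruprasad instability index.

    ``(10 / L) * sum(DIWV(s[i], s[i+1]))`` over the ``L - 1`` consecutive
    dipeptides, using the published 400-entry dipeptide instability weight
    value (DIWV) table. Values below 40 conventionally classify a peptide
    as stable in vitro.
    """
    if len(p) < 2:
        raise PeptideError("instability index undefined below 2 residues")
    diwv = load_scale("guruprasad_diwv")
    s = p.sequence
    total = sum(diwv[s[i : i + 2]] for i in range(len(s) - 1))
    return 10.0 / len(s) * total


def average_mass(p: Peptide) -> float:
    """Average (not monoisotopic) molecular mass in daltons.

    Sum of residue average masses plus one water, minus the amidation delta
    if the C-terminus is an amide, plus any N-terminal adduct mass (e.g. a
    NOTA-type chelator supplied by the caller; no adduct is assumed).
    """
    scale = load_scale("residue_average_mass")
    mass = sum(scale[r] for r in p) + WATER_MASS
    if p.c_terminal_amide:
        mass -= AMIDATION_DELTA
    return mass + p.n_terminal_mod_mass


def hydropathy_profile(
    p: Peptide,
    window: int = 9,
    scale: PropertyScale | None = None,
) -> list[tuple[int, float]]:
    """ProtScale-style sliding-window profile.

    Returns ``L - window + 1`` entries of ``(center_position, mean_value)``
    with 1-based window-center positions. No edge padding is applied, so
    the output is shorter than the input. ``window`` must be odd and at
    most the sequence length.
    """
    if scale is None:
        scale = load_scale("kyte_doolittle")
    L = len(p)
    if window < 1 or window % 2 == 0:
        raise PeptideError(f"window must be an odd positive integer, got {window}")
    if window > L:
        raise PeptideError(f"window {window} exceeds sequence length {L}")
    vals = [scale[r] for r in p]
    half = window // 2
    out: list[tuple[int, float]] = []
    for start in range(L - window + 1):
        center = start + half + 1  # 1-based
        out.append((center, math.fsum(vals[start : start + window]) / window))
    return out


@dataclass(frozen=True)
class DescriptorSet:
    """Whole-sequence descriptor bundle for one peptide.

    ``insertion_hydrophobicity`` and ``insertion_moment`` describe the
    C-terminal membrane-insertion window (see :mod:`phlipkit.helix`); they
    are None for peptides shorter than that window.
    """

    id: str
    sequence: str
    length: int
    net_charge: int
    gravy: float
    instability_index: float
    average_mass: float
    insertion_hydrophobicity: float | None = None
    insertion_moment: float | None = None

    def rounded(self) -> dict[str, object]:
        """Report-precision view: 2 decimals for instability, 3 elsewhere."""
        return {
            "id": self.id,
            "sequence": self.sequence,
            "length": self.length,
            "net_charge": self.net_charge,
            "instability_index": round(self.instability_index, 2),
            "gravy": round(self.gravy, 3),
            "average_mass": round(self.average_mass, 2),
            "insertion_hydrophobicity": (
                None
                if self.insertion_hydrophobicity is None
                else round(self.insertion_hydrophobicity, 3)
            ),
            "insertion_moment": (
                None
                if self.insertion_moment is None
                else round(self.insertion_moment, 3)
            ),
        }


def describe(p: Peptide, insertion_window: int = 18) -> DescriptorSet:
    """Compute the full descriptor bundle for one peptide."""
    # imported here to keep seqcore free of a hard dependency direction
    from . import helix

    ins_h = ins_m = None
    if len(p) >= insertion_window:
        w = helix.insertion_region(p, insertion_window)
        ins_h = helix.mean_hydrophobicity(w)
        ins_m = helix.hydrophobic_moment(w)[0]
    return DescriptorSet(
        id=p.id,
        sequence=p.sequence,
        length=len(p),
        net_charge=net_charge(p),
        gravy=gravy(p),
        instability_index=instability_index(p),
        average_mass=average_mass(p),
        insertion_hydrophobicity=ins_h,
        insertion_moment=ins_m,
    )
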