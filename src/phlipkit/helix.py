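"""Helical-wheel geometry and amphipathicity analytics.

An ideal alpha-helix advances 100 degrees per residue, so a helical wheel
repeats after 18 residues. The C-terminal transmembrane ("insertion")
segment of a pHLIP is analyzed here as the C-terminal 18-residue window:
with the Fauchere-Pliska hydrophobicity scale this window reproduces the
HeliQuest-style per-residue mean hydrophobicity of the insertion region.
The hydrophobic moment follows the Eisenberg vector-sum formulation; both
the mean (divide by N) and raw-sum normalizations are exposed because
published tools differ on this point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqcore import Peptide, PeptideError, PropertyScale, load_scale

__all__ = [
    "HelicalWindow",
    "AmphipathyResult",
    "insertion_region",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "wheel_positions",
    "scan_windows",
]

#: Residues drawn on the polar face of the wheel; all others are apolar.
POLAR_RESIDUES = frozenset("DEKRHNQSTY")


@dataclass(frozen=True)
class HelicalWindow:
    """A contiguous subsequence laid out on an ideal helix.

    ``start`` is the 1-based inclusive position of the window within its
    parent peptide; residue ``k`` (0-based within the window) sits at angle
    ``(k * delta) mod 360`` degrees, with ``delta`` = 100 for an ideal
    alpha-helix.
    """

    parent_id: str
    start: int
    residues: str
    delta: float = 100.0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise PeptideError(f"window start must be >= 1, got {self.start}")
        if not self.residues:
            raise PeptideError("empty helical window")

    def __len__(self) -> int:
        return len(self.residues)

    def angles(self) -> list[float]:
        return [(k * self.delta) % 360.0 for k in range(len(self.residues))]


@dataclass(frozen=True)
class AmphipathyResult:
    window: HelicalWindow
    mean_hydrophobicity: float
    hydrophobic_moment: float
    moment_direction: float  # degrees in [0, 360)


def insertion_region(p: Peptide, window: int = 18) -> HelicalWindow:
    """The C-terminal ``window`` residues: the membrane-insertion segment.

    Raises if the peptide is shorter than the window.
    """
    L = len(p)
    if window < 1:
        raise PeptideError("window must be >= 1")
    if L < window:
        raise PeptideError(
            f"peptide {p.id!r} has {L} residues, shorter than window {window}"
        )
    start = L - window + 1
    return HelicalWindow(parent_id=p.id, start=start, residues=p.sequence[-window:])


def mean_hydrophobicity(w: HelicalWindow, scale: PropertyScale | None = None) -> float:
    """Unweighted mean scale value over the window (Fauchere-Pliska default)."""
    if scale is None:
        scale = load_scale("fauchere_pliska")
    if scale.kind != "per-residue":
        raise ValueError("mean_hydrophobicity requires a per-residue scale")
    return math.fsum(scale[r] for r in w.residues) / len(w)


def hydrophobic_moment(
    w: HelicalWindow,
    scale: PropertyScale | None = None,
    delta: float | None = None,
    normalization: str = "mean",
) -> tuple[float, float]:
    """Eisenberg hydrophobic moment of a helical window.

    mu_H = (1/N) * sqrt[(sum H_k sin(k*delta))^2 + (sum H_k cos(k*delta))^2]

    with ``normalization="sum"`` the 1/N factor is omitted. Returns
    ``(moment, direction)`` where direction is the azimuth of the resultant
    vector in degrees within [0, 360). The moment is non-negative and
    depends only on relative residue angles.
    """
    if scale is None:
        scale = load_scale("fauchere_pliska")
    if scale.kind != "per-residue":
        raise ValueError("hydrophobic_moment requires a per-residue scale")
    if normalization not in ("mean", "sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    step = w.delta if delta is None else delta
    sin_sum = math.fsum(
        scale[r] * math.sin(math.radians(k * step))
        for k, r in enumerate(w.residues)
    )
    cos_sum = math.fsum(
        scale[r] * math.cos(math.radians(k * step))
        for k, r in enumerate(w.residues)
    )
    moment = math.hypot(sin_sum, cos_sum)
    if normalization == "mean":
        moment /= len(w)
    direction = math.degrees(math.atan2(sin_sum, cos_sum)) % 360.0
    if moment == 0.0:
        direction = 0.0
    return moment, direction


def wheel_positions(w: HelicalWindow) -> list[tuple[int, str, float, str]]:
    """Helical-wheel layout: ``(position, residue, angle, class)`` per residue.

    ``position`` is 1-based within the parent peptide; ``class`` is
    ``"polar"`` for D/E/K/R/H/N/Q/S/T/Y and ``"apolar"`` otherwise.
    """
    out = []
    for k, (res, ang) in enumerate(zip(w.residues, w.angles())):
        cls = "polar" if res in POLAR_RESIDUES else "apolar"
        out.append((w.start + k, res, ang, cls))
    return out


def scan_windows(
    p: Peptide,
    window: int,
    scale: PropertyScale | None = None,
    criterion: str = "mean_hydrophobicity",
) -> list[AmphipathyResult]:
    """Score every window of the peptide and rank by the chosen criterion.

    One :class:`AmphipathyResult` per start position 1 .. L-window+1,
    sorted descending by ``criterion`` (``"mean_hydrophobicity"`` or
    ``"hydrophobic_moment"``); ties go to the smaller start position.
    """
    if scale is None:
        scale = load_scale("fauchere_pliska")
    if criterion not in ("mean_hydrophobicity", "hydrophobic_moment"):
        raise ValueError(f"unknown criterion {criterion!r}")
    L = len(p)
    if window > L:
        raise PeptideError(f"window {window} exceeds sequence length {L}")
    results: list[AmphipathyResult] = []
    for start in range(1, L - window + 2):
        w = HelicalWindow(
            parent_id=p.id, start=start, residues=p.sequence[start - 1 : start - 1 + window]
        )
        moment, direction = hydrophobic_moment(w, scale)
        results.append(
            AmphipathyResult(
                window=w,
                mean_hydrophobicity=mean_hydrophobicity(w, scale),
                hydrophobic_moment=moment,
                moment_direction=direction,
            )
        )
    key = (
        (lambda r: r.mean_hydrophobicity)
        if criterion == "mean_hydrophobicity"
        else (lambda r: r.hydrophobic_moment)
    )
    # stable sort on -score keeps the smaller start first among ties
    return sorted(results, key=lambda r: (-key(r), r.window.start))
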