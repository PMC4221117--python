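"""Screw-axis geometry: axis location, mechanical hinges, pitch, motion type.

By Chasles' theorem a rigid displacement is a screw motion about a
unique axis. Where that axis sits relative to the protein is
informative: an axis outside the body of the protein means no residue
exercises local control over the rotation, so any rotation about a
structural hinge must be accompanied by an in-plane translation. A
bending region with a C-alpha atom within 5.5 A of the axis is a
"mechanical hinge" — a backbone site that controls the movement like a
door hinge — and an axis with at least one mechanical hinge is an
"effective hinge axis". The pitch (translation per degree of rotation)
and the closure/twist annotation complete the per-movement record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contacts import DEFAULT_AXIS_CUTOFF, point_line_distances
from .structure_io import DomainSpec, ResidueKey, ScrewAxisRecord, Structure

__all__ = [
    "AxisAnalysis",
    "bending_regions",
    "axis_outside_protein",
    "mechanical_hinges",
    "pitch",
    "motion_type",
    "analyze_axis",
    "axis_analysis_report",
]


@dataclass
class AxisAnalysis:
    """Per-movement screw-axis summary."""

    axis_outside_protein: bool
    mechanical_hinges: list[str]  # region identifiers, e.g. "A:51-54"
    has_effective_hinge_axis: bool
    pitch: float | None  # A/degree, None when the rotation angle is zero
    motion_type: str  # "closure" | "twist"


def bending_regions(spec: DomainSpec) -> list[list[ResidueKey]]:
    """Group bending residues into contiguous backbone segments.

    Residues are consecutive when they share a chain and their author
    numbers differ by at most one (insertion codes at the same number
    stay in one region).
    """
    keys = sorted(spec.bending)
    regions: list[list[ResidueKey]] = []
    for key in keys:
        if (
            regions
            and regions[-1][-1].chain_id == key.chain_id
            and key.residue_number - regions[-1][-1].residue_number <= 1
        ):
            regions[-1].append(key)
        else:
            regions.append([key])
    return regions


def region_id(region: Sequence[ResidueKey]) -> str:
    first, last = region[0], region[-1]
    return (
        f"{first.chain_id}:{first.residue_number}{first.insertion_code}"
        f"-{last.residue_number}{last.insertion_code}"
    )


def axis_outside_protein(
    structure: Structure,
    axis: ScrewAxisRecord,
    cutoff: float = DEFAULT_AXIS_CUTOFF,
) -> bool:
    """True iff no heavy atom of the structure lies within ``cutoff`` of the axis.

    "Within" is inclusive, so an atom exactly at the cutoff puts the
    axis inside the protein.
    """
    coords = structure.all_coords()
    if coords.size == 0:
        raise ValueError("structure has no atoms")
    return bool(point_line_distances(coords, axis).min() > cutoff)


def mechanical_hinges(
    structure: Structure,
    spec: DomainSpec,
    axis: ScrewAxisRecord,
    cutoff: float = DEFAULT_AXIS_CUTOFF,
) -> list[str]:
    """Bending regions with at least one C-alpha within ``cutoff`` of the axis.

    Only C-alpha atoms are tested (a side chain reaching towards the
    axis does not make a hinge). Bending residues with no C-alpha are
    skipped with a warning.
    """
    import warnings

    hinges: list[str] = []
    for region in bending_regions(spec):
        near = False
        for key in region:
            if key not in structure:
                continue
            ca = structure.ca_coord(key)
            if ca is None:
                warnings.warn(f"bending residue {key} has no C-alpha; skipped")
                continue
            if point_line_distances(ca.reshape(1, 3), axis)[0] <= cutoff:
                near = True
                break
        if near:
            hinges.append(region_id(region))
    return hinges


def pitch(axis: ScrewAxisRecord) -> float:
    """Pitch of the screw motion, |translation| / rotation_angle (A/degree)."""
    if axis.rotation_angle <= 0:
        raise ValueError("pitch is undefined for a zero rotation angle")
    return abs(axis.translation) / axis.rotation_angle


def motion_type(axis: ScrewAxisRecord) -> str:
    """"closure" when percent closure > 50, else "twist"."""
    return "closure" if axis.percent_closure > 50.0 else "twist"


def analyze_axis(
    structure: Structure,
    spec: DomainSpec,
    axis: ScrewAxisRecord,
    cutoff: float = DEFAULT_AXIS_CUTOFF,
) -> AxisAnalysis:
    hinges = mechanical_hinges(structure, spec, axis, cutoff)
    return AxisAnalysis(
        axis_outside_protein=axis_outside_protein(structure, axis, cutoff),
        mechanical_hinges=hinges,
        has_effective_hinge_axis=bool(hinges),
        pitch=pitch(axis) if axis.rotation_angle > 0 else None,
        motion_type=motion_type(axis),
    )


def axis_analysis_report(analysis: AxisAnalysis) -> str:
    pitch_txt = "undefined" if analysis.pitch is None else f"{analysis.pitch:.6f}"
    return (
        f"axis_outside_protein = {str(analysis.axis_outside_protein).lower()}\n"
        f"n_mechanical_hinges = {len(analysis.mechanical_hinges)}\n"
        f"mechanical_hinges = {','.join(analysis.mechanical_hinges) or '-'}\n"
        f"effective_hinge_axis = {str(analysis.has_effective_hinge_axis).lower()}\n"
        f"pitch_A_per_deg = {pitch_txt}\n"
        f"motion_type = {analysis.motion_type}\n"
    )
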