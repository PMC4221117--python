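"""Interdomain residue contacts for one conformation.

Two residues are in contact when any heavy atom of one lies within 4 A
(inclusive) of any heavy atom of the other. Before contacts between the
two domains are collected, residues assigned to bending regions are
removed, as are residues with any heavy atom within 5.5 A of the
interdomain screw axis: both kinds would show maintained contacts
whatever the mechanism of the movement and would only dilute the signal.

The production search uses a k-d tree over atoms; a naive all-pairs scan
with identical semantics is kept here as the reference oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import DomainSpec, ResidueKey, ScrewAxisRecord, Structure

__all__ = [
    "ContactPair",
    "ContactSet",
    "residues_in_contact",
    "excluded_residues",
    "compute_interdomain_contacts",
    "compute_interdomain_contacts_bruteforce",
    "point_line_distances",
    "contact_set_to_text",
    "contact_set_from_text",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.0  # A, heavy-atom minimum distance
DEFAULT_AXIS_CUTOFF = 5.5  # A, perpendicular distance to the screw axis


@dataclass(frozen=True, order=True)
class ContactPair:
    """An interdomain contact: residue ``a`` in domain A, ``b`` in domain B."""

    a: ResidueKey
    b: ResidueKey


@dataclass
class ContactSet:
    """The set of interdomain contact pairs of one conformation."""

    conformation_label: str
    pairs: frozenset[ContactPair] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[ContactPair]:
        return sorted(self.pairs)


def residues_in_contact(
    res_i: np.ndarray | Sequence[Sequence[float]],
    res_j: np.ndarray | Sequence[Sequence[float]],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> bool:
    """True iff the minimum heavy-atom distance between two residues is <= cutoff.

    The comparison is inclusive: atoms exactly at the cutoff count as a
    contact ("within 4 A" read inclusively). Symmetric in its arguments.
    """
    a = np.atleast_2d(np.asarray(res_i, dtype=float))
    b = np.atleast_2d(np.asarray(res_j, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("residue atom lists must be non-empty")
    return bool(cdist(a, b).min() <= cutoff)


def point_line_distances(points: np.ndarray, axis: ScrewAxisRecord) -> np.ndarray:
    """Perpendicular distances from points to the (infinite) axis line."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - axis.point
    proj = rel @ axis.direction
    perp = rel - np.outer(proj, axis.direction)
    return np.linalg.norm(perp, axis=1)


def excluded_residues(
    structure: Structure,
    spec: DomainSpec,
    axis: ScrewAxisRecord,
    axis_cutoff: float = DEFAULT_AXIS_CUTOFF,
) -> frozenset[ResidueKey]:
    """Residues removed before contact computation.

    Returns the bending residues plus every residue of the spec with any
    heavy atom whose perpendicular distance to the infinite screw-axis
    line is <= ``axis_cutoff`` (inclusive).
    """
    excluded: set[ResidueKey] = set(spec.bending)
    for key in spec.domain_a | spec.domain_b | spec.bending:
        coords = structure.residues.get(key)
        if coords is None:
            continue
        if point_line_distances(coords, axis).min() <= axis_cutoff:
            excluded.add(key)
    return frozenset(excluded)


def _eligible(
    structure: Structure,
    spec: DomainSpec,
    axis: ScrewAxisRecord,
    axis_cutoff: float,
) -> tuple[list[ResidueKey], list[ResidueKey]]:
    """Present, non-excluded residues of each domain (sorted)."""
    for name, role in (("domain_a", spec.domain_a), ("domain_b", spec.domain_b)):
        present = [k for k in role if k in structure]
        missing = len(role) - len(present)
        if not present:
            raise ValueError(
                f"no {name} residues of the domain specification are present "
                f"in structure {structure.conformation_label!r}"
            )
        if missing:
            logger.warning(
                "%d %s residues missing from structure %s; skipped",
                missing,
                name,
                structure.conformation_label,
            )
    excl = excluded_residues(structure, spec, axis, axis_cutoff)
    dom_a = sorted(k for k in spec.domain_a if k in structure and k not in excl)
    dom_b = sorted(k for k in spec.domain_b if k in structure and k not in excl)
    return dom_a, dom_b


def compute_interdomain_contacts(
    structure: Structure,
    spec: DomainSpec,
    axis: ScrewAxisRecord,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    axis_cutoff: float = DEFAULT_AXIS_CUTOFF,
) -> ContactSet:
    """All interdomain residue contact pairs of one conformation.

    Residues of the domain specification missing from the structure are
    skipped with a warning; bending and near-axis residues are excluded.
    The search is k-d-tree accelerated; results are identical to the
    all-pairs scan (:func:`compute_interdomain_contacts_bruteforce`).
    """
    dom_a, dom_b = _eligible(structure, spec, axis, axis_cutoff)
    pairs: set[ContactPair] = set()
    if dom_a and dom_b:
        coords_a = [structure.residues[k] for k in dom_a]
        coords_b = [structure.residues[k] for k in dom_b]
        idx_a = np.concatenate(
            [np.full(len(c), i) for i, c in enumerate(coords_a)]
        )
        idx_b = np.concatenate(
            [np.full(len(c), i) for i, c in enumerate(coords_b)]
        )
        tree_b = cKDTree(np.vstack(coords_b))
        neighbours = tree_b.query_ball_point(np.vstack(coords_a), r=cutoff)
        for atom_a, hits in enumerate(neighbours):
            if hits:
                ra = dom_a[idx_a[atom_a]]
                for atom_b in hits:
                    pairs.add(ContactPair(ra, dom_b[idx_b[atom_b]]))
    return ContactSet(structure.conformation_label, frozenset(pairs))


def compute_interdomain_contacts_bruteforce(
    structure: Structure,
    spec: DomainSpec,
    axis: ScrewAxisRecord,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    axis_cutoff: float = DEFAULT_AXIS_CUTOFF,
) -> ContactSet:
    """Reference all-pairs contact scan (O(n_a * n_b) residue pairs)."""
    dom_a, dom_b = _eligible(structure, spec, axis, axis_cutoff)
    pairs = frozenset(
        ContactPair(ra, rb)
        for ra in dom_a
        for rb in dom_b
        if residues_in_contact(structure.residues[ra], structure.residues[rb], cutoff)
    )
    return ContactSet(structure.conformation_label, pairs)


def contact_set_to_text(contacts: ContactSet) -> str:
    """Serialize a contact set: header line then one tab-separated pair per line."""
    lines = [f"# conformation {contacts.conformation_label}"]
    lines += [f"{p.a}\t{p.b}" for p in contacts.sorted_pairs()]
    return "\n".join(lines) + "\n"


def contact_set_from_text(text: str) -> ContactSet:
    """Parse the serialization produced by :func:`contact_set_to_text`."""
    label = ""
    pairs: set[ContactPair] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line[1:].strip().startswith("conformation"):
                label = line[1:].strip()[len("conformation") :].strip()
            continue
        a_txt, b_txt = line.split("\t")
        pairs.add(ContactPair(ResidueKey.parse(a_txt), ResidueKey.parse(b_txt)))
    return ContactSet(label, frozenset(pairs))
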