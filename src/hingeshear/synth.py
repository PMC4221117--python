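"""Synthetic two-conformation fixtures, random DCGs and simulated training data.

The fixture generator emulates the input regime of the analysis without
any real structures: poly-alanine-like residues (N, CA, C, O, CB heavy
atoms) arranged as two facing domains, with conformation 2 produced by a
rigid screw motion of domain B about a declared axis while domain A
stays fixed (the DynDom fixed-domain superposition convention).

Three motion kinds are generated:

hinge
    two facing residue chains in contact; a 30 degree rotation about an
    axis at the edge of the interface swings domain B away, breaking
    every interdomain contact — a "pacman" opening dominated by new
    contact changes;
shear
    two facing residue grids; a small rotation about the interface
    normal slides the domains across a preserved flat interface,
    leaving contacts maintained;
no_contact
    the domains are too far apart to touch in either conformation.

Small seeded coordinate jitter (default 0.03 A) keeps fixtures from
being perfectly degenerate while staying far from any decision
boundary, so contact counts are stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .classifier import LogisticModel, TrainingSet
from .dcg import DynamicContactGraph, Edge
from .structure_io import (
    DomainSpec,
    ResidueKey,
    ScrewAxisRecord,
    Structure,
    write_axis_config,
    write_domain_spec,
)

__all__ = [
    "MotionScenario",
    "make_two_conformation_fixture",
    "write_fixture",
    "write_structure_pdb",
    "make_random_dcg",
    "make_training_set",
]

# Idealized alanine heavy atoms, CA at the origin, CB along +z (towards
# the partner domain; mirrored for domain B).
_RESIDUE_TEMPLATE = {
    "N": np.array([-0.53, 1.36, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.15, 1.05, 0.0]),
    "CB": np.array([-0.51, -0.77, 1.21]),
}

_INTERFACE_GAP = 5.9  # A between the CA planes: facing CB atoms sit 3.48 A apart
_GRID_SPACING = 5.0  # A between neighbouring residues within a domain

_DEFAULT_ANGLES = {"hinge": 30.0, "shear": 5.0, "no_contact": 5.0}
_DEFAULT_CLOSURE = {"hinge": 84.0, "shear": 30.0, "no_contact": 50.0}


@dataclass(frozen=True)
class MotionScenario:
    """Parameters of one synthetic domain movement (seed-deterministic)."""

    kind: str  # hinge | shear | no_contact
    n_residues_per_domain: int = 0  # 0 -> kind-specific default
    rotation_angle: float | None = None  # degrees; None -> kind default
    translation: float = 0.0  # A along the axis
    jitter: float = 0.03  # A, uniform coordinate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("hinge", "shear", "no_contact"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")

    @property
    def angle(self) -> float:
        return (
            _DEFAULT_ANGLES[self.kind]
            if self.rotation_angle is None
            else self.rotation_angle
        )

    @property
    def n_per_domain(self) -> int:
        if self.n_residues_per_domain > 0:
            return self.n_residues_per_domain
        return 8 if self.kind == "hinge" else 25


def _residue_atoms(ca: np.ndarray, flip_z: bool) -> np.ndarray:
    sign = -1.0 if flip_z else 1.0
    coords = []
    for name, local in _RESIDUE_TEMPLATE.items():
        v = local.copy()
        v[2] *= sign
        coords.append(ca + v)
    return np.asarray(coords)


def _rotation_matrix(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    d = direction / np.linalg.norm(direction)
    th = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]], dtype=float
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def _screw_transform(
    coords: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray,
    angle_deg: float, translation: float,
) -> np.ndarray:
    rot = _rotation_matrix(axis_dir, angle_deg)
    unit = axis_dir / np.linalg.norm(axis_dir)
    return (coords - axis_point) @ rot.T + axis_point + translation * unit


def _grid_positions(n: int, z: float) -> np.ndarray:
    """n residue CA positions on a centred square-ish grid in the plane z."""
    m = int(np.ceil(np.sqrt(n)))
    pts = []
    for i in range(m):
        for j in range(m):
            if len(pts) == n:
                break
            pts.append(
                [
                    _GRID_SPACING * (i - (m - 1) / 2.0),
                    _GRID_SPACING * (j - (m - 1) / 2.0),
                    z,
                ]
            )
    return np.asarray(pts)


def make_two_conformation_fixture(
    scenario: MotionScenario,
) -> tuple[Structure, Structure, DomainSpec, ScrewAxisRecord]:
    """Build (conformation 1, conformation 2, domain spec, screw axis).

    Conformation 2 equals conformation 1 with domain B screw-transformed
    about the declared axis; domain A and the bending residues are fixed,
    so both conformations are already in the common fixed-domain frame.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_per_domain
    gap = _INTERFACE_GAP
    mid_z = gap / 2.0

    if scenario.kind == "hinge":
        # facing linear chains; axis along y at the edge of the interface
        ca_a = np.asarray([[_GRID_SPACING * i, 0.0, 0.0] for i in range(n)])
        ca_b = ca_a + np.array([0.0, 0.0, gap])
        axis_point = np.array([-7.0, 0.0, mid_z])
        axis_dir = np.array([0.0, -1.0, 0.0])  # sense: positive angle opens B away
        bend_ca = [np.array([-7.0, -4.0, mid_z]), np.array([-7.0, 1.0, mid_z])]
    elif scenario.kind == "shear":
        # facing grids; axis = interface normal through the grid centre
        ca_a = _grid_positions(n, 0.0)
        ca_b = _grid_positions(n, gap)
        axis_point = np.array([0.0, 0.0, 0.0])
        axis_dir = np.array([0.0, 0.0, 1.0])
        side = _GRID_SPACING * np.sqrt(n)
        bend_ca = [
            np.array([-side - 8.0, 0.0, mid_z]),
            np.array([-side - 8.0, 5.0, mid_z]),
        ]
    else:  # no_contact
        ca_a = _grid_positions(min(n, 9), 0.0)
        ca_b = _grid_positions(min(n, 9), 40.0)
        axis_point = np.array([0.0, 0.0, 0.0])
        axis_dir = np.array([0.0, 0.0, 1.0])
        bend_ca = [np.array([-25.0, 0.0, 20.0]), np.array([-25.0, 5.0, 20.0])]

    def build(ca_list, flip, start_num) -> dict[ResidueKey, np.ndarray]:
        res = {}
        for i, ca in enumerate(ca_list):
            atoms = _residue_atoms(np.asarray(ca, dtype=float), flip)
            atoms = atoms + rng.uniform(
                -scenario.jitter, scenario.jitter, atoms.shape
            )
            res[ResidueKey("A", start_num + i)] = atoms
        return res

    na, nb = len(ca_a), len(ca_b)
    res_a = build(ca_a, flip=False, start_num=1)
    res_bend = build(bend_ca, flip=False, start_num=na + 1)
    res_b = build(ca_b, flip=True, start_num=na + 3)

    all_a = np.vstack(list(res_a.values()))
    all_b = np.vstack(list(res_b.values()))
    min_sep = np.min(
        np.linalg.norm(all_a[:, None, :] - all_b[None, :, :], axis=-1)
    )
    if min_sep < 1.8:
        raise ValueError(
            f"impossible geometry: domains overlap (min separation {min_sep:.2f} A)"
        )

    names = list(_RESIDUE_TEMPLATE)
    conf1 = Structure("conf1")
    for key, atoms in {**res_a, **res_bend, **res_b}.items():
        conf1.residues[key] = atoms
        conf1.atom_names[key] = list(names)

    conf2 = Structure("conf2")
    for key, atoms in {**res_a, **res_bend}.items():
        conf2.residues[key] = atoms.copy()
        conf2.atom_names[key] = list(names)
    for key, atoms in res_b.items():
        conf2.residues[key] = _screw_transform(
            atoms, axis_point, axis_dir, scenario.angle, scenario.translation
        )
        conf2.atom_names[key] = list(names)

    spec = DomainSpec(
        domain_a=frozenset(res_a),
        domain_b=frozenset(res_b),
        bending=frozenset(res_bend),
    )
    axis = ScrewAxisRecord(
        point=axis_point,
        direction=axis_dir,
        rotation_angle=abs(scenario.angle),
        translation=scenario.translation,
        percent_closure=_DEFAULT_CLOSURE[scenario.kind],
    )
    return conf1, conf2, spec, axis


def write_structure_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file (poly-ALA, single model)."""
    st = gemmi.Structure()
    st.name = structure.conformation_label
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for key in sorted(structure.residues):
        chain = chains.get(key.chain_id)
        if chain is None:
            chain = gemmi.Chain(key.chain_id)
            chains[key.chain_id] = chain
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(key.residue_number, key.insertion_code or " ")
        for name, pos in zip(structure.atom_names[key], structure.residues[key]):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        chain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_fixture(scenario: MotionScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write conf1.pdb, conf2.pdb, domains.txt and axis.txt; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conf1, conf2, spec, axis = make_two_conformation_fixture(scenario)
    paths = {
        "conf1": out / "conf1.pdb",
        "conf2": out / "conf2.pdb",
        "domains": out / "domains.txt",
        "axis": out / "axis.txt",
    }
    write_structure_pdb(conf1, paths["conf1"])
    write_structure_pdb(conf2, paths["conf2"])
    write_domain_spec(spec, paths["domains"])
    write_axis_config(axis, paths["axis"])
    return paths


def make_random_dcg(
    n_forward: int,
    n_backward: int,
    n_nodes_a: int,
    n_nodes_b: int,
    seed: int = 0,
) -> DynamicContactGraph:
    """Uniform random DCG with distinct forward and distinct backward edges."""
    n_pairs = n_nodes_a * n_nodes_b
    if n_forward > n_pairs or n_backward > n_pairs:
        raise ValueError("requested edges exceed the number of possible pairs")
    rng = np.random.default_rng(seed)
    nodes_a = [ResidueKey("A", i + 1) for i in range(n_nodes_a)]
    nodes_b = [ResidueKey("B", j + 1) for j in range(n_nodes_b)]

    def sample(k: int) -> frozenset[Edge]:
        idx = rng.choice(n_pairs, size=k, replace=False)
        return frozenset(
            (nodes_a[i // n_nodes_b], nodes_b[i % n_nodes_b]) for i in idx
        )

    fwd = sample(n_forward)
    bwd = sample(n_backward)
    return DynamicContactGraph(
        nodes_a=frozenset(a for a, _ in fwd | bwd),
        nodes_b=frozenset(b for _, b in fwd | bwd),
        forward_edges=fwd,
        backward_edges=bwd,
    )


# Poisson means per elemental-count component for the two regimes the
# simulator mixes: hinge-like movements are dominated by exchanged-pair
# and new contact changes, shear-like by maintained and exchanged-partner.
# The regimes emulate clear-cut, intuitively assignable movements (large
# preserved interfaces for shear, wholesale contact creation for hinge),
# so most simulated predictions sit near 0 or 1 rather than mid-range.
HINGE_LIKE_MEANS = (0.3, 0.2, 4.0, 14.0)
SHEAR_LIKE_MEANS = (20.0, 6.0, 0.2, 0.3)


def make_training_set(
    model: LogisticModel,
    n: int,
    hinge_means: tuple[float, float, float, float] = HINGE_LIKE_MEANS,
    shear_means: tuple[float, float, float, float] = SHEAR_LIKE_MEANS,
    seed: int = 0,
) -> TrainingSet:
    """Simulate labelled count vectors from a logistic model.

    Half of the items draw their counts from independent Poissons with
    hinge-like means, half with shear-like means; each label is then
    Bernoulli(y(N)) — the model output read as the posterior probability
    of shear. Both classes are guaranteed present (the most extreme
    items are flipped if a draw leaves one class empty, which only
    happens for tiny n).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    for means in (hinge_means, shear_means):
        if len(means) != 4 or any(m < 0 for m in means):
            raise ValueError(f"invalid Poisson means {means!r}")
    rng = np.random.default_rng(seed)
    n_hinge_like = n // 2
    counts = np.vstack(
        [
            rng.poisson(hinge_means, size=(n_hinge_like, 4)),
            rng.poisson(shear_means, size=(n - n_hinge_like, 4)),
        ]
    ).astype(float)
    y = model.predict(counts)
    labels = (rng.uniform(size=n) < y).astype(int)
    if labels.min() == labels.max():  # degenerate draw: force both classes
        flip = int(np.argmax(y) if labels[0] == 0 else np.argmin(y))
        labels[flip] = 1 - labels[flip]
    ids = [f"sim{i:04d}" for i in range(n)]
    return TrainingSet(counts=counts, labels=labels, ids=ids)
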