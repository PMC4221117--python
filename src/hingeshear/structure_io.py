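"""Read protein structures, domain specifications and screw-axis records.

The package analyses a domain movement given as two conformations of the
same protein (PDB-format coordinate files, pre-superposed on one domain),
a partition of residues into domain A, domain B and bending regions (as
produced by a DynDom-style analysis), and the interdomain screw axis that
maps one conformation onto the other (Chasles' theorem guarantees such an
axis exists for any rigid displacement).

Only heavy atoms are kept: the contact definition used downstream is a
heavy-atom distance criterion, so hydrogens (and deuteriums) are dropped
at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

__all__ = [
    "ResidueKey",
    "Structure",
    "DomainSpec",
    "ScrewAxisRecord",
    "StructureParseError",
    "read_structure",
    "read_domain_spec",
    "read_axis",
    "write_axis_config",
    "write_domain_spec",
]


class StructureParseError(ValueError):
    """Raised when a coordinate or specification file cannot be parsed."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identifies one residue: chain id, author residue number, insertion code.

    The triple is unique within a conformation and totally ordered
    (chain, number, insertion code) so that serialized output and
    tie-breaking are deterministic.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{self.insertion_code}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        m = re.fullmatch(r"(\w):(-?\d+)([A-Za-z]?)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse residue key {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))


@dataclass
class Structure:
    """Heavy-atom coordinates of one conformation.

    ``residues`` maps each :class:`ResidueKey` to an (n_atoms, 3) float
    array of heavy-atom coordinates in angstroms, in file order.
    ``atom_names`` holds the matching atom names (needed to locate
    C-alpha atoms for the mechanical-hinge test).
    """

    conformation_label: str
    residues: dict[ResidueKey, np.ndarray] = field(default_factory=dict)
    atom_names: dict[ResidueKey, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.residues

    def coords(self, key: ResidueKey) -> np.ndarray:
        return self.residues[key]

    def ca_coord(self, key: ResidueKey) -> np.ndarray | None:
        """C-alpha coordinate of a residue, or None if it has no CA atom."""
        try:
            idx = self.atom_names[key].index("CA")
        except (KeyError, ValueError):
            return None
        return self.residues[key][idx]

    def all_coords(self) -> np.ndarray:
        """All heavy-atom coordinates stacked into one (N, 3) array."""
        if not self.residues:
            return np.empty((0, 3))
        return np.vstack(list(self.residues.values()))


@dataclass(frozen=True)
class DomainSpec:
    """Residue sets for domain A, domain B and the bending regions.

    The three roles are pairwise disjoint; domain A and domain B are
    non-empty. Bending regions are the backbone segments connecting the
    domains within which the rotational transition occurs.
    """

    domain_a: frozenset[ResidueKey]
    domain_b: frozenset[ResidueKey]
    bending: frozenset[ResidueKey] = frozenset()

    def __post_init__(self) -> None:
        if not self.domain_a or not self.domain_b:
            raise ValueError("domain_a and domain_b must be non-empty")
        for x, y, names in (
            (self.domain_a, self.domain_b, "domain_a/domain_b"),
            (self.domain_a, self.bending, "domain_a/bending"),
            (self.domain_b, self.bending, "domain_b/bending"),
        ):
            overlap = x & y
            if overlap:
                ex = ", ".join(str(k) for k in sorted(overlap)[:5])
                raise ValueError(f"roles {names} overlap on residues: {ex}")


@dataclass(frozen=True)
class ScrewAxisRecord:
    """Interdomain screw axis plus the screw-motion scalars.

    point
        Any point on the axis (angstroms).
    direction
        Unit vector along the axis (normalized on construction).
    rotation_angle
        Interdomain rotation in degrees, >= 0.
    translation
        Signed displacement along the axis in angstroms.
    percent_closure
        DynDom's closure percentage in [0, 100]; > 50 means a closure
        motion, <= 50 a twisting motion.
    """

    point: np.ndarray
    direction: np.ndarray
    rotation_angle: float
    translation: float
    percent_closure: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if norm < 1e-12:
            raise ValueError("axis direction must be non-zero")
        object.__setattr__(self, "direction", d / norm)
        if self.rotation_angle < 0:
            raise ValueError("rotation_angle must be >= 0")
        if not (0.0 <= self.percent_closure <= 100.0):
            raise ValueError("percent_closure must lie in [0, 100]")


# Atom-name based element fallback for files with a blank element column.
_HYDROGEN_NAME = re.compile(r"^\d*[HD]")


def _is_heavy(atom: gemmi.Atom) -> bool:
    el = atom.element
    if el is not None and el.name not in ("", "X"):
        return el.name not in ("H", "D", "T")
    return _HYDROGEN_NAME.match(atom.name.strip()) is None


def read_structure(
    path: str | Path,
    chain_filter: set[str] | None = None,
    include_hetatm: bool = False,
    label: str | None = None,
) -> Structure:
    """Read heavy atoms of the first model of a PDB file.

    Parameters
    ----------
    path:
        PDB-format coordinate file.
    chain_filter:
        If given, keep only these chain ids.
    include_hetatm:
        Keep HETATM residues (waters are always dropped). Default is
        protein residues only.
    label:
        Conformation label; defaults to the file stem.

    Notes
    -----
    Hydrogens/deuteriums are dropped; for alternate locations the
    first-listed altloc of each atom name is kept; only model 1 of a
    multi-model file is used. Residue numbering is author numbering with
    insertion codes, unchanged.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models in PDB file {path}")

    out = Structure(conformation_label=label or path.stem)
    model = st[0]
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and not include_hetatm:
                continue
            icode = res.seqid.icode.strip()
            key = ResidueKey(chain.name, res.seqid.num, icode)
            coords: list[list[float]] = out.residues.get(key, np.empty((0, 3))).tolist()
            names: list[str] = out.atom_names.get(key, [])
            seen = set(names)
            for atom in res:
                if not _is_heavy(atom):
                    continue
                if atom.name in seen:  # first-listed altloc wins
                    continue
                seen.add(atom.name)
                names.append(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if coords:
                out.residues[key] = np.asarray(coords, dtype=float)
                out.atom_names[key] = names
    if not out.residues:
        raise StructureParseError(f"no residues selected from {path}")
    return out


_ROLE_ALIASES = {
    "domaina": "domain_a",
    "domain_a": "domain_a",
    "domainb": "domain_b",
    "domain_b": "domain_b",
    "bending": "bending",
}

_RANGE_RE = re.compile(r"(\w):(-?\d+)-(-?\d+)$")


def _expand_ranges(text: str) -> frozenset[ResidueKey]:
    keys: set[ResidueKey] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = _RANGE_RE.fullmatch(part)
        if m is None:
            raise StructureParseError(f"cannot parse residue range {part!r}")
        chain, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
        if hi < lo:
            raise StructureParseError(f"empty residue range {part!r}")
        keys.update(ResidueKey(chain, n) for n in range(lo, hi + 1))
    return frozenset(keys)


def read_domain_spec(source: str | Path) -> DomainSpec:
    """Parse a domain specification into residue sets.

    Accepts a path or literal text with lines of the form::

        domainA A:1-50,A:60-70
        domainB A:75-130
        bending A:51-54

    Roles must be pairwise disjoint and both domains non-empty.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)

    roles: dict[str, frozenset[ResidueKey]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            role_raw, ranges = line.split(None, 1)
        except ValueError:
            raise StructureParseError(f"line {lineno}: expected '<role> <ranges>'")
        role = _ROLE_ALIASES.get(role_raw.lower())
        if role is None:
            raise StructureParseError(f"line {lineno}: unknown role {role_raw!r}")
        roles[role] = roles.get(role, frozenset()) | _expand_ranges(ranges)

    return DomainSpec(
        domain_a=roles.get("domain_a", frozenset()),
        domain_b=roles.get("domain_b", frozenset()),
        bending=roles.get("bending", frozenset()),
    )


def _parse_vector(text: str) -> np.ndarray:
    vals = [float(v) for v in re.split(r"[,\s]+", text.strip()) if v]
    if len(vals) != 3:
        raise StructureParseError(f"expected 3 components, got {text!r}")
    return np.asarray(vals)


def read_axis(
    source: str | Path | Mapping[str, object],
    *,
    angle_deg: float | None = None,
    translation: float | None = None,
    percent_closure: float | None = None,
) -> ScrewAxisRecord:
    """Read a screw-axis specification.

    Three dialects are accepted:

    * a mapping with keys ``point``, ``direction``, ``angle_deg``,
      ``translation_A``, ``percent_closure``;
    * a config file/text with ``key = value`` lines using the same keys;
    * a DynDom-style two-atom "arrow" PDB file whose termini define the
      axis (point = first terminus, direction = terminus difference).
      Arrow files carry no screw scalars, so ``angle_deg``,
      ``translation`` and ``percent_closure`` default to 0 / 0 / 50
      unless passed explicitly.

    Keyword arguments override values found in the source.
    """
    values: dict[str, object]
    if isinstance(source, Mapping):
        values = dict(source)
    else:
        path_like = Path(str(source))
        is_file = "\n" not in str(source) and path_like.is_file()
        text = path_like.read_text() if is_file else str(source)
        first = text.lstrip()[:6]
        if first.startswith(("ATOM", "HETATM", "HEADER", "REMARK")):
            return _axis_from_arrow_pdb(
                path_like if is_file else text,
                angle_deg=angle_deg,
                translation=translation,
                percent_closure=percent_closure,
            )
        values = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                k, v = line.split("=", 1)
            else:
                k, v = line.split(None, 1)
            values[k.strip()] = v.strip()

    try:
        point = _parse_vector(str(values["point"])) if not isinstance(
            values.get("point"), (list, tuple, np.ndarray)
        ) else np.asarray(values["point"], dtype=float)
        raw_dir = values["direction"]
        direction = (
            np.asarray(raw_dir, dtype=float)
            if isinstance(raw_dir, (list, tuple, np.ndarray))
            else _parse_vector(str(raw_dir))
        )
    except KeyError as exc:
        raise StructureParseError(f"axis specification missing key {exc}") from exc

    def _scalar(key: str, override: float | None, default: float | None = None) -> float:
        if override is not None:
            return float(override)
        if key in values:
            return float(values[key])  # type: ignore[arg-type]
        if default is not None:
            return default
        raise StructureParseError(f"axis specification missing key '{key}'")

    return ScrewAxisRecord(
        point=point,
        direction=direction,
        rotation_angle=_scalar("angle_deg", angle_deg),
        translation=_scalar("translation_A", translation),
        percent_closure=_scalar("percent_closure", percent_closure),
    )


def _axis_from_arrow_pdb(
    source: Path | str,
    *,
    angle_deg: float | None,
    translation: float | None,
    percent_closure: float | None,
) -> ScrewAxisRecord:
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = source
    termini: list[np.ndarray] = []
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            termini.append(
                np.asarray(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            )
    if len(termini) < 2:
        raise StructureParseError("arrow PDB must contain at least two atoms")
    start, end = termini[0], termini[-1]
    if np.allclose(start, end):
        raise StructureParseError("arrow PDB termini coincide; axis undefined")
    return ScrewAxisRecord(
        point=start,
        direction=end - start,
        rotation_angle=0.0 if angle_deg is None else angle_deg,
        translation=0.0 if translation is None else translation,
        percent_closure=50.0 if percent_closure is None else percent_closure,
    )


def write_axis_config(axis: ScrewAxisRecord, path: str | Path) -> None:
    """Write an axis record as a key/value config file."""
    p, d = axis.point, axis.direction
    Path(path).write_text(
        f"point = {p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n"
        f"direction = {d[0]:.9f},{d[1]:.9f},{d[2]:.9f}\n"
        f"angle_deg = {axis.rotation_angle:.6f}\n"
        f"translation_A = {axis.translation:.6f}\n"
        f"percent_closure = {axis.percent_closure:.6f}\n"
    )


def _ranges_text(keys: Iterable[ResidueKey]) -> str:
    """Collapse residue keys into 'chain:lo-hi' run-length ranges."""
    runs: list[str] = []
    keys = sorted(keys)
    i = 0
    while i < len(keys):
        j = i
        while (
            j + 1 < len(keys)
            and keys[j + 1].chain_id == keys[j].chain_id
            and keys[j + 1].residue_number == keys[j].residue_number + 1
            and not keys[j].insertion_code
            and not keys[j + 1].insertion_code
        ):
            j += 1
        runs.append(
            f"{keys[i].chain_id}:{keys[i].residue_number}-{keys[j].residue_number}"
        )
        i = j + 1
    return ",".join(runs)


def write_domain_spec(spec: DomainSpec, path: str | Path) -> None:
    """Write a domain specification in the plain-text range format."""
    lines = [
        f"domainA {_ranges_text(spec.domain_a)}",
        f"domainB {_ranges_text(spec.domain_b)}",
    ]
    if spec.bending:
        lines.append(f"bending {_ranges_text(spec.bending)}")
    Path(path).write_text("\n".join(lines) + "\n")
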