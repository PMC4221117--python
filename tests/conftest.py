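from __future__ import annotations

import numpy as np
import pytest

from hingeshear.structure_io import ResidueKey, Structure

ATOM_NAMES = ["N", "CA", "C", "O", "CB"]


def make_structure(
    coords_by_key: dict[ResidueKey, np.ndarray],
    names_by_key: dict[ResidueKey, list[str]] | None = None,
    label: str = "test",
) -> Structure:
    """Assemble a Structure directly from coordinate arrays."""
    st = Structure(conformation_label=label)
    for key, coords in coords_by_key.items():
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        st.residues[key] = coords
        if names_by_key is not None:
            st.atom_names[key] = list(names_by_key[key])
        else:
            st.atom_names[key] = ATOM_NAMES[: len(coords)]
    return st


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    altloc: str = " ",
    icode: str = " ",
    record: str = "ATOM",
) -> str:
    """Format one fixed-width PDB coordinate record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} "
        f"{chain}{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


@pytest.fixture
def remote_axis():
    """A screw axis far from everything placed near the origin."""
    from hingeshear.structure_io import ScrewAxisRecord

    return ScrewAxisRecord(
        point=np.array([500.0, 0.0, 0.0]),
        direction=np.array([0.0, 0.0, 1.0]),
        rotation_angle=10.0,
        translation=0.0,
        percent_closure=84.0,
    )
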