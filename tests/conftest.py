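"""Shared fixtures: programmatic PDB text and small alignment tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    altloc: str = " ",
    icode: str = " ",
    occ: float = 1.0,
    record: str = "ATOM  ",
) -> str:
    return (
        f"{record}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {name[0]:>2s}"
    )


def ssbond_line(serial: int, c1: str, s1: int, c2: str, s2: int) -> str:
    return f"SSBOND {serial:3d} CYS {c1} {s1:4d}    CYS {c2} {s2:4d}"


def make_pdb(
    residues: list[tuple[str, str, int]],  # (resname, chain, resseq)
    ssbonds: list[tuple[str, int, str, int]] = (),
    header_lines: list[str] = (),
    extra_atoms: bool = False,
) -> str:
    """Minimal PDB text: one CA per residue on a helixish curve."""
    lines = list(header_lines)
    for ser, (c1, s1, c2, s2) in enumerate(ssbonds, start=1):
        lines.append(ssbond_line(ser, c1, s1, c2, s2))
    serial = 1
    for i, (resname, chain, resseq) in enumerate(residues):
        x, y, z = 3.8 * i, np.sin(i), np.cos(i)
        if extra_atoms:
            lines.append(atom_line(serial, "N", resname, chain, resseq, x - 1, y, z))
            serial += 1
        lines.append(atom_line(serial, "CA", resname, chain, resseq, x, y, z))
        serial += 1
        if extra_atoms:
            lines.append(atom_line(serial, "C", resname, chain, resseq, x + 1, y, z))
            serial += 1
            if resname == "CYS":
                lines.append(atom_line(serial, "SG", resname, chain, resseq, x, y + 1.8, z))
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def simple_pdb() -> str:
    return make_pdb([("ALA", "A", 1), ("CYS", "A", 2), ("GLY", "A", 3)])


@pytest.fixture
def ssbond_pdb() -> str:
    return make_pdb(
        [("CYS", "A", 1), ("ALA", "A", 2), ("CYS", "A", 3), ("CYS", "A", 9)],
        ssbonds=[("A", 1, "A", 3)],
        header_lines=[
            "EXPDTA    X-RAY DIFFRACTION",
            "REMARK   2 RESOLUTION.    1.80 ANGSTROMS.",
        ],
    )


@pytest.fixture
def small_stats() -> pd.DataFrame:
    """8-row deterministic family table for arithmetic oracles."""
    rng = np.random.default_rng(7)
    pni = np.array([12.0, 25.0, 33.0, 41.0, 55.0, 62.0, 74.0, 88.0])
    sng = np.array([0.5, 1.0, 0.8, 2.2, 3.1, 4.0, 5.5, 7.2])
    rmsd = 0.4 + 0.02 * pni + 0.12 * sng + rng.normal(0, 0.05, 8)
    return pd.DataFrame(
        {"pni": pni, "sng": sng, "rmsd": rmsd, "n_algn": 150, "n_gap": 3}
    )
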