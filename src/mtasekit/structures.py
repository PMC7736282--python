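"""Protein structures and distance-defined active-site shells.

The active site of a 2'O-mRNA methyltransferase is organised in residue
"shells" around the catalytic lysine: a first shell of side chains in direct
contact (within 4 Å), an intermediate second shell, and a third shell beyond
6 Å of the lysine's terminal amine (Nζ).  This module parses PDB structures
and assigns residues to those shells.

Distances are in Å throughout; only heavy atoms are considered (crystal
structures usually lack hydrogens).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

# Backbone heavy atoms; everything else heavy is "side chain".
_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_WATER = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identifier of one residue: chain, sequence number and name."""

    chain: str
    number: int
    name: str

    @property
    def label(self) -> str:
        """One-letter-code style label like 'D138' (falls back to 3-letter)."""
        one = gemmi.find_tabulated_residue(self.name)
        code = one.one_letter_code.upper() if one else "X"
        if not code.strip() or code == " ":
            code = "X"
        return f"{code}{self.number}"


@dataclass
class Structure:
    """Atom table of a (poly)peptide structure.

    ``atoms`` columns: atom_name, element, residue_name, residue_number,
    chain_id, x, y, z (Å), is_hetero.
    """

    atoms: pd.DataFrame
    resolution: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def residues(self) -> list[ResidueId]:
        seen: dict[tuple[str, int], str] = {}
        for row in self.atoms.itertuples():
            seen.setdefault((row.chain_id, row.residue_number), row.residue_name)
        return [ResidueId(c, n, name) for (c, n), name in seen.items()]

    def residue_atoms(self, rid: ResidueId, sidechain_only: bool = False) -> pd.DataFrame:
        sel = (self.atoms["chain_id"] == rid.chain) & (
            self.atoms["residue_number"] == rid.number
        )
        sub = self.atoms[sel]
        if sidechain_only:
            sub = sub[~sub["atom_name"].isin(_BACKBONE)]
        return sub

    def find_residue(self, number: int, chain: str | None = None) -> ResidueId:
        for rid in self.residues:
            if rid.number == number and (chain is None or rid.chain == chain):
                return rid
        raise KeyError(f"residue {number} (chain {chain!r}) not in structure")


@dataclass
class NeighborSet:
    """Residues with a side-chain heavy atom within ``cutoff`` of the focal selection."""

    focal: ResidueId
    focal_atom: str | None
    cutoff: float
    residues: set[ResidueId]
    min_distance: dict[ResidueId, float] = field(default_factory=dict)

    @property
    def labels(self) -> set[str]:
        return {r.label for r in self.residues}


@dataclass
class ShellAssignment:
    """Mapping of residues to active-site shells around a focal residue.

    Shell 1: side chains within ``first_cutoff`` of the focal side chain.
    Shell 3: residues whose nearest side-chain heavy atom is beyond
    ``third_min`` from the focal reference atom (Nζ for lysine).
    Shell 2: the remainder, either as the distance band between the two
    cutoffs (default) or as the graph expansion of shell 1.
    """

    focal: ResidueId
    shell_of: dict[ResidueId, int | None]
    first_cutoff: float
    third_min: float
    second_mode: str
    min_distance: dict[ResidueId, float] = field(default_factory=dict)

    def shell(self, k: int) -> set[ResidueId]:
        return {r for r, s in self.shell_of.items() if s == k}

    def shell_labels(self, k: int) -> set[str]:
        return {r.label for r in self.shell(k)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": r.label,
                "residue_name": r.name,
                "residue_number": r.number,
                "chain": r.chain,
                "shell": s if s is not None else "none",
                "min_distance_A": self.min_distance.get(r, np.nan),
            }
            for r, s in sorted(self.shell_of.items())
        ]
        return pd.DataFrame(rows)


def read_structure(
    path,
    chain: str | None = None,
    include_hetero: bool = False,
    keep_altloc: str = "A",
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Waters are always dropped; other HETATM records only kept when
    ``include_hetero``.  Of alternate locations, the blank altloc and
    ``keep_altloc`` (default 'A') are retained.
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    rows = []
    model = st[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.name in _WATER:
                continue
            het = res.het_flag == "H"
            if het and not include_hetero:
                continue
            for atom in res:
                if atom.altloc not in ("", "\0", keep_altloc):
                    continue
                rows.append(
                    {
                        "atom_name": atom.name,
                        "element": atom.element.name,
                        "residue_name": res.name,
                        "residue_number": res.seqid.num,
                        "chain_id": ch.name,
                        "x": atom.pos.x,
                        "y": atom.pos.y,
                        "z": atom.pos.z,
                        "is_hetero": het,
                    }
                )
    if chain is not None and not rows:
        raise ValueError(f"no atoms found for chain {chain!r} in {path}")
    if not rows:
        raise ValueError(f"no ATOM records found in {path}")
    res = st.resolution if st.resolution and st.resolution > 0 else None
    return Structure(pd.DataFrame(rows), resolution=res, source=str(path))


def _heavy_sidechain(structure: Structure, rid: ResidueId) -> pd.DataFrame:
    sub = structure.residue_atoms(rid, sidechain_only=True)
    return sub[sub["element"] != "H"]


def sidechain_neighbors(
    structure: Structure,
    focal: ResidueId | int,
    cutoff: float,
    focal_atom: str | None = None,
    chain: str | None = None,
) -> NeighborSet:
    """Residues with ≥1 side-chain heavy atom within ``cutoff`` Å of the focal selection.

    The focal selection is the focal residue's side-chain heavy atoms, or a
    single named atom (e.g. ``focal_atom='NZ'`` for a lysine's terminal
    amine).  The focal residue itself is excluded; sequence adjacency is not.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if isinstance(focal, int):
        focal = structure.find_residue(focal, chain)
    if focal_atom is not None:
        fsel = structure.residue_atoms(focal)
        fsel = fsel[fsel["atom_name"] == focal_atom]
        if fsel.empty:
            raise ValueError(f"focal residue {focal.label} has no atom {focal_atom!r}")
    else:
        fsel = _heavy_sidechain(structure, focal)
        if fsel.empty:
            raise ValueError(
                f"focal residue {focal.label} has no side-chain heavy atoms"
            )
    fxyz = fsel[["x", "y", "z"]].to_numpy(float)

    others = structure.atoms[
        ~(
            (structure.atoms["chain_id"] == focal.chain)
            & (structure.atoms["residue_number"] == focal.number)
        )
    ]
    others = others[
        (~others["atom_name"].isin(_BACKBONE)) & (others["element"] != "H")
    ]
    residues: set[ResidueId] = set()
    min_d: dict[ResidueId, float] = {}
    if not others.empty and len(fxyz):
        tree = cKDTree(fxyz)
        oxyz = others[["x", "y", "z"]].to_numpy(float)
        dists, _ = tree.query(oxyz, k=1)
        for (_, row), d in zip(others.iterrows(), dists):
            rid = ResidueId(row["chain_id"], int(row["residue_number"]), row["residue_name"])
            if rid not in min_d or d < min_d[rid]:
                min_d[rid] = float(d)
        residues = {r for r, d in min_d.items() if d <= cutoff}
    return NeighborSet(
        focal=focal,
        focal_atom=focal_atom,
        cutoff=cutoff,
        residues=residues,
        min_distance={r: min_d[r] for r in residues},
    )


def assign_shells(
    structure: Structure,
    focal_residue: ResidueId | int,
    first_cutoff: float = 4.0,
    third_min: float = 6.0,
    chain: str | None = None,
    reference_atom: str | None = None,
    second_mode: Literal["distance_band", "graph"] = "distance_band",
) -> ShellAssignment:
    """Assign every residue to an active-site shell around ``focal_residue``.

    Shell 1 holds residues with a side-chain heavy atom within
    ``first_cutoff`` Å of the focal side chain.  Shell 3 holds residues whose
    nearest side-chain heavy atom to the focal *reference atom* (Nζ for Lys,
    overridable) is beyond ``third_min`` Å.  Shell 2 is the remainder —
    by default the distance band between the cutoffs, alternatively the
    4-Å graph expansion of shell 1 (``second_mode='graph'``), in which case
    residues in neither expansion nor shell 3 get shell ``None``.
    """
    if isinstance(focal_residue, int):
        focal_residue = structure.find_residue(focal_residue, chain)
    shell1 = sidechain_neighbors(structure, focal_residue, first_cutoff)

    if reference_atom is None:
        reference_atom = "NZ" if focal_residue.name == "LYS" else None
    # distance from the reference atom (or whole side chain) to every residue
    far = sidechain_neighbors(
        structure, focal_residue, np.inf, focal_atom=reference_atom
    )
    min_d = far.min_distance

    shell_of: dict[ResidueId, int | None] = {}
    if second_mode == "graph":
        expansion: set[ResidueId] = set()
        for rid in shell1.residues:
            try:
                expansion |= sidechain_neighbors(structure, rid, first_cutoff).residues
            except ValueError:  # glycine member has no side chain to expand from
                continue
        expansion -= shell1.residues | {focal_residue}
    for rid in structure.residues:
        if rid == focal_residue:
            continue
        d = min_d.get(rid, np.inf)
        if rid in shell1.residues:
            shell_of[rid] = 1
        elif d > third_min:
            shell_of[rid] = 3
        elif second_mode == "distance_band":
            shell_of[rid] = 2
        else:
            shell_of[rid] = 2 if rid in expansion else None
    return ShellAssignment(
        focal=focal_residue,
        shell_of=shell_of,
        first_cutoff=first_cutoff,
        third_min=third_min,
        second_mode=second_mode,
        min_distance=min_d,
    )
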