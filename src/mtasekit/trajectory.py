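"""Trajectory-derived observables: H-bond networks, distances, rigidity.

Three observables characterise how active-site mutations rearrange the
hydrogen-bond network of the enzyme along MD trajectories:

* **occurrence networks** — for each residue pair, the number (and fraction)
  of frames containing at least one side-chain–side-chain hydrogen bond;
* **catalytic distance series** — e.g. the distance between the catalytic
  lysine's Nζ and the 2′ oxygen of the mRNA's first transcribed nucleotide
  (~0.3 nm in catalytically competent poses);
* **side-chain rigidity** — RMSD of the first-shell side chains after
  backbone superposition, summarised as median + interquartile range.

A hydrogen bond requires donor–acceptor distance ≤ 0.35 nm and
hydrogen–donor–acceptor angle ≤ 30° (the common MD-package defaults).
Internal units are nm and ps; Å inputs (PDB, MDAnalysis) are converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import MDAnalysis as mda
import networkx as nx
import numpy as np

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN", "H1", "H2", "H3"}
_DONOR_ELEMENTS = {"N", "O", "F"}
_ACCEPTOR_ELEMENTS = {"N", "O", "F"}
_MAX_DH_BOND_NM = 0.125  # covalent D–H bond guess when topology has no bonds


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition (GROMACS-style defaults)."""

    max_distance: float = 0.35  # donor–acceptor, nm
    max_angle: float = 30.0     # hydrogen–donor–acceptor, degrees

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not 0 < self.max_angle <= 90:
            raise ValueError("angle cutoff must be in (0, 90] degrees")


@dataclass
class Trajectory:
    """An MDAnalysis universe plus a replicate tag; positions in Å inside,
    nm at every public output."""

    universe: mda.Universe
    replicate: str = "r1"

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory)

    def times_ps(self) -> np.ndarray:
        return np.array([ts.time for ts in self.universe.trajectory], float)


def read_trajectory(
    topology, *coordinate_files, replicate: str = "r1", dt_ps: float = 1.0
) -> Trajectory:
    """Load a topology (PDB) plus coordinate frames (XTC/DCD/TRR or
    multi-model PDB).  ``dt_ps`` supplies the frame spacing for formats
    that do not carry time stamps."""
    try:
        if coordinate_files:
            u = mda.Universe(str(topology), [str(f) for f in coordinate_files],
                             dt=dt_ps)
        else:
            u = mda.Universe(str(topology), dt=dt_ps)
    except (ValueError, IOError) as exc:
        raise ValueError(f"cannot load trajectory: {exc}") from exc
    return Trajectory(u, replicate=replicate)


# ---------------------------------------------------------------------------
# hydrogen-bond geometry


def hbond_angle_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Hydrogen–donor–acceptor angle (vertex at the donor), degrees."""
    v1 = h - d
    v2 = a - d
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    positions_nm: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    criteria: HBondCriteria | None = None,
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame.

    ``donors`` are (donor-heavy-atom, attached-hydrogen) index pairs;
    ``acceptors`` are atom indices.  A bond (D, H, A) is reported iff the
    D–A distance is within the cutoff and the H–D–A angle within the angle
    cutoff.  The donor itself is never its own acceptor.
    """
    criteria = criteria or HBondCriteria()
    if not donors or not acceptors:
        warnings.warn("empty donor or acceptor selection")
        return []
    pos = np.asarray(positions_nm, float)
    acc = np.asarray(list(acceptors), int)
    out = []
    for d_idx, h_idx in donors:
        dvec = pos[acc] - pos[d_idx]
        dist = np.linalg.norm(dvec, axis=1)
        for a_idx, dd in zip(acc, dist):
            if a_idx == d_idx or a_idx == h_idx:
                continue
            if dd > criteria.max_distance:
                continue
            ang = hbond_angle_deg(pos[d_idx], pos[h_idx], pos[a_idx])
            if ang <= criteria.max_angle:
                out.append((int(d_idx), int(h_idx), int(a_idx)))
    return out


def _element_of(atom) -> str:
    try:
        el = atom.element
        if el:
            return el.upper()
    except mda.exceptions.NoDataError:
        pass
    return mda.topology.guessers.guess_atom_element(atom.name).upper()


def find_donors_acceptors(
    atoms: mda.AtomGroup, sidechain_only: bool = False
) -> tuple[list[tuple[int, int]], list[int]]:
    """Polar donors (with attached hydrogens) and acceptors in a selection.

    Hydrogens are attached to the nearest polar heavy atom within covalent
    range when the topology carries no bond table.  Indices are positions in
    the universe's atom array.
    """
    u = atoms.universe
    elements = np.array([_element_of(a) for a in u.atoms])
    keep = set(atoms.indices)
    if sidechain_only:
        keep = {i for i in keep if u.atoms[i].name not in _BACKBONE_NAMES}
    heavies = [
        i for i in keep if elements[i] in _DONOR_ELEMENTS
    ]
    acceptors = [i for i in heavies if elements[i] in _ACCEPTOR_ELEMENTS]

    donors: list[tuple[int, int]] = []
    hydrogens = np.where(elements == "H")[0]
    if len(hydrogens) and heavies:
        pos = u.atoms.positions / 10.0  # Å -> nm
        try:
            bonds = {tuple(sorted(b.indices)) for b in u.bonds}
        except mda.exceptions.NoDataError:
            bonds = None
        for h in hydrogens:
            if bonds is not None:
                partners = [
                    j for j in heavies if tuple(sorted((h, j))) in bonds
                ]
            else:
                d = np.linalg.norm(pos[heavies] - pos[h], axis=1)
                partners = [
                    heavies[int(np.argmin(d))]
                ] if d.min() <= _MAX_DH_BOND_NM else []
            for j in partners:
                donors.append((int(j), int(h)))
    return donors, sorted(acceptors)


def _residue_of(u: mda.Universe, idx: int) -> tuple[str, int]:
    atom = u.atoms[idx]
    return (atom.resname, int(atom.resid))


def _frame_pairs(
    traj: Trajectory,
    residue_ids: set[int],
    criteria: HBondCriteria,
) -> Iterable[tuple[float, set[tuple], list]]:
    """Yield (time_ps, residue-pair set, bond list) per frame, side-chain
    bonds between residues of interest only."""
    u = traj.universe
    sel = u.select_atoms("resid " + " ".join(map(str, sorted(residue_ids))))
    donors, acceptors = find_donors_acceptors(sel, sidechain_only=True)
    for ts in u.trajectory:
        pos = u.atoms.positions / 10.0
        bonds = detect_hbonds(pos, donors, acceptors, criteria)
        pairs = set()
        kept = []
        for d, h, a in bonds:
            ra, rb = _residue_of(u, d), _residue_of(u, a)
            if ra[1] == rb[1]:
                continue  # intra-residue contacts are not network edges
            pairs.add(tuple(sorted((ra, rb))))
            kept.append((d, h, a))
        yield float(ts.time), pairs, kept


def occurrence_network(
    trajectories: Sequence[Trajectory],
    residue_ids: Iterable[int],
    criteria: HBondCriteria | None = None,
    equilibration_ps: float = 0.0,
) -> nx.Graph:
    """Residue-pair graph weighted by H-bond frame occurrence.

    Edge attributes: ``count`` (frames with ≥1 side-chain H-bond in either
    direction, pooled over replicates), ``occupancy`` = count / frames
    analysed, and per-replicate counts.  Frames before ``equilibration_ps``
    are discarded.
    """
    criteria = criteria or HBondCriteria()
    residue_ids = set(residue_ids)
    g = nx.Graph()
    frames_total = 0
    for traj in trajectories:
        for rid in sorted(residue_ids):
            sel = traj.universe.select_atoms(f"resid {rid}")
            if len(sel):
                g.add_node(f"{sel.resnames[0]}{rid}")
        for t_ps, pairs, _ in _frame_pairs(traj, residue_ids, criteria):
            if t_ps < equilibration_ps:
                continue
            frames_total += 1
            for (ra, rb) in pairs:
                na, nb = f"{ra[0]}{ra[1]}", f"{rb[0]}{rb[1]}"
                if not g.has_edge(na, nb):
                    g.add_edge(na, nb, count=0, per_replicate={})
                g[na][nb]["count"] += 1
                per = g[na][nb]["per_replicate"]
                per[traj.replicate] = per.get(traj.replicate, 0) + 1
    g.graph["frames_analysed"] = frames_total
    for _, _, d in g.edges(data=True):
        d["occupancy"] = d["count"] / frames_total if frames_total else 0.0
    return g


def hbond_count_series(
    trajectories: Sequence[Trajectory],
    residue_a: int,
    residue_b: int,
    criteria: HBondCriteria | None = None,
    equilibration_ps: float = 0.0,
) -> dict:
    """Per-frame number of simultaneous distinct H-bonds between two
    residues, with median and IQR over pooled frames."""
    criteria = criteria or HBondCriteria()
    counts, times, replicates = [], [], []
    for traj in trajectories:
        for t_ps, _, bonds in _frame_pairs(traj, {residue_a, residue_b}, criteria):
            if t_ps < equilibration_ps:
                continue
            u = traj.universe
            n = sum(
                1
                for d, h, a in bonds
                if {_residue_of(u, d)[1], _residue_of(u, a)[1]}
                == {residue_a, residue_b}
            )
            counts.append(n)
            times.append(t_ps)
            replicates.append(traj.replicate)
    counts = np.array(counts, float)
    return {
        "times_ps": np.array(times),
        "replicates": replicates,
        "counts": counts,
        "median": float(np.median(counts)) if counts.size else np.nan,
        "iqr": float(np.percentile(counts, 75) - np.percentile(counts, 25))
        if counts.size
        else np.nan,
    }


@dataclass
class DistanceSeries:
    times_ps: np.ndarray
    distances_nm: np.ndarray


def atom_distance_series(
    traj: Trajectory, selection_a: str, selection_b: str
) -> DistanceSeries:
    """Euclidean distance (nm) between two single atoms per frame."""
    u = traj.universe
    ga, gb = u.select_atoms(selection_a), u.select_atoms(selection_b)
    for name, g in (("a", ga), ("b", gb)):
        if len(g) != 1:
            raise ValueError(
                f"selection {name!r} must match exactly one atom; matched "
                f"{[f'{x.resname}{x.resid}:{x.name}' for x in g]}"
            )
    if ga.indices[0] == gb.indices[0]:
        raise ValueError("both selections resolve to the same atom")
    times, dist = [], []
    for ts in u.trajectory:
        times.append(float(ts.time))
        dist.append(float(np.linalg.norm(ga.positions[0] - gb.positions[0]) / 10.0))
    return DistanceSeries(np.array(times), np.array(dist))


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto ref."""
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, rc - r @ mc


def superposed_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray,
    rmsd_indices: np.ndarray,
) -> float:
    """RMSD over ``rmsd_indices`` after least-squares superposition of
    ``mobile`` onto ``reference`` over ``fit_indices`` (float64 throughout;
    exactly zero, to rounding, under any rigid motion of the mobile frame).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    r, t = _kabsch(mobile[fit_indices], reference[fit_indices])
    moved = mobile[rmsd_indices] @ r.T + t
    diff = moved - reference[rmsd_indices]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


@dataclass
class RMSDSeries:
    times_ps: np.ndarray
    rmsd_nm: np.ndarray
    replicates: list[str]
    median: float
    iqr: float
    per_replicate_median: dict[str, float]


def sidechain_rmsd_series(
    trajectories: Sequence[Trajectory],
    reference: Trajectory | None,
    residue_ids: Iterable[int],
    fit_selection: str = "backbone",
    equilibration_ps: float = 0.0,
) -> RMSDSeries:
    """Side-chain RMSD of a residue set after superposition, per frame.

    Each frame is least-squares superposed onto the reference (its first
    frame; by default the first trajectory's first frame) over
    ``fit_selection`` (whole-protein backbone by default — sensitive to
    internal side-chain motion, i.e. a rigidity measure), then RMSD is taken
    over side-chain heavy atoms of ``residue_ids``.  Reports median and
    interquartile range pooled and per replicate.
    """
    residue_ids = sorted(set(residue_ids))
    reference = reference or trajectories[0]
    uref = reference.universe
    uref.trajectory[0]
    fit_ref = uref.select_atoms(fit_selection).positions.copy() / 10.0

    def sidechain_group(u):
        sel = u.select_atoms(
            "resid " + " ".join(map(str, residue_ids))
        )
        g = sel.select_atoms(
            "not name " + " ".join(_BACKBONE_NAMES) + " and not element H",
        )
        if not len(g):
            # element record may be absent; fall back to name-based H filter
            g = sel.select_atoms("not name " + " ".join(_BACKBONE_NAMES))
            g = g[[not a.name.startswith("H") for a in g]]
        return g

    for rid in residue_ids:
        res = uref.select_atoms(f"resid {rid}")
        if len(res) and res.resnames[0] == "GLY":
            raise ValueError(f"residue {rid} (GLY) has no side chain")
    sc_ref_group = sidechain_group(uref)
    sc_ref = sc_ref_group.positions.copy() / 10.0

    times, vals, reps = [], [], []
    for traj in trajectories:
        u = traj.universe
        fit_g = u.select_atoms(fit_selection)
        sc_g = sidechain_group(u)
        if len(sc_g) != len(sc_ref_group):
            raise ValueError("side-chain selection differs from reference topology")
        for ts in u.trajectory:
            if ts.time < equilibration_ps:
                continue
            r, t = _kabsch(fit_g.positions / 10.0, fit_ref)
            moved = (sc_g.positions.astype(float) / 10.0) @ r.T + t
            rmsd = float(np.sqrt(np.mean(np.sum((moved - sc_ref) ** 2, axis=1))))
            times.append(float(ts.time))
            vals.append(rmsd)
            reps.append(traj.replicate)
    vals_arr = np.array(vals)
    per_rep = {
        rep: float(np.median(vals_arr[[r == rep for r in reps]]))
        for rep in dict.fromkeys(reps)
    }
    return RMSDSeries(
        times_ps=np.array(times),
        rmsd_nm=vals_arr,
        replicates=reps,
        median=float(np.median(vals_arr)) if vals_arr.size else np.nan,
        iqr=float(np.percentile(vals_arr, 75) - np.percentile(vals_arr, 25))
        if vals_arr.size
        else np.nan,
        per_replicate_median=per_rep,
    )


def equilibration_start_ps(
    traj: Trajectory,
    fit_selection: str = "backbone",
    window_ps: float = 1000.0,
    tolerance: float = 0.05,
) -> float:
    """Equilibration cut from a steady-state RMSD criterion.

    Returns the first time at which the running mean of the global RMSD (to
    the first frame, after superposition) changes by less than ``tolerance``
    (relative) over a ``window_ps`` window.
    """
    u = traj.universe
    u.trajectory[0]
    g = u.select_atoms(fit_selection)
    ref = g.positions.copy() / 10.0
    times, rmsds = [], []
    for ts in u.trajectory:
        r, t = _kabsch(g.positions / 10.0, ref)
        moved = (g.positions / 10.0) @ r.T + t
        rmsds.append(float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))))
        times.append(float(ts.time))
    times, rmsds = np.array(times), np.array(rmsds)
    run_mean = np.cumsum(rmsds) / (np.arange(len(rmsds)) + 1)
    for i, t0 in enumerate(times):
        j = np.searchsorted(times, t0 + window_ps)
        if j >= len(times):
            break
        lo, hi = run_mean[i], run_mean[j]
        if lo > 0 and abs(hi - lo) / lo < tolerance:
            return float(t0)
    return float(times[0])
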