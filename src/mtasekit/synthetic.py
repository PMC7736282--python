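"""Synthetic fixtures with known ground truth for every pipeline stage.

No data accessions exist for the original measurements, so each analysis
stage is exercised on generated inputs whose generating parameters are the
truth the stage must recover: two-/three-state tryptophan melts rendered as
emission spectra, linear-then-saturating resorufin traces, toy structures
with hand-placed side-chain geometry, harmonic-fluctuation toy trajectories
with a switchable hydrogen-bond schedule, and mutation-derived sequence
families with controlled identity and planted residues.

Every generator is deterministic under a fixed seed and returns a
machine-readable truth record alongside the data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mtasekit.activity import KineticTrace
from mtasekit.family import SequenceRecord
from mtasekit.melt import EmissionSpectrum, double_sigmoid, single_sigmoid

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# melt spectra


def gen_melt_spectra(
    T_m1: float,
    a: float,
    bcm_N: float,
    bcm_D: float,
    T_m2: float | None = None,
    b: float | None = None,
    bcm_2: float | None = None,
    noise_sd: float = 0.0,
    temperatures: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    peak_width: float = 25.0,
    seed: int = 0,
) -> tuple[list[EmissionSpectrum], dict]:
    """Emission spectra over a temperature ramp with a sigmoidal melt.

    Spectra are two-Gaussian mixtures (folded centre ``bcm_N``, unfolded
    centre ``bcm_D``, width 25 nm); the mixing fraction follows the same
    sigmoid the melt fit assumes, so the analytic barycentric mean equals
    the model curve before noise.  ``noise_sd`` is the nm-equivalent
    standard deviation of the barycentric mean induced by multiplicative
    intensity noise.  Three-state melts add an intermediate centre
    ``bcm_2`` with midpoints ``T_m1 < T_m2``.
    """
    if bcm_D <= bcm_N:
        raise ValueError("bcm_D must exceed bcm_N (unfolding red-shifts)")
    if not (300 <= bcm_N <= 450 and 300 <= bcm_D <= 450):
        raise ValueError("bcm values must lie within 300-450 nm")
    rng = np.random.default_rng(seed)
    T = (
        np.arange(25.0, 91.0, 1.0)
        if temperatures is None
        else np.asarray(temperatures, float)
    )
    # window wide enough that Gaussian truncation does not bias the bcm
    lam = (
        np.arange(260.0, 461.0, 1.0)
        if wavelengths is None
        else np.asarray(wavelengths, float)
    )

    def gauss(center: float) -> np.ndarray:
        return np.exp(-0.5 * ((lam - center) / peak_width) ** 2)

    g_n, g_d = gauss(bcm_N), gauss(bcm_D)
    g_2 = gauss(bcm_2) if bcm_2 is not None else None

    spectra = []
    for t in T:
        f1 = 1.0 / (1.0 + np.exp((T_m1 - t) / a))
        if T_m2 is not None:
            f2 = 1.0 / (1.0 + np.exp((T_m2 - t) / (b if b is not None else a)))
            intens = (1 - f1) * g_n + (f1 - f1 * f2) * g_2 + f1 * f2 * g_d \
                if g_2 is not None else (1 - f1) * g_n + f1 * g_d
            # weights: native (1-f1), intermediate f1(1-f2), denatured f1·f2
        else:
            intens = (1 - f1) * g_n + f1 * g_d
        if noise_sd > 0:
            total = intens.sum()
            bcm = (lam * intens).sum() / total
            spread = np.sqrt((intens**2 * (lam - bcm) ** 2).sum()) / total
            cv = noise_sd / spread
            intens = np.clip(intens * (1 + rng.normal(0, cv, lam.shape)), 0, None)
        spectra.append(EmissionSpectrum(float(t), lam.copy(), intens))
    truth = {
        "T_m1": T_m1,
        "a": a,
        "T_m2": T_m2,
        "b": b,
        "bcm_N": bcm_N,
        "bcm_D": bcm_D,
        "bcm_2": bcm_2,
        "red_shift": bcm_D - bcm_N,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return spectra, truth


# ---------------------------------------------------------------------------
# kinetic traces


def gen_kinetic_traces(
    true_ratio_per_variant: Mapping[str, float],
    wt_rate: float = 100.0,
    ko_rate: float = 5.0,
    noise_cv: float = 0.05,
    saturation_time: float | None = None,
    replicates: int = 3,
    times: np.ndarray | None = None,
    baseline: float = 50.0,
    seed: int = 0,
) -> tuple[dict[str, list[KineticTrace]], dict]:
    """Linear-then-plateau resorufin traces for a panel of variants.

    Each variant's underlying rate is ``ko_rate + ratio·(wt_rate − ko_rate)``;
    'WT' and 'KO' traces are always included.  Replicate rates vary with
    coefficient of variation ``noise_cv`` and points carry additive
    measurement noise of the same relative scale.
    """
    if not wt_rate > ko_rate >= 0:
        raise ValueError("need wt_rate > ko_rate >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 31.0, 1.0) if times is None else np.asarray(times, float)
    panel = {"WT": 1.0, "KO": 0.0, **dict(true_ratio_per_variant)}
    traces: dict[str, list[KineticTrace]] = {}
    for name, ratio in panel.items():
        rate = ko_rate + ratio * (wt_rate - ko_rate)
        traces[name] = []
        for _ in range(replicates):
            r = rate * (1 + rng.normal(0, noise_cv)) if noise_cv > 0 else rate
            t_eff = np.minimum(t, saturation_time) if saturation_time else t
            y = baseline + r * t_eff
            if noise_cv > 0:
                y = y + rng.normal(0, noise_cv * max(rate, 1e-9), t.shape)
            traces[name].append(KineticTrace(t.copy(), y, sample=name))
    truth = {
        "ratios": dict(panel),
        "wt_rate": wt_rate,
        "ko_rate": ko_rate,
        "noise_cv": noise_cv,
        "saturation_time": saturation_time,
        "seed": seed,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# toy structures


def _pdb_atom(serial, name, resname, chain, resnum, xyz, element) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
        f"{element:>2s}\n"
    )


def gen_toy_structure(
    sidechain_x: Sequence[float],
    focal_index: int = 0,
    chain: str = "A",
) -> tuple[str, dict]:
    """Linear toy protein whose side-chain x-positions are given exactly.

    Residue ``i`` is an alanine-like residue with backbone N/CA/C/O offset
    in y and a single side-chain CB atom at ``(sidechain_x[i], 0, 0)`` Å, so
    all side-chain–side-chain distances are the |Δx| the caller chose.  The
    focal residue is built as a lysine with its Nζ co-located with CB.
    """
    lines = ["REMARK synthetic toy structure (generated fixture)\n"]
    serial = 1
    truth_pos = {}
    for i, x in enumerate(sidechain_x):
        resnum = i + 1
        resname = "LYS" if i == focal_index else "ALA"
        for name, off, el in (
            ("N", (-0.5, 2.0, 0.0), "N"),
            ("CA", (0.0, 2.0, 0.0), "C"),
            ("C", (0.5, 2.0, 0.0), "C"),
            ("O", (0.5, 3.0, 0.0), "O"),
        ):
            lines.append(
                _pdb_atom(serial, name, resname, chain, resnum,
                          (x + off[0], off[1], off[2]), el)
            )
            serial += 1
        lines.append(_pdb_atom(serial, "CB", resname, chain, resnum, (x, 0, 0), "C"))
        serial += 1
        if i == focal_index:
            lines.append(
                _pdb_atom(serial, "NZ", resname, chain, resnum, (x, 0, 0.01), "N")
            )
            serial += 1
        truth_pos[resnum] = float(x)
    lines.append("END\n")
    truth = {"sidechain_x": truth_pos, "focal_residue": focal_index + 1}
    return "".join(lines), truth


# hand-placed coordinates reproducing the enzyme's active-site geometry:
# first shell of the catalytic lysine = D138/E207/R209 (within 4 Å of its
# side chain), K41's Nζ contacts L42/E207/Q198/A201 (within 4 Å), and
# K41/L42/Q198/A201 sit beyond 6 Å of the catalytic Nζ (third shell).
_MIMIC = [
    # resname, resnum, [(atom, element, xyz), ...] — side chains only listed
    ("LYS", 175, [("CB", "C", (0.0, 0.0, 1.5)), ("NZ", "N", (0.0, 0.0, 0.0))]),
    ("ASP", 138, [("CB", "C", (-4.4, 0.0, 0.8)), ("OD1", "O", (-3.0, 0.0, 0.0))]),
    ("GLU", 207, [("CB", "C", (3.9, 0.8, 2.2)), ("OE1", "O", (3.0, 0.0, 1.0)),
                  ("OE2", "O", (4.8, 0.0, 1.0))]),
    ("ARG", 209, [("CB", "C", (0.8, 0.0, -4.3)), ("NH1", "N", (0.0, 0.0, -3.0))]),
    ("LYS", 41, [("CB", "C", (7.0, 0.0, 1.5)), ("NZ", "N", (7.0, 0.0, 0.0))]),
    ("LEU", 42, [("CB", "C", (10.2, 0.0, 1.2)), ("CD1", "C", (9.5, 0.0, 0.0))]),
    ("GLN", 198, [("CB", "C", (7.0, 4.1, 0.9)), ("NE2", "N", (7.0, 2.8, 0.0))]),
    ("ALA", 201, [("CB", "C", (7.0, -2.9, 0.0))]),
    ("TYR", 66, [("CB", "C", (0.8, 6.3, 0.6)), ("OH", "O", (0.0, 5.0, 0.0))]),
    ("GLU", 46, [("CB", "C", (-5.6, 3.0, 0.7)), ("OE1", "O", (-4.5, 2.0, 0.0))]),
]


def gen_activesite_mimic(chain: str = "A") -> tuple[str, dict]:
    """Synthetic stand-in for the enzyme's active site (PDB text).

    Coordinates are hand-placed (not crystallographic) so that shell
    assignment around the catalytic lysine reproduces the published residue
    lists: first shell {D138, E207, R209}; Nζ(K41) 4-Å side-chain neighbors
    {L42, E207, Q198, A201}; K41/L42/Q198/A201 in the third shell.
    """
    lines = ["REMARK synthetic active-site mimic (generated fixture, not 1vp3)\n"]
    serial = 1
    for resname, resnum, sidechain in sorted(_MIMIC, key=lambda r: r[1]):
        cx = sidechain[0][2][0]
        for name, off, el in (
            ("N", -0.5, "N"), ("CA", 0.0, "C"), ("C", 0.5, "C"),
        ):
            lines.append(
                _pdb_atom(serial, name, resname, chain, resnum, (cx + off, 9.0, 0), el)
            )
            serial += 1
        lines.append(_pdb_atom(serial, "O", resname, chain, resnum, (cx + 0.5, 10.0, 0), "O"))
        serial += 1
        for name, el, xyz in sidechain:
            lines.append(_pdb_atom(serial, name, resname, chain, resnum, xyz, el))
            serial += 1
    lines.append("END\n")
    truth = {
        "focal": 175,
        "first_shell": {"D138", "E207", "R209"},
        "k41_nz_neighbors": {"L42", "E207", "Q198", "A201"},
        "third_shell_members": {"K41", "L42", "Q198", "A201"},
    }
    return "".join(lines), truth


# ---------------------------------------------------------------------------
# toy trajectories

_RES_SPACING = 12.0  # Å between toy residues: far outside any H-bond cutoff
_SC_NAMES = {"CB", "OG", "HG"}


def _toy_residue_atoms(x: float) -> list[tuple[str, str, np.ndarray]]:
    return [
        ("N", "N", np.array([x - 1.2, 1.0, 0.0])),
        ("CA", "C", np.array([x, 1.0, 0.0])),
        ("C", "C", np.array([x + 1.2, 1.0, 0.0])),
        ("O", "O", np.array([x + 1.2, 2.2, 0.0])),
        ("CB", "C", np.array([x, -0.5, 0.0])),
        ("OG", "O", np.array([x, -2.0, 0.0])),
        ("HG", "H", np.array([x, -2.0, 0.97])),
    ]


def gen_toy_trajectory(
    n_residues: int = 4,
    n_frames: int = 100,
    sigma_nm: float = 0.0,
    hbond_schedule: Mapping[tuple[int, int], Sequence[int] | float] | None = None,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """Serine-like toy trajectory: topology PDB + multi-model frame PDB text.

    Residues sit 1.2 nm apart (no accidental contacts).  ``hbond_schedule``
    maps a residue pair (1-based ids) to either the fraction of frames or an
    explicit frame-index list in which the pair is placed in hydrogen-bond
    geometry (O···O 0.29 nm, H–D–A angle 10°); all other frames keep them
    out of cutoff.  ``sigma_nm`` is the per-atom isotropic fluctuation
    applied to side-chain atoms not constrained by the schedule; backbone
    atoms stay fixed so superposition is exact and the RMSD expectation has
    a closed form.
    """
    rng = np.random.default_rng(seed)
    base: list[tuple[str, str, int, np.ndarray]] = []
    for i in range(n_residues):
        for name, el, xyz in _toy_residue_atoms(i * _RES_SPACING):
            base.append((name, el, i + 1, xyz))
    index = {(resnum, name): k for k, (name, _, resnum, _) in enumerate(base)}

    schedule_frames: dict[tuple[int, int], set[int]] = {}
    for pair, spec in (hbond_schedule or {}).items():
        a, b = sorted(pair)
        if isinstance(spec, float):
            k = int(round(spec * n_frames))
            frames = set(rng.choice(n_frames, size=k, replace=False).tolist())
        else:
            frames = set(int(f) for f in spec)
        schedule_frames[(a, b)] = frames

    frames_xyz = []
    for f in range(n_frames):
        xyz = np.array([p for *_, p in base], float)
        pinned: set[int] = set()
        for (a, b), frames in schedule_frames.items():
            ia_og, ia_hg = index[(a, "OG")], index[(a, "HG")]
            ib_og, ib_hg = index[(b, "OG")], index[(b, "HG")]
            if f in frames:
                mid = 0.5 * (xyz[index[(a, "CA")], 0] + xyz[index[(b, "CA")], 0])
                d_pos = np.array([mid - 1.45, -2.0, 0.0])
                a_pos = np.array([mid + 1.45, -2.0, 0.0])
                xyz[ia_og] = d_pos
                ang = np.radians(10.0)
                xyz[ia_hg] = d_pos + 0.97 * np.array([np.cos(ang), np.sin(ang), 0.0])
                xyz[ib_og] = a_pos
                xyz[ib_hg] = a_pos + np.array([0.0, 0.0, 0.97])
                pinned |= {ia_og, ia_hg, ib_og, ib_hg}
        if sigma_nm > 0:
            for k, (name, _, resnum, _) in enumerate(base):
                if name in _SC_NAMES and k not in pinned:
                    xyz[k] = xyz[k] + rng.normal(0, sigma_nm * 10.0, 3)
        frames_xyz.append(xyz)

    def render(xyz: np.ndarray) -> str:
        out = []
        for serial, ((name, el, resnum, _), p) in enumerate(zip(base, xyz), 1):
            out.append(_pdb_atom(serial, name, "SER", "A", resnum, p, el))
        return "".join(out)

    topology = (
        "REMARK synthetic toy topology (noiseless base geometry)\n"
        + render(np.array([p for *_, p in base], float))
        + "END\n"
    )
    frames_txt = []
    for f, xyz in enumerate(frames_xyz, 1):
        frames_txt.append(f"MODEL     {f:4d}\n" + render(xyz) + "ENDMDL\n")
    truth = {
        "n_frames": n_frames,
        "sigma_nm": sigma_nm,
        "schedule": {k: sorted(v) for k, v in schedule_frames.items()},
        "occupancy": {
            k: len(v) / n_frames for k, v in schedule_frames.items()
        },
        "seed": seed,
    }
    return topology, "".join(frames_txt), truth


# ---------------------------------------------------------------------------
# sequence families


def gen_sequence_family(
    root_length: int = 300,
    clades: Sequence[tuple[int, float]] = ((10, 0.9), (10, 0.5)),
    planted_position: int = 41,
    planted_residue: str = "D",
    n_planted: int = 0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict]:
    """Mutation-derived family around a random root sequence.

    Each clade contributes ``n`` members at a target fractional identity to
    the root, realised by substituting exactly ``round((1−identity)·L)``
    positions.  The root carries a lysine at ``planted_position``; the first
    ``n_planted`` members of the *last* clade carry ``planted_residue``
    there instead (emulating the orthologs that replace the conserved lysine
    with an aspartate), and the column is never mutated otherwise.  With no
    indels the family doubles as its own alignment.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    root = rng.choice(aa, root_length)
    root[planted_position - 1] = "K"
    records = [SequenceRecord("ROOT", "".join(root))]
    truth_identity = {}
    planted_ids = []
    remaining_planted = n_planted
    for ci, (n, ident) in enumerate(clades):
        n_mut = int(round((1 - ident) * root_length))
        for mi in range(n):
            name = f"C{ci}_{mi}"
            seq = root.copy()
            allowed = [p for p in range(root_length) if p != planted_position - 1]
            sites = rng.choice(allowed, size=min(n_mut, len(allowed)), replace=False)
            for p in sites:
                choices = [c for c in AMINO_ACIDS if c != seq[p]]
                seq[p] = choices[rng.integers(len(choices))]
            if ci == len(clades) - 1 and remaining_planted > 0:
                seq[planted_position - 1] = planted_residue
                planted_ids.append(name)
                remaining_planted -= 1
            records.append(SequenceRecord(name, "".join(seq)))
            truth_identity[name] = 1 - len(sites) / root_length
    truth = {
        "root": records[0].sequence,
        "identity_to_root": truth_identity,
        "planted_position": planted_position,
        "planted_residue": planted_residue,
        "planted_ids": planted_ids,
        "seed": seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# full study bundle

#: (T_m1 °C, red-shift nm, activity ratio) per variant: a panel emulating the
#: qualitative picture of the mutagenesis study — a rescue double mutant with
#: positive-activity/negative-stability epistasis, an inactive-but-stable
#: knock-out, a misfolded low-shift variant and penalised single mutants.
DEFAULT_PANEL: dict[str, tuple[float, float, float]] = {
    "WT": (60.0, 7.8, 1.00),
    "K175C": (60.0, 7.8, 0.00),   # knock-out control
    "K41D": (54.0, 7.8, 0.05),
    "A201K": (54.0, 7.8, 1.00),
    "A201R": (60.0, 7.8, 1.20),
    "A201G": (53.0, 7.8, 0.51),
    "K41D-A201K": (46.0, 7.8, 0.00),  # −2 °C below additivity: negative epistasis
    "K41D-A201R": (58.0, 7.8, 1.70),
    "A201Q": (52.0, 5.0, 0.00),
}

#: fitness class implied by DEFAULT_PANEL under the default thresholds
DEFAULT_PANEL_CLASSES: dict[str, str] = {
    "WT": "wt_like",
    "K175C": "inactive_stable",
    "K41D": "activity_and_stability_penalty",
    "A201K": "stability_penalty",
    "A201R": "wt_like",
    "A201G": "activity_and_stability_penalty",
    "K41D-A201K": "inactive_unstable",
    "K41D-A201R": "wt_like",
    "A201Q": "misfolded",
}


def gen_study_bundle(
    out_dir,
    seed: int = 0,
    panel: Mapping[str, tuple[float, float, float]] | None = None,
    melt_noise_sd: float = 0.1,
    activity_noise_cv: float = 0.05,
    replicates: int = 3,
) -> dict:
    """Write a complete synthetic variant study (spectra.csv + traces.csv).

    Emulates the full measurement campaign for a variant panel: triplicate
    melt spectra per variant and triplicate kinetic traces, with the panel's
    (T_m1, red-shift, activity) triples as ground truth.  Variants with a
    planted activity of exactly 0 follow the knock-out signal and should be
    flagged below detection downstream.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = dict(panel or DEFAULT_PANEL)
    rows = ["sample,replicate,temperature,wavelength,intensity\n"]
    for i, (name, (tm, shift, _)) in enumerate(panel.items()):
        for rep in range(1, replicates + 1):
            spectra, _ = gen_melt_spectra(
                T_m1=tm, a=2.0, bcm_N=352.2, bcm_D=352.2 + shift,
                noise_sd=melt_noise_sd, seed=seed + 1000 * i + rep,
            )
            for sp in spectra:
                for lam, inten in zip(sp.wavelengths, sp.intensities):
                    rows.append(
                        f"{name},{rep},{sp.temperature},{lam},{inten:.6g}\n"
                    )
    (out / "spectra.csv").write_text("".join(rows))

    ratios = {n: act for n, (_, _, act) in panel.items() if n not in ("WT", "K175C")}
    traces, _ = gen_kinetic_traces(
        ratios, noise_cv=activity_noise_cv, replicates=replicates,
        seed=seed + 999_983,
    )
    traces["K175C"] = traces.pop("KO")
    write_traces_csv(traces, out / "traces.csv")
    return {
        "panel": panel,
        "classes": {
            n: DEFAULT_PANEL_CLASSES.get(n) for n in panel
        } if panel.keys() == DEFAULT_PANEL.keys() else {"panel": "custom"},
        "spectra": str(out / "spectra.csv"),
        "traces": str(out / "traces.csv"),
        "seed": seed,
    }


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_spectra_csv(spectra_by_sample: Mapping[str, Sequence[EmissionSpectrum]], path) -> None:
    """Long-format spectra table: sample, temperature, wavelength, intensity."""
    with open(path, "w") as fh:
        fh.write("sample,temperature,wavelength,intensity\n")
        for sample, spectra in spectra_by_sample.items():
            for sp in spectra:
                for lam, inten in zip(sp.wavelengths, sp.intensities):
                    fh.write(f"{sample},{sp.temperature},{lam},{inten}\n")


def write_traces_csv(traces: Mapping[str, Sequence[KineticTrace]], path) -> None:
    """Long-format kinetic table: sample, replicate, time_min, intensity."""
    with open(path, "w") as fh:
        fh.write("sample,replicate,time_min,intensity\n")
        for sample, reps in traces.items():
            for ri, tr in enumerate(reps, 1):
                for t, y in zip(tr.times, tr.intensities):
                    fh.write(f"{sample},{ri},{t},{y}\n")


def write_blast_tabular(hits, path) -> None:
    """12-column BLAST-style tabular hit file."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                        str(h.alignment_length), "0", "0", "1",
                        str(h.alignment_length), "1", str(h.alignment_length),
                        f"{h.e_value:.3e}", "0",
                    ]
                )
                + "\n"
            )
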