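import pathlib

import pytest

from mtasekit import synthetic as syn
from mtasekit.structures import read_structure
from mtasekit.trajectory import read_trajectory


@pytest.fixture(scope="session")
def mimic_structure(tmp_path_factory):
    """Synthetic active-site mimic with known shell membership."""
    d = tmp_path_factory.mktemp("mimic")
    pdb, truth = syn.gen_activesite_mimic()
    path = d / "mimic.pdb"
    path.write_text(pdb)
    return read_structure(path), truth


@pytest.fixture(scope="session")
def toy_structure(tmp_path_factory):
    """Three-residue toy with side chains at x = 0, 3, 10 Å."""
    d = tmp_path_factory.mktemp("toy")
    pdb, truth = syn.gen_toy_structure([0.0, 3.0, 10.0])
    path = d / "toy.pdb"
    path.write_text(pdb)
    return read_structure(path), truth


def make_trajectory(tmp_path, name="traj", replicate="r1", **kwargs):
    top, frames, truth = syn.gen_toy_trajectory(**kwargs)
    (tmp_path / f"{name}_top.pdb").write_text(top)
    (tmp_path / f"{name}_frames.pdb").write_text(frames)
    traj = read_trajectory(
        tmp_path / f"{name}_top.pdb",
        tmp_path / f"{name}_frames.pdb",
        replicate=replicate,
    )
    ref = read_trajectory(tmp_path / f"{name}_top.pdb", replicate="ref")
    return traj, ref, truth
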