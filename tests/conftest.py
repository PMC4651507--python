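import numpy as np
import pytest

from tsbind.trajectory_io import Atom, StructureFrame, Trajectory


def make_atom(serial=1, name="CA", element="C", res_name="ALA", res_seq=1,
              chain="A", xyz=(0.0, 0.0, 0.0)):
    return Atom(serial=serial, name=name, element=element, res_name=res_name,
                res_seq=res_seq, chain=chain, xyz=tuple(xyz))


def make_frame(coords, frame_index=0, names=None, res_seqs=None, elements=None,
               res_names=None, chains=None, time_ps=0.0):
    """Build a StructureFrame from an (n, 3) coordinate array plus metadata lists."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["CA"] * n
    elements = elements or [nm[0] for nm in names]
    res_seqs = res_seqs or list(range(1, n + 1))
    res_names = res_names or ["ALA"] * n
    chains = chains or ["A"] * n
    atoms = [
        make_atom(serial=i + 1, name=names[i], element=elements[i],
                  res_name=res_names[i], res_seq=res_seqs[i], chain=chains[i],
                  xyz=coords[i])
        for i in range(n)
    ]
    return StructureFrame(frame_index=frame_index, time_ps=time_ps, atoms=atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def two_frame_traj():
    """Tiny 2-frame, 5-atom trajectory with distinct coordinates per frame."""
    base = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [1.5, 1.5, 0.0],
                     [0.0, 1.5, 1.5], [3.0, 3.0, 3.0]])
    names = ["N", "CA", "C", "O", "CB"]
    frames = [
        make_frame(base + 0.25 * i, frame_index=i, names=names,
                   res_seqs=[1, 1, 1, 1, 1], time_ps=10.0 * i)
        for i in range(2)
    ]
    return Trajectory(frames)


def random_rotation(rng):
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
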