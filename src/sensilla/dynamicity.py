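"""Per-atom explored-volume ("dynamicity") analysis of molecular trajectories.

Given a trajectory of a protein (e.g. from MD production runs, supplied as
multi-model PDB or XYZ), the analysis proceeds in three stages:

1. every frame is superposed onto a reference frame by the optimal
   least-squares rigid transform (Kabsch algorithm, proper rotation enforced),
   removing global tumbling and drift;
2. for each atom, the volume of the 3-D convex hull of its positions across
   all frames — the *explored volume* V_i (Angstrom^3) — quantifies its
   mobility; dividing by the number of frames gives the per-step volume
   v_i = V_i / n_frames;
3. profiles from a liganded (holo) and an unliganded (apo) trajectory are
   compared atom-by-atom as the ratio R_i = v_i(holo) / v_i(apo): mean R < 1
   indicates global rigidification upon ligand binding, while localized
   regions of R > 1 (e.g. an intracellular loop) flag allosteric mobilization.

The trajectory must already be periodic-boundary-corrected (unwrapped); a
bond-length sanity check guards against wrapped inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Trajectory",
    "DynamicityProfile",
    "read_trajectory",
    "write_trajectory",
    "concatenate_replicas",
    "superpose_frames",
    "kabsch",
    "atom_explored_volume",
    "dynamicity_profile",
    "relative_dynamicity",
]


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Angstrom) with atom/residue metadata."""

    coords: np.ndarray
    residue_ids: np.ndarray | None = None
    atom_names: np.ndarray | None = None
    replica_ids: np.ndarray | None = None
    frame_spacing_ns: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if self.residue_ids is None:
            self.residue_ids = np.arange(self.n_atoms) + 1
        self.residue_ids = np.asarray(self.residue_ids)
        if len(self.residue_ids) != self.n_atoms:
            raise ValueError("residue_ids length mismatch")
        if self.atom_names is None:
            self.atom_names = np.array(["CA"] * self.n_atoms, dtype=object)
        if self.replica_ids is None:
            self.replica_ids = np.zeros(self.n_frames, dtype=int)
        self.replica_ids = np.asarray(self.replica_ids)
        if len(self.replica_ids) != self.n_frames:
            raise ValueError("replica_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def same_atom_map(self, other: "Trajectory") -> bool:
        return (self.n_atoms == other.n_atoms
                and np.array_equal(self.residue_ids, other.residue_ids))


@dataclass
class DynamicityProfile:
    """Per-atom explored volumes of a superposed trajectory.

    ``explored_volume`` is V_i (Angstrom^3), ``per_step_volume`` is
    v_i = V_i / n_frames, ``degenerate`` flags atoms whose positions were
    coplanar/collinear (volume reported as 0).
    """

    explored_volume: np.ndarray
    per_step_volume: np.ndarray
    degenerate: np.ndarray
    residue_ids: np.ndarray
    n_frames: int

    @property
    def mean_per_step_volume(self) -> float:
        """Summary mobility: mean v_i over all atoms."""
        return float(self.per_step_volume.mean())

    def per_residue(self, how: str = "mean") -> pd.DataFrame:
        """Aggregate v_i per residue (mean over member atoms, or sum)."""
        if how not in ("mean", "sum"):
            raise ValueError("how must be 'mean' or 'sum'")
        df = pd.DataFrame({"residue_id": self.residue_ids,
                           "per_step_volume": self.per_step_volume})
        agg = df.groupby("residue_id")["per_step_volume"].agg(how)
        return agg.reset_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "atom_index": np.arange(len(self.explored_volume)),
            "residue_id": self.residue_ids,
            "explored_volume_A3": self.explored_volume,
            "per_step_volume_A3": self.per_step_volume,
            "degenerate": self.degenerate,
        })


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _read_xyz(path: Path) -> Trajectory:
    frames: list[np.ndarray] = []
    lines = path.read_text().splitlines()
    i = 0
    model = 0
    n_ref = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        model += 1
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"malformed XYZ atom count at line {i + 1}") from exc
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise ValueError(
                f"atom-count mismatch in model {model}: {n} != {n_ref}")
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ValueError(f"truncated XYZ model {model}")
        coords = np.array([[float(v) for v in ln.split()[1:4]]
                           for ln in block])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError("no frames found in XYZ file")
    return Trajectory(np.stack(frames))


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f + 1}\n")
            for name, xyz in zip(traj.atom_names, traj.coords[f]):
                elem = str(name)[:1] or "C"
                fh.write(f"{elem} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def _read_multi_model_pdb(path: Path) -> Trajectory:
    import biotite.structure.io.pdb as pdb
    from biotite.structure import AtomArrayStack

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception:
        # fall back to per-model parsing to report which model is inconsistent
        counts = []
        for m in range(1, pdb_file.get_model_count() + 1):
            counts.append(pdb_file.get_structure(model=m).array_length())
        bad = [i + 1 for i, c in enumerate(counts) if c != counts[0]]
        raise ValueError(
            f"atom-count mismatch between models: model(s) {bad} have "
            f"{[counts[b - 1] for b in bad]} atoms, model 1 has {counts[0]}")
    if not isinstance(stack, AtomArrayStack):
        stack = stack[None, :] if stack.coord.ndim == 2 else stack
    return Trajectory(np.asarray(stack.coord, dtype=float),
                      residue_ids=np.asarray(stack.res_id),
                      atom_names=np.asarray(stack.atom_name, dtype=object))


def _write_multi_model_pdb(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    atoms = struc.AtomArray(traj.n_atoms)
    atoms.coord = traj.coords[0]
    atoms.res_id = np.asarray(traj.residue_ids, dtype=int)
    atoms.res_name = np.array(["GLY"] * traj.n_atoms)
    atoms.atom_name = np.array([str(n) for n in traj.atom_names])
    atoms.element = np.array([str(n)[:1] or "C" for n in traj.atom_names])
    atoms.chain_id = np.array(["A"] * traj.n_atoms)
    stack = struc.stack([atoms] * traj.n_frames)
    stack.coord = traj.coords.copy()
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a trajectory from multi-model PDB or XYZ (coordinates in Angstrom).

    The format is inferred from the suffix unless given.  PDB MODEL order is
    preserved and the residue map taken from the records; XYZ files fall back
    to sequential one-residue-per-atom numbering.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_multi_model_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported trajectory format: {fmt!r}")


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or XYZ."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        _write_multi_model_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")


# --------------------------------------------------------------------------
# Concatenation & superposition
# --------------------------------------------------------------------------

def concatenate_replicas(trajectories: list[Trajectory]) -> Trajectory:
    """Frame-wise concatenation of replica trajectories, preserving replica ids."""
    if not trajectories:
        raise ValueError("no trajectories given")
    first = trajectories[0]
    for i, t in enumerate(trajectories[1:], start=2):
        if not first.same_atom_map(t):
            raise ValueError(f"atom map of replica {i} does not match replica 1")
    coords = np.concatenate([t.coords for t in trajectories], axis=0)
    replica_ids = np.concatenate(
        [np.full(t.n_frames, i) for i, t in enumerate(trajectories)])
    return Trajectory(coords, residue_ids=first.residue_ids,
                      atom_names=first.atom_names, replica_ids=replica_ids,
                      frame_spacing_ns=first.frame_spacing_ns)


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal least-squares rigid superposition (rotation R, translation t).

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the RMSD to
    ``reference``.  A proper rotation (det = +1) is enforced by flipping the
    sign of the smallest singular direction when needed.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    # rank-deficient cross-covariance => collinear points, rotation ambiguous
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("need at least 3 non-collinear atoms for superposition")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose_frames(traj: Trajectory, reference_frame: int = 0,
                     fit_atoms: str | np.ndarray = "all") -> Trajectory:
    """Superpose every frame onto a reference frame of the same trajectory.

    ``fit_atoms`` selects the atom subset used to determine the transform
    ("all", "backbone" for N/CA/C/O atom names, or an index array); the
    transform is then applied to all atoms.  Superposition is idempotent.
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise ValueError("reference_frame out of range")
    if isinstance(fit_atoms, str):
        if fit_atoms == "all":
            sel = np.arange(traj.n_atoms)
        elif fit_atoms == "backbone":
            names = np.asarray([str(n) for n in traj.atom_names])
            sel = np.flatnonzero(np.isin(names, ("N", "CA", "C", "O")))
            if len(sel) < 3:
                raise ValueError("fewer than 3 backbone atoms to fit on")
        else:
            raise ValueError("fit_atoms must be 'all', 'backbone' or indices")
    else:
        sel = np.asarray(fit_atoms, dtype=int)
    ref = traj.coords[reference_frame, sel]
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        rot, trans = kabsch(traj.coords[f, sel], ref)
        out[f] = traj.coords[f] @ rot.T + trans
    return Trajectory(out, residue_ids=traj.residue_ids,
                      atom_names=traj.atom_names, replica_ids=traj.replica_ids,
                      frame_spacing_ns=traj.frame_spacing_ns)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two (n, 3) coordinate sets."""
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2,
                                        axis=1))))


def validate_unwrapped(traj: Trajectory, max_step: float = 10.0) -> bool:
    """Sanity check that the trajectory is PBC-unwrapped.

    Flags frame-to-frame jumps of any atom larger than ``max_step`` Angstrom,
    the signature of coordinates wrapped back across a periodic box.
    """
    if traj.n_frames < 2:
        return True
    jumps = np.linalg.norm(np.diff(traj.coords, axis=0), axis=2)
    if jumps.max() > max_step:
        warnings.warn(
            f"frame-to-frame atom jump of {jumps.max():.1f} A exceeds "
            f"{max_step} A; trajectory may not be PBC-corrected", stacklevel=2)
        return False
    return True


# --------------------------------------------------------------------------
# Explored volumes
# --------------------------------------------------------------------------

def atom_explored_volume(traj: Trajectory, atom_index: int
                         ) -> tuple[float, bool]:
    """Convex-hull volume (Angstrom^3) of one atom's positions across frames.

    Returns ``(volume, degenerate)``; degenerate point sets (fewer than four
    points, or collinear/coplanar positions) yield volume 0 with the flag set
    — a frozen atom explores no volume, which is meaningful, not an error.
    """
    points = traj.coords[:, atom_index, :]
    if len(points) <= 3:
        return 0.0, True
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False


def dynamicity_profile(traj: Trajectory, window: int | None = None
                       ) -> DynamicityProfile:
    """Per-atom explored volumes of a (superposed) trajectory.

    By default one cumulative hull per atom is computed over all frames and
    v_i = V_i / n_frames.  With ``window`` set, the trajectory is split into
    consecutive blocks of that many frames, hull volumes are computed per
    block, and V_i is their mean (v_i then divides by the window length) —
    an alternative reading of "volume explored per step" for long composite
    trajectories.
    """
    n_atoms = traj.n_atoms
    if window is None:
        volumes = np.empty(n_atoms)
        degenerate = np.zeros(n_atoms, dtype=bool)
        for i in range(n_atoms):
            volumes[i], degenerate[i] = atom_explored_volume(traj, i)
        per_step = volumes / traj.n_frames
        n_frames = traj.n_frames
    else:
        if window < 4:
            raise ValueError("window must be >= 4 frames for 3-D hulls")
        n_blocks = traj.n_frames // window
        if n_blocks < 1:
            raise ValueError("trajectory shorter than one window")
        vols = np.zeros((n_blocks, n_atoms))
        degs = np.zeros((n_blocks, n_atoms), dtype=bool)
        for b in range(n_blocks):
            sub = Trajectory(traj.coords[b * window:(b + 1) * window],
                             residue_ids=traj.residue_ids,
                             atom_names=traj.atom_names)
            for i in range(n_atoms):
                vols[b, i], degs[b, i] = atom_explored_volume(sub, i)
        volumes = vols.mean(axis=0)
        degenerate = degs.all(axis=0)
        per_step = volumes / window
        n_frames = window
    return DynamicityProfile(explored_volume=volumes, per_step_volume=per_step,
                             degenerate=degenerate,
                             residue_ids=np.asarray(traj.residue_ids),
                             n_frames=n_frames)


def relative_dynamicity(holo: DynamicityProfile, apo: DynamicityProfile,
                        high_threshold: float = 1.5,
                        aggregate: str = "mean") -> pd.DataFrame:
    """Holo/apo ratio of per-step explored volumes, atom by atom.

    Returns a frame with per-atom ``ratio`` = v_i(holo) / v_i(apo) (NaN where
    the apo volume is zero — those atoms are flagged ``excluded`` and left out
    of summaries), per-residue aggregated ratios, and a ``high`` flag marking
    atoms whose ratio exceeds ``high_threshold`` (mobilized regions such as an
    intracellular loop).  The mean ratio over included atoms summarizes the
    global effect of ligand binding (< 1 = stabilization).
    """
    if len(holo.per_step_volume) != len(apo.per_step_volume):
        raise ValueError("profiles have different atom counts")
    if not np.array_equal(holo.residue_ids, apo.residue_ids):
        raise ValueError("profiles have different residue maps")
    apo_v = apo.per_step_volume
    holo_v = holo.per_step_volume
    excluded = apo_v <= 0
    ratio = np.full(len(apo_v), np.nan)
    ratio[~excluded] = holo_v[~excluded] / apo_v[~excluded]
    out = pd.DataFrame({
        "atom_index": np.arange(len(ratio)),
        "residue_id": holo.residue_ids,
        "ratio": ratio,
        "excluded": excluded,
        "high": np.nan_to_num(ratio, nan=0.0) > high_threshold,
    })
    return out


def mean_relative_dynamicity(ratios: pd.DataFrame) -> float:
    """Mean holo/apo ratio over non-excluded atoms."""
    return float(ratios.loc[~ratios["excluded"], "ratio"].mean())
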