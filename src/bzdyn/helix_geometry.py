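"""Base-pair and base-pair-step parameters plus flexibility metrics.

Base reference frames are obtained by least-squares fitting of idealized
planar base templates to the observed ring atoms (Kabsch superposition).
Step parameters use the symmetric mid-frame scheme: the two frames are
rotated by half the bending angle about their common hinge so that their
z-axes coincide, twist is measured about the shared z-axis, and the
translational parameters are expressed in the mid-frame.  Intra-base-pair
parameters use the same decomposition after flipping the complementary
base frame 180 degrees about its x-axis.

Flexibility metrics follow the usual trajectory conventions: RMSD after
optimal superposition, and theoretical B-factors B = (8*pi^2/3) <|r - <r>|^2>
averaged over the heavy atoms of each residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._bases import RING_ATOMS, ring_coordinates
from ._geom import kabsch, rotation_about_axis, unit

__all__ = [
    "ReferenceFrame",
    "base_frame",
    "pair_parameters",
    "step_parameters",
    "compose_step",
    "structure_pair_frames",
    "step_series",
    "superpose",
    "average_structure",
    "bfactors",
    "rmsd_series",
    "STEP_COLUMNS",
    "PAIR_COLUMNS",
]

STEP_COLUMNS = ("shift", "slide", "rise", "tilt", "roll", "twist")
PAIR_COLUMNS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")

_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 degree rotation about the frame x-axis


@dataclass(frozen=True)
class ReferenceFrame:
    """Right-handed orthonormal frame: ``axes`` columns are x, y, z."""

    origin: np.ndarray
    axes: np.ndarray

    def flipped(self) -> "ReferenceFrame":
        """Frame rotated 180 degrees about its own x-axis (strand flip)."""
        return ReferenceFrame(self.origin, self.axes @ _FLIP_X)


def base_frame(atoms: dict, base: str) -> ReferenceFrame:
    """Fit the idealized ``base`` template to observed ring atoms.

    ``atoms`` maps atom names to positions; at least three ring atoms must
    be present.  Returns the frame carrying the template into the observed
    base (frame origin = fitted template origin, axes = fitted template axes).
    """
    names = [n for n in RING_ATOMS[base] if n in atoms]
    if len(names) < 3:
        raise ValueError(f"undefined frame: only {len(names)} ring atoms present")
    tpl = ring_coordinates(base)
    sel = [RING_ATOMS[base].index(n) for n in names]
    obs = np.stack([np.asarray(atoms[n], float) for n in names])
    R, t, _ = kabsch(tpl[sel], obs)
    return ReferenceFrame(origin=t.copy(), axes=R.copy())


def _mid_axes(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Orthonormal bisector of two frames with a shared z-axis."""
    z = unit(Ra[:, 2] + Rb[:, 2])
    x = Ra[:, 0] + Rb[:, 0]
    x = unit(x - np.dot(x, z) * z)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _signed_angle(u, v, about) -> float:
    return float(
        np.degrees(np.arctan2(np.dot(np.cross(u, v), about), np.dot(u, v)))
    )


def step_parameters(frame1: ReferenceFrame, frame2: ReferenceFrame) -> np.ndarray:
    """Six step parameters (shift, slide, rise, tilt, roll, twist) taking
    ``frame1`` into ``frame2``.  Distances in Angstrom, angles in degrees;
    twist is positive for right-handed stacking."""
    p, _ = _decompose(frame1, frame2)
    return p


def _decompose(frame1: ReferenceFrame, frame2: ReferenceFrame):
    R1, R2 = frame1.axes, frame2.axes
    z1, z2 = R1[:, 2], R2[:, 2]
    cosg = float(np.clip(np.dot(z1, z2), -1.0, 1.0))
    gamma = np.degrees(np.arccos(cosg))
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) < 1e-12:
        R1p, R2p = R1, R2
        hinge = None
    else:
        hinge = unit(hinge)
        H = rotation_about_axis(hinge, gamma / 2.0)
        Hm = rotation_about_axis(hinge, -gamma / 2.0)
        R1p = H @ R1
        R2p = Hm @ R2
    Rm = _mid_axes(R1p, R2p)
    zm = Rm[:, 2]
    twist = _signed_angle(R1p[:, 0], R2p[:, 0], zm)
    if hinge is None:
        tilt = roll = 0.0
    else:
        phi = _signed_angle(hinge, Rm[:, 1], zm)
        tilt = gamma * np.sin(np.radians(phi))
        roll = gamma * np.cos(np.radians(phi))
    disp = Rm.T @ (frame2.origin - frame1.origin)
    mid = ReferenceFrame(0.5 * (frame1.origin + frame2.origin), Rm)
    return np.array([disp[0], disp[1], disp[2], tilt, roll, twist]), mid


def compose_step(frame1: ReferenceFrame, params) -> ReferenceFrame:
    """Inverse of :func:`step_parameters`: construct the next frame from the
    six step parameters, measured relative to ``frame1``."""
    shift, slide, rise, tilt, roll, twist = (float(v) for v in params)
    gamma = float(np.hypot(tilt, roll))
    phi = float(np.degrees(np.arctan2(tilt, roll)))
    # Hinge direction in frame1 coordinates: y-axis rotated by (twist/2 - phi)
    # about z (derived so that decomposition recovers the inputs).
    hl = rotation_about_axis([0, 0, 1.0], twist / 2.0 - phi) @ np.array([0.0, 1.0, 0.0])
    H = rotation_about_axis(hl, gamma)
    Hhalf = rotation_about_axis(hl, gamma / 2.0)
    Rz = rotation_about_axis([0, 0, 1.0], twist)
    Rzhalf = rotation_about_axis([0, 0, 1.0], twist / 2.0)
    R_rel = H @ Rz
    Rm_local = Hhalf @ Rzhalf
    R1 = frame1.axes
    origin2 = frame1.origin + R1 @ (Rm_local @ np.array([shift, slide, rise]))
    return ReferenceFrame(origin2, R1 @ R_rel)


def pair_parameters(frame_w: ReferenceFrame, frame_c: ReferenceFrame):
    """Intra-base-pair parameters and the base-pair frame.

    ``frame_w`` is the Watson (strand 1) base frame, ``frame_c`` the Crick
    (strand 2) base frame.  The Crick frame is flipped about its x-axis and
    the step decomposition is applied from the flipped Crick frame to the
    Watson frame: translations map to (shear, stretch, stagger) and
    rotations to (buckle, propeller, opening).  Returns ``(params, pair_frame)``.
    """
    p, mid = _decompose(frame_c.flipped(), frame_w)
    return p, mid


def structure_pair_frames(model, coords: np.ndarray | None = None):
    """Base-pair frames (and per-pair base frames) of a duplex model.

    Pairs residue i of chain 1 with residue N-i+1 of chain 2.  Returns a
    list of ``ReferenceFrame`` of length n_bp.
    """
    xyz = model.coords if coords is None else np.asarray(coords, float)
    chains = model.chain_order()
    if len(chains) != 2:
        raise ValueError("pair frames require a two-chain duplex")
    s1 = model.chain_residues(chains[0])
    s2 = model.chain_residues(chains[1])
    if len(s1) != len(s2):
        raise ValueError("strands differ in length")
    frames = []
    for k, i1 in enumerate(s1):
        i2 = s2[len(s2) - 1 - k]
        fw = base_frame(model.residue_atoms(i1, xyz), model.residues[i1].base)
        fc = base_frame(model.residue_atoms(i2, xyz), model.residues[i2].base)
        _, mid = pair_parameters(fw, fc)
        frames.append(mid)
    return frames


def step_series(model, coords: np.ndarray | None = None) -> pd.DataFrame:
    """Step parameters for every successive base-pair step of one structure."""
    frames = structure_pair_frames(model, coords)
    rows = []
    for i in range(len(frames) - 1):
        p = step_parameters(frames[i], frames[i + 1])
        rows.append({"step": i + 1, **dict(zip(STEP_COLUMNS, p))})
    return pd.DataFrame(rows)


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition; returns ``(rotation, translation, rmsd)``."""
    return kabsch(mobile, reference)


def average_structure(frames: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Mean structure after iterative superposition onto the running mean."""
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    ref = frames[0]
    fitted = frames
    for _ in range(n_iter):
        fitted = np.empty_like(frames)
        for i, f in enumerate(frames):
            R, t, _ = kabsch(f, ref)
            fitted[i] = f @ R.T + t
        ref = fitted.mean(axis=0)
    return ref


def rmsd_series(traj, reference: np.ndarray, atom_indices=None) -> np.ndarray:
    """Per-frame RMSD to ``reference`` after optimal superposition."""
    idx = slice(None) if atom_indices is None else np.asarray(atom_indices)
    out = np.empty(traj.n_frames)
    ref = np.asarray(reference, float)[idx]
    for i in range(traj.n_frames):
        _, _, out[i] = kabsch(traj.frames[i][idx], ref)
    return out


def bfactors(
    traj,
    model,
    reference: np.ndarray | None = None,
    include_terminal: bool = False,
) -> pd.Series:
    """Theoretical per-residue B-factors in Angstrom^2.

    Frames are superposed onto the average structure (computed here when
    ``reference`` is None), atomic mean-square fluctuations are converted
    via B = (8*pi^2/3) <|r - <r>|^2>, and residue values are means over the
    residue's heavy atoms.  Terminal residues of each chain are excluded by
    default, mirroring end-effect removal in duplex analyses.
    """
    if traj.n_frames < 2:
        raise ValueError("B-factors need at least two frames")
    if reference is None:
        reference = average_structure(traj.frames)
    fitted = np.empty_like(traj.frames)
    for i, f in enumerate(traj.frames):
        R, t, _ = kabsch(f, reference)
        fitted[i] = f @ R.T + t
    mean = fitted.mean(axis=0)
    msf = np.mean(np.sum((fitted - mean) ** 2, axis=-1), axis=0)
    b_atom = (8.0 * np.pi**2 / 3.0) * msf
    terminal = model.terminal_residue_indices()
    data = {}
    for i, res in enumerate(model.residues):
        if not include_terminal and i in terminal:
            continue
        idx = [
            j
            for j in model.residue_atom_indices(i).values()
        ]
        heavy = [j for j in idx if not model.atom_names[j].startswith("H")]
        data[res.number] = float(np.mean(b_atom[heavy]))
    return pd.Series(data, name="B")
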