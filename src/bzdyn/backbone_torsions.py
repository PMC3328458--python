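"""Backbone/glycosidic dihedrals and sugar-pucker descriptors.

Torsion definitions (per residue i, 5'->3'):

* alpha   = O3'(i-1) - P(i) - O5'(i) - C5'(i)
* beta    = P(i) - O5'(i) - C5'(i) - C4'(i)
* gamma   = O5'(i) - C5'(i) - C4'(i) - C3'(i)
* delta   = C5'(i) - C4'(i) - C3'(i) - O3'(i)
* epsilon = C4'(i) - C3'(i) - O3'(i) - P(i+1)
* zeta    = C3'(i) - O3'(i) - P(i+1) - O5'(i+1)
* chi     = O4'-C1'-N9-C4 (purines), O4'-C1'-N1-C2 (pyrimidines)

Angles are reported in [-180, 180).  Terminal residues lacking the atoms a
torsion needs carry NaN for that torsion rather than failing globally.

The sugar pucker uses the Altona-Sundaralingam pseudorotation: with ring
torsions nu_j = tau_m * cos(P + 144*(j-2)),

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 * nu2 * (sin 36 + sin 72))

and amplitude tau_m = nu2 / cos P, evaluated in the numerically stable
two-argument arctangent form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._bases import CHI_REFERENCE, GLYCOSIDIC_N
from ._geom import dihedral as dihedral  # re-exported public primitive
from ._geom import _wrap180

__all__ = [
    "dihedral",
    "assign_backbone_torsions",
    "pucker",
    "pucker_from_phase",
    "classify_pucker",
    "pucker_sector",
    "TORSION_NAMES",
]

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")

_SIN36_72 = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))

_NU_QUADS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

#: Ten 36-degree pseudorotation states (each the union of two 18-degree
#: sectors of the wheel), half-open on the left edge.  "O4'-endo" is the
#: same state some authors print as "O1'-endo".
PUCKER_STATES = (
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
)

PUCKER_SYNONYMS = {"O1'-endo": "O4'-endo", "O1'-exo": "O4'-exo"}


def pucker(nu0, nu1, nu2, nu3, nu4):
    """Pseudorotation ``(phase P in [0, 360), amplitude)`` in degrees from the
    five furanose ring torsions.  A near-planar ring (amplitude < 1 degree)
    yields ``(nan, amplitude)``."""
    nu = [np.asarray(v, dtype=float) for v in (nu0, nu1, nu2, nu3, nu4)]
    a = (nu[4] + nu[1]) - (nu[3] + nu[0])
    sin_part = a / (2.0 * _SIN36_72)  # tau_m * sin P
    amplitude = np.hypot(nu[2], sin_part)
    phase = np.degrees(np.arctan2(sin_part, nu[2])) % 360.0
    phase = np.where(amplitude < 1.0, np.nan, phase)
    if phase.ndim == 0:
        return float(phase), float(amplitude)
    return phase, amplitude


def pucker_from_phase(P: float, amplitude: float) -> tuple:
    """Inverse of :func:`pucker`: the five ring torsions
    nu_j = amplitude * cos(P + 144 * (j - 2))."""
    return tuple(
        amplitude * np.cos(np.radians(P + 144.0 * (j - 2))) for j in range(5)
    )


def pucker_sector(P: float) -> int:
    """Index (0..19) of the half-open 18-degree pseudorotation sector."""
    if np.isnan(P):
        raise ValueError("undefined phase")
    return int((P % 360.0) // 18.0)


def classify_pucker(P: float) -> str:
    """Named pucker state for phase ``P`` (degrees); NaN -> ``"planar"``."""
    if P is None or np.isnan(P):
        return "planar"
    return PUCKER_STATES[int((P % 360.0) // 36.0)]


def _atom_quad(model, res_index, prev_index, next_index, torsion):
    """Atom indices for one named torsion of one residue, or None."""
    own = model.residue_atom_indices(res_index)
    prv = model.residue_atom_indices(prev_index) if prev_index is not None else {}
    nxt = model.residue_atom_indices(next_index) if next_index is not None else {}
    base = model.residues[res_index].base
    quads = {
        "alpha": ((prv, "O3'"), (own, "P"), (own, "O5'"), (own, "C5'")),
        "beta": ((own, "P"), (own, "O5'"), (own, "C5'"), (own, "C4'")),
        "gamma": ((own, "O5'"), (own, "C5'"), (own, "C4'"), (own, "C3'")),
        "delta": ((own, "C5'"), (own, "C4'"), (own, "C3'"), (own, "O3'")),
        "epsilon": ((own, "C4'"), (own, "C3'"), (own, "O3'"), (nxt, "P")),
        "zeta": ((own, "C3'"), (own, "O3'"), (nxt, "P"), (nxt, "O5'")),
        "chi": (
            (own, "O4'"), (own, "C1'"),
            (own, GLYCOSIDIC_N[base]), (own, CHI_REFERENCE[base]),
        ),
    }[torsion]
    idx = []
    for table, name in quads:
        if name not in table:
            return None
        idx.append(table[name])
    return idx


def assign_backbone_torsions(traj, model) -> pd.DataFrame:
    """Per-residue, per-frame backbone torsions and sugar pucker.

    ``traj`` may be a Trajectory or a single coordinate set; ``model``
    supplies atom naming and chain connectivity.  Returns a long-format
    DataFrame with columns ``time_ps, chain, residue, base, alpha..chi,
    phase, amplitude, terminal``; undefined angles are NaN.
    """
    frames = getattr(traj, "frames", None)
    if frames is None:
        frames = np.asarray(traj, float)
        if frames.ndim == 2:
            frames = frames[None]
        dt = 1.0
    else:
        dt = traj.dt
    n_frames = frames.shape[0]

    terminal = model.terminal_residue_indices()
    records = []
    for ch in model.chain_order():
        order = model.chain_residues(ch)
        for k, ri in enumerate(order):
            prev_i = order[k - 1] if k > 0 else None
            next_i = order[k + 1] if k < len(order) - 1 else None
            res = model.residues[ri]
            row = {
                "chain": ch,
                "residue": res.number,
                "base": res.base,
                "terminal": ri in terminal,
            }
            angles = {}
            for name in TORSION_NAMES:
                quad = _atom_quad(model, ri, prev_i, next_i, name)
                if quad is None:
                    angles[name] = np.full(n_frames, np.nan)
                else:
                    p = frames[:, quad, :]
                    angles[name] = np.atleast_1d(
                        dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
                    )
            own = model.residue_atom_indices(ri)
            if all(n in own for quad in _NU_QUADS for n in quad):
                nus = []
                for quad in _NU_QUADS:
                    p = frames[:, [own[n] for n in quad], :]
                    nus.append(np.atleast_1d(dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])))
                phase, amplitude = pucker(*nus)
                phase = np.atleast_1d(phase)
                amplitude = np.atleast_1d(amplitude)
            else:
                phase = np.full(n_frames, np.nan)
                amplitude = np.full(n_frames, np.nan)
            for f in range(n_frames):
                rec = dict(row)
                rec["time_ps"] = f * dt
                for name in TORSION_NAMES:
                    rec[name] = angles[name][f]
                rec["phase"] = phase[f]
                rec["amplitude"] = amplitude[f]
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    cols = ["time_ps", "chain", "residue", "base", *TORSION_NAMES, "phase", "amplitude", "terminal"]
    return df[cols].sort_values(["time_ps", "chain", "residue"], kind="stable").reset_index(drop=True)


def wrap_angle(a):
    """Wrap angle(s) to [-180, 180)."""
    return _wrap180(a)
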