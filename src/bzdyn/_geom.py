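"""Low-level vector geometry shared by the builder and the analysis modules.

All positions are in Angstrom, all angles in degrees unless a name says
otherwise.  Torsion angles follow the IUPAC convention: cis = 0, positive
when the far bond rotates clockwise while looking from the second to the
third atom.
"""

from __future__ import annotations

import numpy as np

__all__ = ["unit", "dihedral", "bond_angle", "nerf", "rotation_about_axis", "kabsch"]


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize the last axis of ``v``."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def dihedral(p1, p2, p3, p4) -> np.ndarray | float:
    """Torsion angle p1-p2-p3-p4 in degrees, in [-180, 180).

    Accepts single points or arrays broadcast over leading axes.  Raises
    ``ValueError`` for collinear (undefined) geometries on scalar input;
    array input yields NaN for degenerate entries.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / np.where(b2n == 0, np.nan, b2n)
    scalar = x.ndim == 0
    with np.errstate(invalid="ignore"):
        bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    if scalar:
        if bad:
            raise ValueError("undefined dihedral: collinear triplet")
        ang = np.degrees(np.arctan2(y, x))
        return float(_wrap180(ang))
    ang = np.degrees(np.arctan2(y, x))
    ang = _wrap180(ang)
    return np.where(bad, np.nan, ang)


def _wrap180(a):
    """Wrap angle(s) to the half-open interval [-180, 180)."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees."""
    u = unit(np.asarray(p1, float) - p2)
    v = unit(np.asarray(p3, float) - p2)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |d-c| = bond, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg (natural extension reference frame).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    p = np.cross(n, bc)
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    d = (
        -np.cos(theta) * bc
        + np.sin(theta) * np.cos(phi) * p
        + np.sin(theta) * np.sin(phi) * n
    )
    return c + bond * d


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about ``axis`` by ``angle_deg``."""
    ax = unit(np.asarray(axis, float))
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    x, y, z = ax
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(ax, ax)


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation/translation mapping ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``reference ~= mobile @ R.T + t``.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("superposition needs two matched sets of >= 3 points")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=-1))))
    return R, t, rmsd
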