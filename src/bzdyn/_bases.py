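"""Idealized planar base templates in the standard base reference frame.

Each base is built from regular-polygon ring geometry with literature-like
bond lengths and is positioned so that the glycosidic nitrogen and the C1'
anchor sit at the standard-frame positions shared by purines and
pyrimidines.  The same templates serve both for model building and for the
least-squares recovery of base reference frames from coordinates, which
makes builder -> geometry round trips exact by construction.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._geom import rotation_about_axis, unit

# Standard-frame anchor positions (x toward the major groove, y toward the
# paired strand's backbone, z along the helix axis; the frame origin sits in
# the base-pair midplane).
C1_ANCHOR = np.array([-2.477, 5.399, 0.0])
N_ANCHOR = np.array([-1.289, 4.551, 0.0])  # N9 (purine) / N1 (pyrimidine)

RING_ATOMS = {
    "G": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

GLYCOSIDIC_N = {"G": "N9", "C": "N1"}
# Reference base atom for the chi torsion O4'-C1'-N-C.
CHI_REFERENCE = {"G": "C4", "C": "C2"}

_HEX_BOND = 1.39
_PENT_BOND = 1.37


def _regular_polygon(center, first_vertex, n, direction):
    """Vertices of a regular n-gon in the z=0 plane, starting at
    ``first_vertex`` and proceeding by signed steps of 360/n degrees."""
    out = [np.asarray(first_vertex, float)]
    step = direction * 360.0 / n
    for k in range(1, n):
        R = rotation_about_axis([0, 0, 1.0], step * k)
        out.append(center + R @ (first_vertex - center))
    return out


@lru_cache(maxsize=None)
def base_template(base: str) -> dict:
    """Heavy-atom coordinates (name -> xyz) of an idealized base, planar in
    the standard reference frame.  ``base`` is 'G' or 'C'."""
    if base not in ("G", "C"):
        raise ValueError(f"unknown base {base!r}; expected 'G' or 'C'")
    u = unit(N_ANCHOR - C1_ANCHOR)  # glycosidic bond direction, points into the ring
    atoms: dict[str, np.ndarray] = {}
    if base == "C":
        # Pyrimidine six-ring N1 C2 N3 C4 C5 C6.
        center = N_ANCHOR + _HEX_BOND * u
        ring = _regular_polygon(center, N_ANCHOR, 6, direction=+1)
        for name, pos in zip(("N1", "C2", "N3", "C4", "C5", "C6"), ring):
            atoms[name] = pos
        atoms["O2"] = atoms["C2"] + 1.23 * unit(atoms["C2"] - center)
        atoms["N4"] = atoms["C4"] + 1.34 * unit(atoms["C4"] - center)
    else:
        # Purine: five-ring N9 C8 N7 C5 C4 fused with six-ring C4 N3 C2 N1 C6 C5.
        r5 = _PENT_BOND / (2.0 * np.sin(np.pi / 5.0))
        c5 = N_ANCHOR + r5 * u
        pent = _regular_polygon(c5, N_ANCHOR, 5, direction=-1)
        for name, pos in zip(("N9", "C8", "N7", "C5", "C4"), pent):
            atoms[name] = pos
        edge_mid = 0.5 * (atoms["C4"] + atoms["C5"])
        apothem = _HEX_BOND * np.sqrt(3.0) / 2.0
        c6 = edge_mid + apothem * unit(edge_mid - c5)
        # Walk the hexagon starting from C4, away from C5.
        cand = []
        for direction in (+1, -1):
            R = rotation_about_axis([0, 0, 1.0], direction * 60.0)
            cand.append((direction, c6 + R @ (atoms["C4"] - c6)))
        direction = max(cand, key=lambda dc: np.linalg.norm(dc[1] - atoms["C5"]))[0]
        hexa = _regular_polygon(c6, atoms["C4"], 6, direction=direction)
        for name, pos in zip(("C4", "N3", "C2", "N1", "C6"), hexa[:5]):
            atoms.setdefault(name, pos)
        atoms["O6"] = atoms["C6"] + 1.23 * unit(atoms["C6"] - c6)
        atoms["N2"] = atoms["C2"] + 1.34 * unit(atoms["C2"] - c6)
    return {k: np.asarray(v, float) for k, v in atoms.items()}


def ring_coordinates(base: str) -> np.ndarray:
    """Stacked ring-atom coordinates in canonical order (for frame fitting)."""
    tpl = base_template(base)
    return np.stack([tpl[name] for name in RING_ATOMS[base]])
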