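"""Construction of idealized B- and Z-form d(GC)n duplexes.

The builder works in base-pair reference frames.  Pair frames are generated
by composing canonical step parameters (B form: uniform 36 degree twist and
3.38 A rise; Z form: a dinucleotide repeat of alternating small/large
negative twists summing to -60 degrees per GpC+CpG dinucleotide).  Base
heavy atoms are placed by rigid transforms of idealized planar templates,
so recomputing pair and step parameters from the coordinates reproduces
the construction values exactly.

Sugar and backbone atoms are attached per residue with the natural
extension reference frame (NeRF) so that the glycosidic torsion chi, the
sugar pucker (phase/amplitude), delta, and the inter-residue torsions
epsilon and zeta take canonical values for the chosen helical form; the
remaining backbone torsions follow from the helical geometry.  The B-form
backbone is built in the BI substate (epsilon - zeta < 0) with C2'-endo
sugars in anti; the Z-form guanosines are syn with C3'-endo sugars.

Hydrogens are not modeled; every analysis in this package uses heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from . import helix_geometry as hg
from ._bases import C1_ANCHOR, CHI_REFERENCE, GLYCOSIDIC_N, N_ANCHOR, base_template
from ._geom import bond_angle, dihedral, nerf, unit

__all__ = [
    "Residue",
    "DuplexModel",
    "build_duplex",
    "methylate",
    "neutralizing_ion_count",
    "B_STEP",
    "Z_STEPS",
    "TORSION_TARGETS",
]

# ---------------------------------------------------------------------------
# Canonical construction parameters
# ---------------------------------------------------------------------------

# B form: uniform fiber-like step (shift, slide, rise, tilt, roll, twist).
B_STEP = (0.0, 0.0, 3.38, 0.0, 0.0, 36.0)

# Z form: dinucleotide repeat keyed by step type along strand 1 (5'->3').
# Twists sum to -60 degrees per dinucleotide; the distinct slide values give
# the bimodal slide/twist distributions characteristic of the zigzag
# backbone.
Z_STEPS = {
    "GC": (0.0, -1.1, 3.7, 0.0, 0.0, -51.0),
    "CG": (0.0, 1.0, 3.7, 0.0, 0.0, -9.0),
}

# Canonical per-residue torsion/pucker targets by (form, base).
# chi: glycosidic torsion; P/tau: sugar pseudorotation phase and amplitude;
# delta: C5'-C4'-C3'-O3'; gamma applies only to the 5'-terminal O5';
# epsilon/zeta are imposed at the 3' phosphodiester junction.
TORSION_TARGETS = {
    ("B", "G"): dict(chi=-117.0, P=162.0, tau=38.0, delta=128.0, gamma=54.0,
                     epsilon=-169.0, zeta=-103.0),
    ("B", "C"): dict(chi=-117.0, P=162.0, tau=38.0, delta=128.0, gamma=54.0,
                     epsilon=-169.0, zeta=-103.0),
    ("Z", "G"): dict(chi=68.0, P=18.0, tau=38.0, delta=95.0, gamma=179.0,
                     epsilon=-104.0, zeta=-69.0),
    ("Z", "C"): dict(chi=-159.0, P=152.0, tau=38.0, delta=138.0, gamma=56.0,
                     epsilon=-94.0, zeta=80.0),
}

# Bond lengths / angles used for backbone attachment (Angstrom / degrees).
_B = dict(
    c1_o4=1.414, c1_c2=1.528, o4_n=108.2, c2_n=113.7,
    c3_o3=1.423, c4_c3_o3=110.5, c4_c5=1.510, c3_c4_c5=115.0,
    o3_p=1.607, c3_o3_p=119.7, p_o5=1.593, o3_p_o5=104.0,
    p_op=1.485, o3_p_op=108.1, c5_o5=1.440, c4_c5_o5=110.2,
)

# Branch signs resolving the two mirror solutions of the sugar attachment;
# chosen so that the exocyclic O3' points toward the following residue and
# the nucleotide has the natural deoxyribose handedness.
_N_BRANCH = +1.0
_O3_BRANCH = -1.0

_COMPLEMENT = {"G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    base: str  # 'G' or 'C'
    methylated: bool = False

    @property
    def res_name(self) -> str:
        if self.base == "G":
            return "DG"
        return "5CM" if self.methylated else "DC"


@dataclass
class DuplexModel:
    """Atoms and residues of a (possibly idealized) DNA duplex."""

    residues: list
    atom_names: list
    atom_residue: np.ndarray
    coords: np.ndarray
    form: str | None = None
    step_parameters: list | None = None
    construction_frames: list | None = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_bp(self) -> int:
        chains = self.chain_order()
        return len(self.chain_residues(chains[0]))

    def chain_order(self):
        seen = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def chain_residues(self, chain: str):
        """Residue indices of one chain, in 5'->3' order (ascending number)."""
        idx = [i for i, r in enumerate(self.residues) if r.chain == chain]
        return sorted(idx, key=lambda i: self.residues[i].number)

    def residue_atom_indices(self, i: int) -> dict:
        mask = np.flatnonzero(self.atom_residue == i)
        return {self.atom_names[j]: int(j) for j in mask}

    def residue_atoms(self, i: int, coords: np.ndarray | None = None) -> dict:
        xyz = self.coords if coords is None else coords
        return {name: xyz[j] for name, j in self.residue_atom_indices(i).items()}

    def terminal_residue_indices(self) -> set:
        out = set()
        for ch in self.chain_order():
            res = self.chain_residues(ch)
            if res:
                out.update({res[0], res[-1]})
        return out

    @property
    def phosphate_count(self) -> int:
        return sum(1 for n in self.atom_names if n == "P")

    @property
    def methylated_count(self) -> int:
        return sum(1 for r in self.residues if r.methylated)

    def copy(self) -> "DuplexModel":
        return DuplexModel(
            residues=list(self.residues),
            atom_names=list(self.atom_names),
            atom_residue=self.atom_residue.copy(),
            coords=self.coords.copy(),
            form=self.form,
            step_parameters=None if self.step_parameters is None else list(self.step_parameters),
            construction_frames=self.construction_frames,
        )


# ---------------------------------------------------------------------------
# Sugar geometry
# ---------------------------------------------------------------------------

_RING_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'")
_NU_QUADS = {
    0: ("C4'", "O4'", "C1'", "C2'"),
    1: ("O4'", "C1'", "C2'", "C3'"),
    2: ("C1'", "C2'", "C3'", "C4'"),
    3: ("C2'", "C3'", "C4'", "O4'"),
    4: ("C3'", "C4'", "O4'", "C1'"),
}


def _ring_from_cp(q: float, phi_deg: float) -> dict:
    """Five-membered ring from a puckered regular pentagon (Cremer-Pople
    style out-of-plane displacements)."""
    r = 1.46 / (2.0 * np.sin(np.pi / 5.0))
    phi = np.radians(phi_deg)
    out = {}
    for j, name in enumerate(_RING_ORDER):
        ang = np.pi / 2.0 + 2.0 * np.pi * j / 5.0
        z = np.sqrt(2.0 / 5.0) * q * np.cos(phi + 4.0 * np.pi * j / 5.0)
        out[name] = np.array([r * np.cos(ang), r * np.sin(ang), z])
    return out


def _ring_pucker(ring: dict):
    from .backbone_torsions import pucker

    nus = [dihedral(*(ring[a] for a in _NU_QUADS[j])) for j in range(5)]
    return pucker(*nus)


@lru_cache(maxsize=None)
def _sugar_ring(P_target: float, tau_target: float) -> tuple:
    """Solve for ring coordinates whose pseudorotation phase/amplitude match
    the targets; returns a tuple of (name, xyz) pairs."""

    def residual(x):
        q, phi = x
        P, tau = _ring_pucker(_ring_from_cp(q, phi))
        dP = (P - P_target + 180.0) % 360.0 - 180.0
        return [dP, tau - tau_target]

    best = None
    for phi0 in (P_target, P_target + 90.0, P_target + 180.0, P_target + 270.0):
        sol = least_squares(residual, x0=[tau_target / 100.0, phi0], xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-16:
            break
    ring = _ring_from_cp(*best.x)
    return tuple((k, v) for k, v in ring.items())


def _place_sugar(base_atoms: dict, base: str, tgt: dict) -> dict:
    """Attach the deoxyribose (ring + O3' + C5') to a placed base.

    The local ring model is positioned so that the glycosidic geometry
    (bond length, the two C1' bond angles and the chi torsion) is exact.
    """
    n_name = GLYCOSIDIC_N[base]
    c_ref_name = CHI_REFERENCE[base]
    n_g = base_atoms[n_name]
    c_ref_g = base_atoms[c_ref_name]
    c1_g = base_atoms["C1'"]

    ring = dict(_sugar_ring(tgt["P"], tgt["tau"]))
    c1 = ring["C1'"]
    u1 = unit(ring["O4'"] - c1)
    u2 = unit(ring["C2'"] - c1)
    # Unit vector d from C1' to N with prescribed angles to O4' and C2'.
    c12 = float(np.dot(u1, u2))
    a1 = np.cos(np.radians(_B["o4_n"]))
    a2 = np.cos(np.radians(_B["c2_n"]))
    M = np.array([[1.0, c12], [c12, 1.0]])
    ab = np.linalg.solve(M, [a1, a2])
    v = ab[0] * u1 + ab[1] * u2
    c2 = max(0.0, 1.0 - float(np.dot(v, v)))
    nrm = unit(np.cross(u1, u2))
    d = v + _N_BRANCH * np.sqrt(c2) * nrm
    bond_n = float(np.linalg.norm(n_g - c1_g))
    n_l = c1 + bond_n * unit(d)
    # Chi reference atom, using the exact base-frame internal geometry so the
    # local and global triangles are congruent.
    c_ref_l = nerf(
        ring["O4'"], c1, n_l,
        bond=float(np.linalg.norm(c_ref_g - n_g)),
        angle_deg=bond_angle(c1_g, n_g, c_ref_g),
        torsion_deg=tgt["chi"],
    )
    # Exocyclic atoms in the local frame.
    nu3 = dihedral(ring["C2'"], ring["C3'"], ring["C4'"], ring["O4'"])
    o3_l = nerf(
        ring["O4'"], ring["C4'"], ring["C3'"],
        bond=_B["c3_o3"], angle_deg=_B["c4_c3_o3"],
        torsion_deg=nu3 + _O3_BRANCH * 120.0,
    )
    c5_l = nerf(
        o3_l, ring["C3'"], ring["C4'"],
        bond=_B["c4_c5"], angle_deg=_B["c3_c4_c5"],
        torsion_deg=tgt["delta"],
    )
    local_pts = np.stack([c1, n_l, c_ref_l])
    global_pts = np.stack([c1_g, n_g, c_ref_g])
    from ._geom import kabsch

    R, t, _ = kabsch(local_pts, global_pts)
    placed = {}
    for name, pos in ring.items():
        placed[name] = pos @ R.T + t
    placed["O3'"] = o3_l @ R.T + t
    placed["C5'"] = c5_l @ R.T + t
    return placed


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

_ATOM_ORDER = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
)


def _validate_sequence(sequence: str):
    seq = sequence.upper()
    for i, b in enumerate(seq):
        if b not in ("G", "C"):
            raise ValueError(f"unsupported base {b!r} at position {i + 1}; expected G/C")
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1]:
            raise ValueError(
                f"sequence must alternate purine/pyrimidine; positions {i} and {i + 1} "
                f"are both {seq[i]!r}"
            )
    return seq


def _step_params_for(form: str, seq: str, i: int):
    if form == "B":
        return np.array(B_STEP)
    return np.array(Z_STEPS[seq[i] + seq[i + 1]])


def build_duplex(sequence: str = "GC", form: str = "B", n_repeats: int = 5) -> DuplexModel:
    """Build an idealized Watson-Crick duplex of ``sequence * n_repeats``.

    ``form`` selects canonical B (right-handed, twist 36, rise 3.38) or Z
    (left-handed dinucleotide repeat, syn guanosines).  Residues are
    numbered 1..N on chain A and N+1..2N on chain B, with residue i pairing
    residue 2N-i+1; 5'-terminal residues carry no phosphate.
    """
    form = form.upper()
    if form not in ("B", "Z"):
        raise ValueError(f"unknown form {form!r}; expected 'B' or 'Z'")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seq = _validate_sequence(sequence) * int(n_repeats)
    n = len(seq)

    # Pair frames from canonical step parameters.
    frames = [hg.ReferenceFrame(np.zeros(3), np.eye(3))]
    steps = []
    for i in range(n - 1):
        p = _step_params_for(form, seq, i)
        steps.append(p)
        frames.append(hg.compose_step(frames[-1], p))

    # Per-residue heavy atoms, keyed (chain, pair index).
    residues: list[Residue] = []
    res_atoms: list[dict] = []
    for i in range(n):
        residues.append(Residue("A", i + 1, seq[i]))
        res_atoms.append(_residue_base_and_sugar(frames[i], seq[i], form, flip=False))
    comp = [(_COMPLEMENT[b]) for b in seq]
    for j in range(n):  # chain B in 5'->3' order pairs with pair index n-1-j
        i_pair = n - 1 - j
        residues.append(Residue("B", n + j + 1, comp[i_pair]))
        res_atoms.append(_residue_base_and_sugar(frames[i_pair], comp[i_pair], form, flip=True))

    # Phosphodiester junctions per strand (5'->3').
    for chain_start in (0, n):
        order = list(range(chain_start, chain_start + n))
        for k, ri in enumerate(order):
            atoms = res_atoms[ri]
            if k == 0:
                prev = None
                tgt = TORSION_TARGETS[(form, residues[ri].base)]
                atoms["O5'"] = nerf(
                    atoms["C3'"], atoms["C4'"], atoms["C5'"],
                    bond=_B["c5_o5"], angle_deg=_B["c4_c5_o5"], torsion_deg=tgt["gamma"],
                )
                continue
            prev = res_atoms[order[k - 1]]
            ptgt = TORSION_TARGETS[(form, residues[order[k - 1]].base)]
            p = nerf(
                prev["C4'"], prev["C3'"], prev["O3'"],
                bond=_B["o3_p"], angle_deg=_B["c3_o3_p"], torsion_deg=ptgt["epsilon"],
            )
            o5 = nerf(
                prev["C3'"], prev["O3'"], p,
                bond=_B["p_o5"], angle_deg=_B["o3_p_o5"], torsion_deg=ptgt["zeta"],
            )
            op1 = nerf(
                prev["C3'"], prev["O3'"], p,
                bond=_B["p_op"], angle_deg=_B["o3_p_op"], torsion_deg=ptgt["zeta"] + 119.0,
            )
            op2 = nerf(
                prev["C3'"], prev["O3'"], p,
                bond=_B["p_op"], angle_deg=_B["o3_p_op"], torsion_deg=ptgt["zeta"] - 119.0,
            )
            atoms.update({"P": p, "OP1": op1, "OP2": op2, "O5'": o5})

    # Assemble flat arrays in residue order with a stable atom order.
    atom_names: list[str] = []
    atom_residue: list[int] = []
    coords: list[np.ndarray] = []
    for ri, atoms in enumerate(res_atoms):
        base_names = [nm for nm in atoms if nm not in _ATOM_ORDER]
        for nm in _ATOM_ORDER:
            if nm in atoms:
                atom_names.append(nm)
                atom_residue.append(ri)
                coords.append(atoms[nm])
        for nm in base_names:
            atom_names.append(nm)
            atom_residue.append(ri)
            coords.append(atoms[nm])

    return DuplexModel(
        residues=residues,
        atom_names=atom_names,
        atom_residue=np.asarray(atom_residue, dtype=int),
        coords=np.asarray(coords, dtype=float),
        form=form,
        step_parameters=steps,
        construction_frames=frames,
    )


def _residue_base_and_sugar(frame: hg.ReferenceFrame, base: str, form: str, flip: bool) -> dict:
    f = frame.flipped() if flip else frame
    R, o = f.axes, f.origin
    atoms = {name: pos @ R.T + o for name, pos in base_template(base).items()}
    atoms["C1'"] = C1_ANCHOR @ R.T + o
    tgt = TORSION_TARGETS[(form, base)]
    atoms.update(_place_sugar(atoms, base, tgt))
    return atoms


# ---------------------------------------------------------------------------
# Methylation and ion bookkeeping
# ---------------------------------------------------------------------------


def methylate(model: DuplexModel, rule="all_non_terminal") -> DuplexModel:
    """Return a copy of ``model`` with selected cytosines methylated at C5.

    ``rule`` is ``"all_non_terminal"`` (every cytosine except chain-terminal
    residues), ``"all"``, or an explicit iterable of residue numbers.  The
    methyl carbon C7 is placed in the base plane on the exterior bisector at
    C5 with a 1.50 A bond; no other coordinate changes.
    """
    if isinstance(rule, str):
        if rule == "all_non_terminal":
            terminal = model.terminal_residue_indices()
            targets = [
                i for i, r in enumerate(model.residues)
                if r.base == "C" and i not in terminal
            ]
        elif rule == "all":
            targets = [i for i, r in enumerate(model.residues) if r.base == "C"]
        else:
            raise ValueError(f"unknown methylation rule {rule!r}")
    else:
        by_number = {r.number: i for i, r in enumerate(model.residues)}
        targets = []
        for num in rule:
            if num not in by_number:
                raise ValueError(f"no residue numbered {num}")
            i = by_number[num]
            if model.residues[i].base != "C":
                raise ValueError(
                    f"cannot methylate residue {num}: base is {model.residues[i].base}, not C"
                )
            targets.append(i)

    new = model.copy()
    names = list(new.atom_names)
    res_idx = list(new.atom_residue)
    xyz = list(new.coords)
    # Insert each C7 right after its residue's last atom to keep residues
    # contiguous.
    for i in sorted(targets, reverse=True):
        atoms = model.residue_atoms(i)
        if "C7" in model.residue_atom_indices(i):
            continue
        c4, c5, c6 = atoms["C4"], atoms["C5"], atoms["C6"]
        direction = unit(unit(c5 - c4) + unit(c5 - c6))
        pos = c5 + 1.50 * direction
        last = max(model.residue_atom_indices(i).values())
        names.insert(last + 1, "C7")
        res_idx.insert(last + 1, i)
        xyz.insert(last + 1, pos)
        new.residues[i] = replace(new.residues[i], methylated=True)
    new.atom_names = names
    new.atom_residue = np.asarray(res_idx, dtype=int)
    new.coords = np.asarray(xyz, dtype=float)
    return new


def neutralizing_ion_count(model: DuplexModel) -> int:
    """Number of monovalent cations needed to neutralize the backbone:
    one per phosphate group."""
    return model.phosphate_count
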