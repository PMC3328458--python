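"""Discrete conformational-state analysis of backbone torsions.

BI/BII: the backbone substate is the sign of the epsilon - zeta difference,
taken as the minimal circular difference wrapped to [-180, 180) so the call
does not depend on the reporting range of the two angles; negative (and the
measure-zero exact zero) is BI, positive is BII.

alpha/gamma rotamers partition the circle into three half-open sectors on
[0, 360): gauche+ [0, 120), trans [120, 240), gauche- [240, 360).  chi is
syn on [-90, 90) and anti otherwise.

Dwell statistics treat a dwell as a maximal run of one label times the
frame spacing; runs truncated by either trajectory end are excluded from
dwell means (but still contribute to occupancy), and a passage is any
label change between successive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import _wrap180

__all__ = [
    "StateTrajectory",
    "classify_bi_bii",
    "classify_rotamer",
    "classify_chi",
    "assign_states",
    "fraction_series",
    "cumulative_mean",
    "dwell_statistics",
    "DwellStats",
    "state_occupancy_table",
]

ROTAMER_LABELS = ("g+", "t", "g-")


def classify_bi_bii(epsilon, zeta):
    """BI/BII label(s) from epsilon and zeta (degrees).

    The difference is wrapped to [-180, 180) before the sign test;
    undefined (NaN) inputs give ``"undefined"``.
    """
    eps = np.asarray(epsilon, dtype=float)
    zet = np.asarray(zeta, dtype=float)
    diff = _wrap180(eps - zet)
    lab = np.where(diff > 0.0, "BII", "BI")
    lab = np.where(np.isnan(diff), "undefined", lab)
    if lab.ndim == 0:
        return str(lab)
    return lab


def classify_rotamer(angle):
    """gauche+/trans/gauche- rotamer label(s) for a torsion in degrees."""
    a = np.asarray(angle, dtype=float) % 360.0
    idx = np.clip((np.nan_to_num(a) // 120.0).astype(int), 0, 2)
    lab = np.take(ROTAMER_LABELS, idx)
    lab = np.where(np.isnan(a), "undefined", lab)
    if lab.ndim == 0:
        return str(lab)
    return lab


def classify_chi(chi):
    """syn/anti label(s): syn for chi in [-90, 90), anti otherwise."""
    c = _wrap180(np.asarray(chi, dtype=float))
    lab = np.where((c >= -90.0) & (c < 90.0), "syn", "anti")
    lab = np.where(np.isnan(c), "undefined", lab)
    if lab.ndim == 0:
        return str(lab)
    return lab


@dataclass
class StateTrajectory:
    """Per-residue, per-frame discrete state labels.

    ``data`` columns: time_ps, chain, residue, base, bi_bii, alpha_state,
    gamma_state, chi_state, terminal.
    """

    data: pd.DataFrame
    dt: float

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.data["time_ps"].nunique()

    def included(self, include_terminal: bool = False) -> pd.DataFrame:
        if include_terminal or "terminal" not in self.data.columns:
            return self.data
        return self.data[~self.data["terminal"]]

    @classmethod
    def from_torsions(cls, torsions: pd.DataFrame, dt: float) -> "StateTrajectory":
        """Discretize a torsion table (see ``assign_backbone_torsions``)."""
        df = torsions.copy()
        df["bi_bii"] = classify_bi_bii(df["epsilon"].to_numpy(), df["zeta"].to_numpy())
        df["alpha_state"] = classify_rotamer(df["alpha"].to_numpy())
        df["gamma_state"] = classify_rotamer(df["gamma"].to_numpy())
        df["chi_state"] = classify_chi(df["chi"].to_numpy())
        keep = ["time_ps", "chain", "residue", "base",
                "bi_bii", "alpha_state", "gamma_state", "chi_state", "terminal"]
        keep = [c for c in keep if c in df.columns]
        return cls(data=df[keep].reset_index(drop=True), dt=dt)

    @classmethod
    def from_labels(cls, labels, dt: float = 2.0, column: str = "bi_bii",
                    residue: int = 1, base: str = "G") -> "StateTrajectory":
        """Single-residue state trajectory from a plain label sequence."""
        labels = np.asarray(labels)
        df = pd.DataFrame(
            {
                "time_ps": np.arange(len(labels)) * dt,
                "chain": "A",
                "residue": residue,
                "base": base,
                column: labels,
                "terminal": False,
            }
        )
        return cls(data=df, dt=dt)


def assign_states(torsions: pd.DataFrame, dt: float) -> StateTrajectory:
    """Functional alias for :meth:`StateTrajectory.from_torsions`."""
    return StateTrajectory.from_torsions(torsions, dt)


def fraction_series(
    states: StateTrajectory,
    which: str = "BI",
    window_ps: float | None = None,
    column: str = "bi_bii",
    include_terminal: bool = False,
) -> pd.Series:
    """Fraction of included residues in state ``which`` versus time,
    smoothed with a centered moving average of width ``window_ps``
    (shrunken at the edges).  ``window_ps = dt`` (or None) leaves the raw
    per-frame fractions."""
    df = states.included(include_terminal)
    df = df[df[column] != "undefined"]
    if df.empty:
        raise ValueError("no residues left after exclusions")
    frac = (df[column] == which).groupby(df["time_ps"]).mean().sort_index()
    if window_ps is None:
        return frac.rename(f"fraction_{which}")
    if window_ps < states.dt:
        raise ValueError("window_ps must be >= dt")
    w = max(1, int(round(window_ps / states.dt)))
    if w == 1:
        return frac.rename(f"fraction_{which}")
    v = frac.to_numpy()
    n = len(v)
    left = (w - 1) // 2
    right = w // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n, idx + right + 1)
    out = (c[hi] - c[lo]) / (hi - lo)
    return pd.Series(out, index=frac.index, name=f"fraction_{which}")


def cumulative_mean(series) -> pd.Series:
    """Element k is the mean of the first k+1 values."""
    s = pd.Series(series)
    if s.empty:
        raise ValueError("empty series")
    out = s.expanding().mean()
    out.name = f"cummean_{s.name}" if s.name else "cummean"
    return out


@dataclass
class DwellStats:
    label: str
    mean_dwell_ps: float
    sd_dwell_ps: float
    n_complete: int
    occupancy: float


@dataclass
class DwellSummary:
    per_label: dict = field(default_factory=dict)
    passages_total: int = 0
    passages_per_residue: float = 0.0

    def __getitem__(self, label: str) -> DwellStats:
        return self.per_label[label]


def _runs(labels: np.ndarray):
    """(label, length, complete) for maximal runs of a label sequence."""
    n = len(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return [
        (labels[s], int(e - s), s > 0 and e < n)
        for s, e in zip(starts, ends)
    ]


def dwell_statistics(
    states: StateTrajectory,
    column: str = "bi_bii",
    include_terminal: bool = False,
) -> DwellSummary:
    """Residence-time statistics and passage counts per label.

    A dwell is a maximal run of one label times dt; runs touching either
    end of the trajectory are excluded from dwell means but counted in
    occupancy.  Passages (label changes) are summed over residues; the
    per-residue mean is also reported.
    """
    df = states.included(include_terminal)
    df = df[df[column] != "undefined"]
    dwells: dict[str, list] = {}
    occupancy: dict[str, int] = {}
    total_frames = 0
    passages = 0
    n_res = 0
    for (_, _), sub in df.groupby(["chain", "residue"], sort=True):
        labels = sub.sort_values("time_ps")[column].to_numpy()
        if len(labels) < 2:
            continue
        n_res += 1
        passages += int(np.sum(labels[1:] != labels[:-1]))
        total_frames += len(labels)
        for lab, length, complete in _runs(labels):
            occupancy[lab] = occupancy.get(lab, 0) + length
            if complete:
                dwells.setdefault(lab, []).append(length * states.dt)
    summary = DwellSummary(
        passages_total=passages,
        passages_per_residue=passages / n_res if n_res else 0.0,
    )
    for lab in sorted(occupancy):
        d = np.asarray(dwells.get(lab, []), dtype=float)
        summary.per_label[lab] = DwellStats(
            label=lab,
            mean_dwell_ps=float(d.mean()) if d.size else float("nan"),
            sd_dwell_ps=float(d.std(ddof=0)) if d.size else float("nan"),
            n_complete=int(d.size),
            occupancy=occupancy[lab] / total_frames,
        )
    return summary


def state_occupancy_table(
    states: StateTrajectory,
    split_steps: bool = False,
    include_terminal: bool = False,
):
    """Percentage of residue-frames in each (alpha state x gamma state) cell.

    With ``split_steps`` the table is computed separately for CpG steps
    (alpha/gamma of G residues) and GpC steps (alpha/gamma of C residues)
    and a dict of tables is returned.  Percentages sum to 100.
    """
    df = states.included(include_terminal)
    df = df[(df["alpha_state"] != "undefined") & (df["gamma_state"] != "undefined")]
    if df.empty:
        raise ValueError("no defined rotamer labels after exclusions")

    def table(sub: pd.DataFrame) -> pd.DataFrame:
        ct = pd.crosstab(sub["alpha_state"], sub["gamma_state"])
        ct = ct.reindex(index=ROTAMER_LABELS, columns=ROTAMER_LABELS, fill_value=0)
        pct = 100.0 * ct / ct.to_numpy().sum()
        pct.index.name = "alpha"
        pct.columns.name = "gamma"
        return pct

    if not split_steps:
        return table(df)
    out = {}
    for step, base in (("CpG", "G"), ("GpC", "C")):
        sub = df[df["base"] == base]
        if not sub.empty:
            out[step] = table(sub)
    if not out:
        raise ValueError("no residues with base annotation for step split")
    return out
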