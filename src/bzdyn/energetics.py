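"""MM/PBSA-style free-energy bookkeeping.

Per snapshot, the derived components are

    E_MM    = E_ELE + E_VDW + E_INT
    E_PBSUR = gamma * SA + b          (if only the surface area is given)
    E_PBSOL = E_PBSUR + E_PBCAL
    E_PBELE = E_ELE + E_PBCAL
    E_PBTOT = E_MM + E_PBSOL
    G       = E_PBTOT + TS            (TS column holds -T*S)

with the standard nonpolar coefficients gamma = 0.00542 kcal/(mol A^2) and
b = 0.92 kcal/mol.  System summaries report means and standard errors
(sample SD / sqrt(n)); contrasts report per-component differences with
propagated SE and a Welch two-sample t-test (a paired test is available
when per-snapshot data align).  The entropy term is always an input, never
computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory_io import EnergyTable

__all__ = [
    "nonpolar_term",
    "summarize",
    "contrast",
    "EnergySummary",
    "NONPOLAR_GAMMA",
    "NONPOLAR_B",
    "DERIVED_ORDER",
]

logger = logging.getLogger(__name__)

NONPOLAR_GAMMA = 0.00542  # kcal/(mol A^2)
NONPOLAR_B = 0.92  # kcal/mol

DERIVED_ORDER = (
    "E_ELE", "E_VDW", "E_INT", "E_MM", "E_PBSUR", "E_PBCAL",
    "E_PBSOL", "E_PBELE", "E_PBTOT", "TS", "G",
)


def nonpolar_term(sa, gamma: float = NONPOLAR_GAMMA, b: float = NONPOLAR_B):
    """Nonpolar solvation free energy gamma*SA + b (kcal/mol) from a
    solvent-accessible surface area in A^2."""
    sa = np.asarray(sa, dtype=float)
    if np.any(sa < 0):
        raise ValueError("surface area must be non-negative")
    out = gamma * sa + b
    return float(out) if out.ndim == 0 else out


@dataclass
class EnergySummary:
    """Means, spreads and per-snapshot derived components of one system."""

    system: str
    n: int
    means: pd.Series
    se: pd.Series
    sd: pd.Series
    snapshots: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "se": self.se, "sd": self.sd})


def summarize(table: EnergyTable, temperature: float = 300.0) -> EnergySummary:
    """Per-snapshot derived components and their system-level summary.

    All identities are applied snapshot-wise, then averaged; SE is the
    sample SD over sqrt(n).  If no entropy column (TS = -T*S) is present,
    G is omitted with a warning.  ``temperature`` is carried for
    reporting; the entropy input is already a free-energy contribution.
    """
    df = table.data.copy()
    if "E_PBSUR" not in df.columns:
        df["E_PBSUR"] = nonpolar_term(df.pop("SA").to_numpy())
    df["E_MM"] = df["E_ELE"] + df["E_VDW"] + df["E_INT"]
    df["E_PBSOL"] = df["E_PBSUR"] + df["E_PBCAL"]
    df["E_PBELE"] = df["E_ELE"] + df["E_PBCAL"]
    df["E_PBTOT"] = df["E_MM"] + df["E_PBSOL"]
    if "TS" in df.columns:
        df["G"] = df["E_PBTOT"] + df["TS"]
    else:
        logger.warning(
            "system %s has no entropy column (TS); total G omitted", table.system
        )
    cols = [c for c in DERIVED_ORDER if c in df.columns]
    df = df[cols]
    n = len(df)
    means = df.mean()
    if n < 2:
        logger.warning("system %s has %d snapshot(s); SE undefined", table.system, n)
        sd = pd.Series(np.nan, index=df.columns)
    else:
        sd = df.std(ddof=1)
    se = sd / np.sqrt(n)
    return EnergySummary(
        system=table.system, n=n, means=means, se=se, sd=sd, snapshots=df
    )


def _welch(d, se_a, se_b, sd_a, sd_b, n_a, n_b):
    """Welch t statistic, degrees of freedom and -log10 two-sided P."""
    va = sd_a**2 / n_a
    vb = sd_b**2 / n_b
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        if d == 0.0:
            return 0.0, float(n_a + n_b - 2), 0.0
        return np.inf if d > 0 else -np.inf, float(n_a + n_b - 2), np.inf
    t = d / denom
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    # -log10 P computed from the log survival function to survive underflow.
    log_p = np.log(2.0) + stats.t.logsf(abs(t), df)
    return float(t), float(df), float(-log_p / np.log(10.0))


def contrast(a: EnergySummary, b: EnergySummary, paired: bool = False) -> pd.DataFrame:
    """Per-component differences a - b with propagated SE and t-test.

    Columns: delta, se, t, df, neg_log10_p.  The default is the Welch
    (unequal-variance) two-sample test; ``paired`` uses the per-snapshot
    paired differences and requires equal snapshot counts.
    """
    common = [c for c in a.means.index if c in set(b.means.index)]
    if not common:
        raise ValueError("summaries share no components")
    if set(a.means.index) != set(b.means.index):
        raise ValueError(
            "mismatched component schemas: "
            f"{sorted(set(a.means.index) ^ set(b.means.index))}"
        )
    rows = []
    for c in common:
        d = float(a.means[c] - b.means[c])
        se = float(np.sqrt(a.se[c] ** 2 + b.se[c] ** 2))
        if paired:
            if a.n != b.n:
                raise ValueError("paired contrast requires equal snapshot counts")
            diff = a.snapshots[c].to_numpy() - b.snapshots[c].to_numpy()
            sd = diff.std(ddof=1)
            if sd == 0.0:
                t = 0.0 if d == 0.0 else np.sign(d) * np.inf
                dof = float(a.n - 1)
                nlp = 0.0 if d == 0.0 else np.inf
            else:
                t = diff.mean() / (sd / np.sqrt(a.n))
                dof = float(a.n - 1)
                log_p = np.log(2.0) + stats.t.logsf(abs(t), dof)
                nlp = float(-log_p / np.log(10.0))
        else:
            t, dof, nlp = _welch(d, a.se[c], b.se[c], a.sd[c], b.sd[c], a.n, b.n)
        rows.append(
            {"component": c, "delta": d, "se": se, "t": t, "df": dof, "neg_log10_p": nlp}
        )
    return pd.DataFrame(rows).set_index("component")
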