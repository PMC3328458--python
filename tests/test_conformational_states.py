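"""BI/BII and rotamer classification, dwell and occupancy statistics."""

import numpy as np
import pandas as pd
import pytest

from bzdyn.conformational_states import (
    StateTrajectory,
    classify_bi_bii,
    classify_chi,
    classify_rotamer,
    cumulative_mean,
    dwell_statistics,
    fraction_series,
    state_occupancy_table,
)
from bzdyn.synthetic_dynamics import TwoStateSpec, simulate_two_state, spec_from_occupancy


@pytest.mark.parametrize(
    "eps,zeta,expected",
    [
        (-170.0, -100.0, "BI"),   # eps - zeta = -70
        (-100.0, -170.0, "BII"),  # +70
        (170.0, -170.0, "BI"),    # raw +340 wraps to -20
        (-170.0, 170.0, "BII"),   # raw -340 wraps to +20
        (50.0, 50.0, "BI"),       # exact zero tie-break
        (float("nan"), 10.0, "undefined"),
    ],
)
def test_classify_bi_bii(eps, zeta, expected):
    assert classify_bi_bii(eps, zeta) == expected


def test_classify_bi_bii_uses_minimal_circular_difference(rng):
    """The call is independent of the angle reporting range."""
    eps = rng.uniform(-180, 180, 500)
    zeta = rng.uniform(-180, 180, 500)
    base = classify_bi_bii(eps, zeta)
    shifted = classify_bi_bii(eps + 360.0, zeta - 720.0)
    assert np.array_equal(base, shifted)


@pytest.mark.parametrize(
    "angle,expected",
    [(300.0, "g-"), (60.0, "g+"), (120.0, "t"), (0.0, "g+"),
     (240.0, "g-"), (-60.0, "g-"), (359.999, "g-")],
)
def test_classify_rotamer(angle, expected):
    assert classify_rotamer(angle) == expected


def test_canonical_b_dna_rotamer_state():
    assert (classify_rotamer(300.0), classify_rotamer(60.0)) == ("g-", "g+")


@pytest.mark.parametrize("chi,expected", [(-117.0, "anti"), (68.0, "syn"),
                                          (90.0, "anti"), (-90.0, "syn")])
def test_classify_chi(chi, expected):
    assert classify_chi(chi) == expected


def test_fraction_series_constant_and_identity_window():
    st = StateTrajectory.from_labels(["BI"] * 50, dt=2.0)
    f = fraction_series(st, "BI", window_ps=None)
    assert (f == 1.0).all()
    st2 = StateTrajectory.from_labels(["BI", "BII"] * 25, dt=2.0)
    raw = fraction_series(st2, "BI", window_ps=None)
    same = fraction_series(st2, "BI", window_ps=2.0)
    assert np.allclose(raw.to_numpy(), same.to_numpy())


def test_fraction_series_smoothing_window():
    labels = ["BI"] * 10 + ["BII"] * 10
    st = StateTrajectory.from_labels(labels, dt=2.0)
    sm = fraction_series(st, "BI", window_ps=10.0)  # 5 frames
    assert sm.iloc[0] == 1.0 and sm.iloc[-1] == 0.0
    # at the boundary the 5-frame window mixes the two states
    assert 0.0 < sm.iloc[10] < 1.0
    # moving average preserves the overall mean of an edge-balanced series
    assert sm.mean() == pytest.approx(0.5, abs=0.02)


def test_fraction_series_recovers_stationary_fraction():
    spec = spec_from_occupancy(0.84, 216.0, dt=2.0, n_steps=500_000, seed=21)
    res = simulate_two_state(spec)
    labels = np.where(res.states == 1, "BI", "BII")
    st = StateTrajectory.from_labels(labels, dt=2.0)
    f = fraction_series(st, "BI", window_ps=500.0)
    assert f.mean() == pytest.approx(0.84, abs=0.01)


def test_fraction_series_empty_after_exclusion():
    st = StateTrajectory.from_labels(["undefined"] * 10, dt=2.0)
    with pytest.raises(ValueError, match="no residues"):
        fraction_series(st, "BI")


def test_cumulative_mean_prefix_oracle(rng):
    v = rng.normal(size=200)
    cm = cumulative_mean(pd.Series(v))
    oracle = np.cumsum(v) / np.arange(1, len(v) + 1)
    assert np.allclose(cm.to_numpy(), oracle)
    assert list(cumulative_mean(pd.Series([1.0, 0.0]))) == [1.0, 0.5]
    assert (cumulative_mean(pd.Series([3.0] * 5)) == 3.0).all()
    with pytest.raises(ValueError):
        cumulative_mean(pd.Series([], dtype=float))


def test_dwell_statistics_hand_counted():
    """BI BI BII BII BII BI at dt=2: one complete BII dwell of 6 ps, 2 passages."""
    st = StateTrajectory.from_labels(["BI", "BI", "BII", "BII", "BII", "BI"], dt=2.0)
    d = dwell_statistics(st)
    assert d.passages_total == 2
    assert d["BII"].n_complete == 1
    assert d["BII"].mean_dwell_ps == 6.0
    # both BI runs touch an end: counted in occupancy, not in dwell means
    assert d["BI"].n_complete == 0
    assert np.isnan(d["BI"].mean_dwell_ps)
    assert d["BI"].occupancy == pytest.approx(0.5)


def test_dwell_statistics_single_label():
    st = StateTrajectory.from_labels(["BI"] * 20, dt=2.0)
    d = dwell_statistics(st)
    assert d.passages_total == 0
    assert d["BI"].n_complete == 0


@pytest.mark.parametrize("p_stay", [0.9, 0.99, 0.999])
def test_dwell_recovery_from_simulated_chain(p_stay):
    """Recovered mean dwell within 5% of dt/(1-p_stay) at 1e6 steps."""
    spec = TwoStateSpec(p_stay_1=p_stay, p_stay_2=p_stay, dt=2.0,
                        n_steps=1_000_000, seed=int(p_stay * 1000))
    res = simulate_two_state(spec)
    labels = np.where(res.states == 1, "BI", "BII")
    d = dwell_statistics(StateTrajectory.from_labels(labels, dt=2.0))
    expect = 2.0 / (1 - p_stay)
    assert d["BI"].mean_dwell_ps == pytest.approx(expect, rel=0.05)
    assert d["BII"].mean_dwell_ps == pytest.approx(expect, rel=0.05)


def test_classifier_recovers_simulated_states():
    """Sign classification of the emitted angle recovers ground truth with
    error rate < 1e-3 for +-70 degree wells at kappa >= 20."""
    spec = TwoStateSpec(p_stay_1=0.95, p_stay_2=0.9, mean_1=-70, mean_2=70,
                        kappa_1=20, kappa_2=20, n_steps=200_000, seed=30)
    res = simulate_two_state(spec)
    labels = classify_bi_bii(res.angles, np.zeros_like(res.angles))
    truth = np.where(res.states == 1, "BI", "BII")
    assert np.mean(labels != truth) < 1e-3


def _multi_residue_states(frames=400):
    rows = []
    rng = np.random.default_rng(0)
    for residue, base in [(2, "G"), (3, "C"), (4, "G")]:
        alpha = np.full(frames, 300.0)
        gamma = np.full(frames, 60.0)
        rows.append(pd.DataFrame({
            "time_ps": np.arange(frames) * 2.0,
            "chain": "A", "residue": residue, "base": base,
            "alpha_state": classify_rotamer(alpha),
            "gamma_state": classify_rotamer(gamma),
            "bi_bii": "BI", "terminal": False,
        }))
    return StateTrajectory(pd.concat(rows, ignore_index=True), dt=2.0)


def test_occupancy_table_all_canonical():
    st = _multi_residue_states()
    tab = state_occupancy_table(st)
    assert tab.loc["g-", "g+"] == pytest.approx(100.0)
    assert tab.to_numpy().sum() == pytest.approx(100.0, abs=0.01)


def test_occupancy_table_minor_state_injection():
    """A 1% g+/t admixture shows up as a ~1% cell."""
    frames = 20_000
    rng = np.random.default_rng(42)
    minor = rng.random(frames) < 0.01
    alpha = np.where(minor, 60.0, 300.0)
    gamma = np.where(minor, 150.0, 60.0)
    df = pd.DataFrame({
        "time_ps": np.arange(frames) * 2.0,
        "chain": "A", "residue": 2, "base": "G",
        "alpha_state": classify_rotamer(alpha),
        "gamma_state": classify_rotamer(gamma),
        "terminal": False,
    })
    tab = state_occupancy_table(StateTrajectory(df, dt=2.0))
    assert tab.loc["g+", "t"] == pytest.approx(1.0, abs=0.3)
    assert tab.to_numpy().sum() == pytest.approx(100.0, abs=0.01)


def test_occupancy_table_step_split():
    st = _multi_residue_states()
    tabs = state_occupancy_table(st, split_steps=True)
    assert set(tabs) == {"CpG", "GpC"}
    for t in tabs.values():
        assert t.to_numpy().sum() == pytest.approx(100.0, abs=0.01)


def test_occupancy_table_empty_after_exclusion():
    df = _multi_residue_states().data.assign(terminal=True)
    with pytest.raises(ValueError):
        state_occupancy_table(StateTrajectory(df, dt=2.0))


def test_state_trajectory_from_torsions(b_duplex):
    from bzdyn.backbone_torsions import assign_backbone_torsions

    tor = assign_backbone_torsions(b_duplex.coords, b_duplex)
    st = StateTrajectory.from_torsions(tor, dt=2.0)
    sub = st.included()
    assert set(sub.bi_bii.dropna()) <= {"BI", "BII", "undefined"}
    # ideal BI-built backbone: every defined non-terminal label is BI
    defined = sub[sub.bi_bii != "undefined"]
    assert (defined.bi_bii == "BI").all()
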