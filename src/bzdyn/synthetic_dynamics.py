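"""Synthetic inputs with the statistical structure the analyses assume.

Two generators stand in for explicit-solvent MD trajectories:

* :func:`perturb_trajectory` adds isotropic Gaussian thermal noise to a
  reference structure, giving trajectories with known per-atom mean-square
  fluctuation 3*sigma^2 (hence known theoretical B-factors).
* :func:`simulate_two_state` emits a torsion-like angular time series from
  a two-state first-order Markov chain with von Mises emissions, the
  minimal model of BI/BII-style backbone flips: geometric dwell times with
  mean dt/(1 - p_stay), stationary occupancies set by the transition
  probabilities, and circular emission wells.

Both are seed-deterministic and return ground truth where applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "TwoStateSpec",
    "TwoStateResult",
    "perturb_trajectory",
    "simulate_two_state",
    "spec_from_occupancy",
    "boltzmann_two_state_spec",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987e-3


@dataclass
class Trajectory:
    """Ordered coordinate frames congruent with a topology model."""

    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    dt: float = 2.0  # ps
    seed: int | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class TwoStateSpec:
    """Two-state Markov chain with circular (von Mises) emissions.

    ``p_stay_1``/``p_stay_2`` are per-step self-transition probabilities;
    means are emission centers in degrees on an epsilon-zeta-like
    coordinate; kappas are von Mises concentrations.
    """

    p_stay_1: float
    p_stay_2: float
    mean_1: float = -70.0
    mean_2: float = 70.0
    kappa_1: float = 20.0
    kappa_2: float = 20.0
    dt: float = 2.0
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_stay_1, self.p_stay_2):
            if not 0.0 < p < 1.0:
                raise ValueError("self-transition probabilities must be in (0, 1)")
        if self.kappa_1 <= 0 or self.kappa_2 <= 0:
            raise ValueError("kappa must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def stationary_1(self) -> float:
        """Stationary occupancy of state 1."""
        q1 = 1.0 - self.p_stay_1
        q2 = 1.0 - self.p_stay_2
        return q2 / (q1 + q2)

    @property
    def mean_dwell_1(self) -> float:
        """Mean dwell time in state 1 (ps): dt / (1 - p_stay_1)."""
        return self.dt / (1.0 - self.p_stay_1)

    @property
    def mean_dwell_2(self) -> float:
        return self.dt / (1.0 - self.p_stay_2)


@dataclass
class TwoStateResult:
    times: np.ndarray  # ps
    angles: np.ndarray  # degrees in [-180, 180)
    states: np.ndarray  # ground-truth labels, 1 or 2
    spec: TwoStateSpec = field(repr=False, default=None)


def perturb_trajectory(model, n_frames: int, sigma: float, seed: int, dt: float = 2.0) -> Trajectory:
    """Reference coordinates plus i.i.d. zero-mean Gaussian noise of
    standard deviation ``sigma`` (Angstrom) per atom per axis."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    ref = np.asarray(getattr(model, "coords", model), dtype=float)
    rng = np.random.default_rng(seed)
    frames = ref[None, :, :] + rng.normal(0.0, sigma, size=(n_frames, *ref.shape))
    return Trajectory(frames=frames, dt=dt, seed=seed)


def simulate_two_state(spec: TwoStateSpec) -> TwoStateResult:
    """Simulate the hidden two-state chain and its angular observable.

    States alternate in maximal runs whose lengths are geometric with
    success probability (1 - p_stay); the first state is drawn from the
    stationary distribution.  Emissions are von Mises around the active
    state's mean.  Returns the observable series and ground-truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_steps
    p_stay = {1: spec.p_stay_1, 2: spec.p_stay_2}
    state = 1 if rng.random() < spec.stationary_1 else 2

    states = np.empty(n, dtype=np.int8)
    pos = 0
    while pos < n:
        run = rng.geometric(1.0 - p_stay[state])
        run = min(run, n - pos)
        states[pos : pos + run] = state
        pos += run
        state = 3 - state
    mu = np.where(states == 1, spec.mean_1, spec.mean_2)
    kappa = np.where(states == 1, spec.kappa_1, spec.kappa_2)
    angles = np.degrees(rng.vonmises(np.radians(mu), kappa))
    angles = (angles + 180.0) % 360.0 - 180.0
    times = np.arange(n) * spec.dt
    return TwoStateResult(times=times, angles=angles, states=states, spec=spec)


def spec_from_occupancy(
    stationary_1: float,
    mean_dwell_1_ps: float,
    dt: float = 2.0,
    **kwargs,
) -> TwoStateSpec:
    """Spec with a prescribed stationary occupancy of state 1 and mean
    dwell time in state 1; the state-2 dwell follows from detailed balance.
    """
    if not 0.0 < stationary_1 < 1.0:
        raise ValueError("stationary_1 must be in (0, 1)")
    q1 = dt / mean_dwell_1_ps
    q2 = q1 * stationary_1 / (1.0 - stationary_1)
    if not 0.0 < q2 < 1.0:
        raise ValueError("inconsistent occupancy/dwell combination")
    return TwoStateSpec(p_stay_1=1.0 - q1, p_stay_2=1.0 - q2, dt=dt, **kwargs)


def boltzmann_two_state_spec(
    delta_g_kcal: float,
    temperature: float = 300.0,
    dt: float = 2.0,
    **kwargs,
) -> TwoStateSpec:
    """Spec drawing i.i.d. samples from a two-well Boltzmann distribution.

    State 1 is the deeper well, lower in free energy by ``delta_g_kcal``;
    occupancies follow p1/p2 = exp(dG / RT).  Setting each self-transition
    probability equal to its own stationary weight makes successive states
    independent while preserving the Boltzmann occupancies.
    """
    rt = GAS_CONSTANT_KCAL * temperature
    w = np.exp(delta_g_kcal / rt)
    p1 = w / (1.0 + w)
    return TwoStateSpec(p_stay_1=p1, p_stay_2=1.0 - p1, dt=dt, **kwargs)
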