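"""Pyramidal-interneuron gamma (PING) network of Izhikevich neurons.

The network couples regular-spiking excitatory cells (E) and fast-spiking
inhibitory interneurons (I) through conductance-like AMPA and GABA synapses
with first-order gating kinetics.  Each cell follows the two-variable
Izhikevich dynamics

    v' = 0.04 v^2 + 5 v + 140 - u + I + I_syn
    u' = a (b v - u)

with the reset rule ``v -> c``, ``u -> u + d`` whenever ``v`` crosses
+30 mV.  Synaptic gates of the *sending* cell evolve as

    s' = alpha F(v) (1 - s) - beta s,      F(v) = 1 / (1 + exp(-v / 2))

and drive a current in each *receiving* cell proportional to the
connection weight and to the distance of the receiver's membrane
potential from the reversal potential of the synapse.

The GABAergic feedback loop sets the rhythm: each volley of E spikes
excites the I population, whose GABA conductance silences the network
for roughly one decay time of the gate, producing a population rhythm
near 48 Hz for the default parameters.  The population signal (a local
field potential proxy) is the average membrane potential of the E cells.

Integration is forward Euler at ``dt`` = 1 ms by default, with all
right-hand sides evaluated at the current state and the reset applied
after the update; a finer ``dt`` may be configured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPIKE_THRESHOLD",
    "CellParameters",
    "SynapseKinetics",
    "NetworkConfig",
    "ConnectivityMatrix",
    "SimulationState",
    "SimulationResult",
    "sigmoid_gate",
    "build_connectivity",
    "synaptic_current",
    "step",
    "simulate",
    "mean_field",
]

#: Membrane potential (mV) above which a spike is registered.
SPIKE_THRESHOLD = 30.0

ROLE_EXCITATORY = "excitatory-regular-spiking"
ROLE_INHIBITORY = "inhibitory-fast-spiking"


@dataclass(frozen=True)
class CellParameters:
    """Izhikevich cell parameters.

    Parameters
    ----------
    a : float
        Recovery time scale (1/ms in model units).
    b : float
        Sensitivity of the recovery variable to ``v``.
    c : float
        Post-spike reset potential (mV); must lie below the +30 mV
        spike threshold.
    d : float
        Post-spike increment of the recovery variable.
    role : str
        Either ``"excitatory-regular-spiking"`` or
        ``"inhibitory-fast-spiking"``.
    """

    a: float
    b: float
    c: float
    d: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in (ROLE_EXCITATORY, ROLE_INHIBITORY):
            raise ValueError(f"unknown cell role: {self.role!r}")
        if not self.c < SPIKE_THRESHOLD:
            raise ValueError(
                f"reset potential c={self.c} must lie below the "
                f"{SPIKE_THRESHOLD} mV spike threshold"
            )

    @classmethod
    def regular_spiking(cls) -> "CellParameters":
        """Default excitatory (regular spiking) parameters."""
        return cls(a=0.02, b=0.2, c=-65.0, d=8.0, role=ROLE_EXCITATORY)

    @classmethod
    def fast_spiking(cls) -> "CellParameters":
        """Default inhibitory (fast spiking) parameters."""
        return cls(a=0.1, b=0.2, c=-65.0, d=2.0, role=ROLE_INHIBITORY)


@dataclass(frozen=True)
class SynapseKinetics:
    """AMPA/GABA gating rates (1/ms) and reversal potentials (mV).

    The GABA reversal depends on the receiving population: -70 mV on
    E cells and -75 mV on I cells.
    """

    alpha_ampa: float = 12.0
    beta_ampa: float = 0.5
    alpha_gaba: float = 12.0
    beta_gaba: float = 0.1
    v_ampa: float = 0.0
    v_gaba_on_e: float = -70.0
    v_gaba_on_i: float = -75.0

    def __post_init__(self) -> None:
        for name in ("alpha_ampa", "beta_ampa", "alpha_gaba", "beta_gaba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (self.v_gaba_on_e < self.v_ampa and self.v_gaba_on_i < self.v_ampa):
            raise ValueError("GABA reversal potentials must lie below the AMPA reversal")


@dataclass(frozen=True)
class NetworkConfig:
    """Network size, connection strengths and integration settings.

    Connection strengths are the *maximum* current-per-spike coupling of
    a single connection; each realized weight is the block strength
    scaled by an independent Uniform[0, 1] draw.  ``c_xy`` denotes the
    strength of connections from population ``y`` onto population ``x``
    (e.g. ``c_ie`` is I -> E).

    ``v0_spread`` is the width (mV) of the uniform interval, centred on
    the reset potential, from which initial membrane potentials are
    drawn; it breaks the artificial symmetry of identical initial
    conditions so the network settles into its stationary rhythm within
    a few hundred milliseconds.
    """

    n_e: int = 400
    n_i: int = 100
    c_ee: float = 0.0
    c_ei: float = 0.003
    c_ie: float = 0.006
    c_ii: float = 0.004
    dt: float = 1.0
    seed: int | None = None
    cell_params_e: CellParameters = field(default_factory=CellParameters.regular_spiking)
    cell_params_i: CellParameters = field(default_factory=CellParameters.fast_spiking)
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    v0_spread: float = 10.0

    def __post_init__(self) -> None:
        if self.n_e < 1 or self.n_i < 1:
            raise ValueError("n_e and n_i must be at least 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("c_ee", "c_ei", "c_ie", "c_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.v0_spread < 0:
            raise ValueError("v0_spread must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    def with_total_size(self, total: int) -> "NetworkConfig":
        """Resize the network preserving the 4:1 E:I ratio."""
        if total % 5 != 0 or total < 5:
            raise ValueError("total network size must be a positive multiple of 5")
        return replace(self, n_e=4 * total // 5, n_i=total // 5)

    def roles(self) -> tuple[str, ...]:
        return (ROLE_EXCITATORY,) * self.n_e + (ROLE_INHIBITORY,) * self.n_i


@dataclass
class ConnectivityMatrix:
    """Weighted directed synaptic strengths, ``weights[receiver, sender]``."""

    weights: np.ndarray
    cell_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.cell_roles):
            raise ValueError("weights and cell_roles sizes disagree")
        if np.any(w < 0):
            raise ValueError("synaptic weights must be non-negative")
        self.weights = w

    @property
    def n_e(self) -> int:
        return sum(1 for r in self.cell_roles if r == ROLE_EXCITATORY)


@dataclass
class SimulationState:
    """Instantaneous network state.

    ``s_ampa`` holds one gate per E cell and ``s_gaba`` one gate per
    I cell; both are kept in [0, 1] by clipping after each Euler step.
    """

    v: np.ndarray
    u: np.ndarray
    s_ampa: np.ndarray
    s_gaba: np.ndarray
    t: float = 0.0


@dataclass
class SimulationResult:
    """Output of :func:`simulate`.

    ``mean_field`` is the average membrane potential of the E cells at
    every step (spike excursions capped at +30 mV for recording), the
    model's proxy for the population signal seen by MEG.
    """

    time: np.ndarray
    spikes: list[np.ndarray]
    mean_field: np.ndarray
    config: NetworkConfig
    seed: int | None
    stimulus_used: object = None
    v_traces: np.ndarray | None = None

    def raster_frame(self) -> pd.DataFrame:
        """Spikes as a tidy two-column table (cell_id, spike_time_ms)."""
        cells = np.concatenate(
            [np.full(len(t), i) for i, t in enumerate(self.spikes)]
        ) if any(len(t) for t in self.spikes) else np.array([], dtype=int)
        times = np.concatenate(self.spikes) if len(cells) else np.array([])
        return pd.DataFrame({"cell_id": cells.astype(int), "spike_time_ms": times})

    def save(self, path: str | Path) -> None:
        """Write arrays to ``<path>.npz`` and config/seed to ``<path>.json``."""
        path = Path(path)
        arrays = {
            "time": self.time,
            "mean_field": self.mean_field,
            "spike_cell": self.raster_frame()["cell_id"].to_numpy(),
            "spike_time_ms": self.raster_frame()["spike_time_ms"].to_numpy(),
        }
        if self.v_traces is not None:
            arrays["v_traces"] = self.v_traces
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"seed": self.seed, "config": _config_to_dict(self.config)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationResult":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        config = _config_from_dict(meta["config"])
        spikes = [np.array([]) for _ in range(config.n_total)]
        cells = data["spike_cell"].astype(int)
        for i in range(config.n_total):
            spikes[i] = data["spike_time_ms"][cells == i]
        return cls(
            time=data["time"],
            spikes=spikes,
            mean_field=data["mean_field"],
            config=config,
            seed=meta["seed"],
            v_traces=data["v_traces"] if "v_traces" in data else None,
        )


def _config_to_dict(config: NetworkConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    d["cell_params_e"] = CellParameters(**d["cell_params_e"])
    d["cell_params_i"] = CellParameters(**d["cell_params_i"])
    d["kinetics"] = SynapseKinetics(**d["kinetics"])
    return NetworkConfig(**d)


def sigmoid_gate(v):
    """Sigmoid gate drive ``F(v) = 1 / (1 + exp(-v / 2))``.

    Strictly increasing in ``v``; raises on non-finite input.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    out = 1.0 / (1.0 + np.exp(-np.clip(v, -700.0, 700.0) / 2.0))
    return out if out.ndim else float(out)


def build_connectivity(
    config: NetworkConfig, seed: int | np.random.Generator | None = None
) -> ConnectivityMatrix:
    """Draw a block-structured connectivity matrix.

    Every allowed pair is connected with weight ``base * u``,
    ``u ~ Uniform[0, 1]``, where the base strength depends only on the
    sender/receiver populations.  Self-connections are removed.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_e, n_i, n = config.n_e, config.n_i, config.n_total
    w = np.zeros((n, n))
    w[:n_e, :n_e] = config.c_ee * rng.uniform(size=(n_e, n_e))
    w[n_e:, :n_e] = config.c_ei * rng.uniform(size=(n_i, n_e))
    w[:n_e, n_e:] = config.c_ie * rng.uniform(size=(n_e, n_i))
    w[n_e:, n_e:] = config.c_ii * rng.uniform(size=(n_i, n_i))
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, cell_roles=config.roles())


def synaptic_current(
    state: SimulationState,
    conn: ConnectivityMatrix,
    kinetics: SynapseKinetics,
) -> np.ndarray:
    """Per-cell synaptic current from the current gates and potentials.

    For receiver ``k``::

        I_syn(k) = sum_i C[k, i] s_ampa(i) (v_ampa - v_k)
                 + sum_j C[k, j] s_gaba(j) (v_gaba(role_k) - v_k)

    with the GABA reversal chosen by the *receiver's* role.
    """
    n = conn.weights.shape[0]
    n_e = conn.n_e
    if state.v.shape[0] != n:
        raise ValueError("state and connectivity sizes disagree")
    if state.s_ampa.shape[0] != n_e or state.s_gaba.shape[0] != n - n_e:
        raise ValueError("gate vectors do not match the population split")
    g_ampa = conn.weights[:, :n_e] @ state.s_ampa
    g_gaba = conn.weights[:, n_e:] @ state.s_gaba
    v_gaba = np.where(
        np.asarray(conn.cell_roles) == ROLE_EXCITATORY,
        kinetics.v_gaba_on_e,
        kinetics.v_gaba_on_i,
    )
    return g_ampa * (kinetics.v_ampa - state.v) + g_gaba * (v_gaba - state.v)


class _NetworkArrays:
    """Precomputed per-cell parameter vectors for the update loop."""

    def __init__(self, config: NetworkConfig):
        n_e, n_i = config.n_e, config.n_i
        pe, pi = config.cell_params_e, config.cell_params_i
        self.n_e, self.n_i = n_e, n_i
        self.a = np.r_[np.full(n_e, pe.a), np.full(n_i, pi.a)]
        self.b = np.r_[np.full(n_e, pe.b), np.full(n_i, pi.b)]
        self.c = np.r_[np.full(n_e, pe.c), np.full(n_i, pi.c)]
        self.d = np.r_[np.full(n_e, pe.d), np.full(n_i, pi.d)]
        k = config.kinetics
        self.v_gaba = np.r_[np.full(n_e, k.v_gaba_on_e), np.full(n_i, k.v_gaba_on_i)]
        self.kin = k


def _euler_update(v, u, s_ampa, s_gaba, i_ext, conn_e, conn_i, arrays, dt):
    """One forward-Euler step; returns new state arrays and spike mask.

    All derivatives are evaluated at the incoming state; the threshold
    test uses the updated potential and the reset is applied afterwards.
    """
    k = arrays.kin
    g_ampa = conn_e @ s_ampa
    g_gaba = conn_i @ s_gaba
    i_syn = g_ampa * (k.v_ampa - v) + g_gaba * (arrays.v_gaba - v)
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_ext + i_syn)
    u_new = u + dt * arrays.a * (arrays.b * v - u)
    gate = 1.0 / (1.0 + np.exp(-np.clip(v, -700.0, 700.0) / 2.0))
    n_e = arrays.n_e
    s_ampa_new = np.clip(
        s_ampa + dt * (k.alpha_ampa * gate[:n_e] * (1.0 - s_ampa) - k.beta_ampa * s_ampa),
        0.0,
        1.0,
    )
    s_gaba_new = np.clip(
        s_gaba + dt * (k.alpha_gaba * gate[n_e:] * (1.0 - s_gaba) - k.beta_gaba * s_gaba),
        0.0,
        1.0,
    )
    spiked = v_new > SPIKE_THRESHOLD
    v_rec = np.minimum(v_new, SPIKE_THRESHOLD)
    v_new = np.where(spiked, arrays.c, v_new)
    u_new = np.where(spiked, u_new + arrays.d, u_new)
    return v_new, u_new, s_ampa_new, s_gaba_new, spiked, v_rec


def step(
    state: SimulationState,
    input_current: np.ndarray | tuple[float, float],
    conn: ConnectivityMatrix,
    kinetics: SynapseKinetics | None = None,
    config: NetworkConfig | None = None,
    dt: float = 1.0,
) -> tuple[SimulationState, np.ndarray]:
    """Advance the network by one Euler step.

    ``input_current`` is either a per-cell vector or an ``(i_e, i_i)``
    pair broadcast over the two populations.  Raises if the incoming
    state contains NaNs, naming the first offending cell.
    """
    if config is None:
        config = NetworkConfig(n_e=conn.n_e, n_i=len(conn.cell_roles) - conn.n_e)
        if kinetics is not None:
            config = replace(config, kinetics=kinetics)
    if dt <= 0:
        raise ValueError("dt must be positive")
    bad = np.flatnonzero(np.isnan(state.v))
    if bad.size:
        raise FloatingPointError(
            f"NaN membrane potential in cell {bad[0]} at t={state.t} ms"
        )
    arrays = _NetworkArrays(config)
    if isinstance(input_current, tuple):
        i_ext = np.r_[
            np.full(config.n_e, float(input_current[0])),
            np.full(config.n_i, float(input_current[1])),
        ]
    else:
        i_ext = np.asarray(input_current, dtype=float)
    n_e = config.n_e
    v, u, sa, sg, spiked, _ = _euler_update(
        state.v,
        state.u,
        state.s_ampa,
        state.s_gaba,
        i_ext,
        conn.weights[:, :n_e],
        conn.weights[:, n_e:],
        arrays,
        dt,
    )
    new = SimulationState(v=v, u=u, s_ampa=sa, s_gaba=sg, t=state.t + dt)
    return new, spiked


def initial_state(
    config: NetworkConfig, rng: np.random.Generator | int | None = None
) -> SimulationState:
    """Initial state: ``v`` uniform on ``c ± v0_spread/2``, ``u = b v``."""
    rng = np.random.default_rng(rng)
    arrays = _NetworkArrays(config)
    v = arrays.c + config.v0_spread * (rng.uniform(size=config.n_total) - 0.5)
    return SimulationState(
        v=v,
        u=arrays.b * v,
        s_ampa=np.zeros(config.n_e),
        s_gaba=np.zeros(config.n_i),
        t=0.0,
    )


def simulate(
    config: NetworkConfig,
    stimulus,
    duration_ms: float | None = None,
    seed: int | np.random.SeedSequence | None = None,
    record_traces: bool = False,
) -> SimulationResult:
    """Integrate the full network under a stimulus train.

    Parameters
    ----------
    config : NetworkConfig
    stimulus : StimulusTrain
        Must cover ``[0, duration_ms]`` at the configured ``dt``.
    duration_ms : float, optional
        Defaults to the stimulus duration.
    seed : int or SeedSequence, optional
        Controls the connectivity draw and the initial conditions.
        Identical ``(config, stimulus, seed)`` give bit-identical output.
    record_traces : bool
        Keep per-cell membrane traces (float32, capped at +30 mV).

    Returns
    -------
    SimulationResult
    """
    dt = config.dt
    i_e = np.asarray(stimulus.i_e, dtype=float)
    i_i = np.asarray(stimulus.i_i, dtype=float)
    if duration_ms is None:
        duration_ms = len(i_e) * dt
    n_steps = int(round(duration_ms / dt))
    if len(i_e) < n_steps or len(i_i) < n_steps:
        raise ValueError(
            f"stimulus covers {len(i_e) * dt:g} ms but {duration_ms:g} ms requested"
        )
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)
    conn = build_connectivity(config, rng)
    state = initial_state(config, rng)
    arrays = _NetworkArrays(config)
    n_e, n = config.n_e, config.n_total
    conn_e = conn.weights[:, :n_e]
    conn_i = conn.weights[:, n_e:]
    v, u = state.v, state.u
    sa, sg = state.s_ampa, state.s_gaba
    mean_field_arr = np.empty(n_steps)
    spike_steps: list[np.ndarray] = []
    traces = np.empty((n_steps, n), dtype=np.float32) if record_traces else None
    i_ext = np.empty(n)
    for t in range(n_steps):
        i_ext[:n_e] = i_e[t]
        i_ext[n_e:] = i_i[t]
        v, u, sa, sg, spiked, v_rec = _euler_update(
            v, u, sa, sg, i_ext, conn_e, conn_i, arrays, dt
        )
        if np.isnan(v).any():
            bad = int(np.flatnonzero(np.isnan(v))[0])
            raise FloatingPointError(
                f"NaN membrane potential in cell {bad} at t={(t + 1) * dt:g} ms"
            )
        mean_field_arr[t] = v_rec[:n_e].mean()
        spike_steps.append(np.flatnonzero(spiked))
        if record_traces:
            traces[t] = v_rec
    spikes: list[list[float]] = [[] for _ in range(n)]
    for t, cells in enumerate(spike_steps):
        tms = (t + 1) * dt
        for cidx in cells:
            spikes[cidx].append(tms)
    time = np.arange(1, n_steps + 1) * dt
    return SimulationResult(
        time=time,
        spikes=[np.asarray(s) for s in spikes],
        mean_field=mean_field_arr,
        config=config,
        seed=seed if isinstance(seed, int) or seed is None else None,
        stimulus_used=stimulus,
        v_traces=traces,
    )


def mean_field(result: SimulationResult) -> np.ndarray:
    """Average membrane potential over the E cells only.

    Recomputed from the stored traces when available, otherwise the
    running average recorded during integration is returned.
    """
    if result.v_traces is not None:
        return result.v_traces[:, : result.config.n_e].mean(axis=1)
    return result.mean_field
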