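"""The stochastic 1D loop-extrusion engine.

A :class:`SimState` owns the mutable arrays describing every LEF (positions,
roles, stall flags) plus the site-occupancy table, and is advanced either
event-by-event (the single-event operations, useful for tests and for
stepping coupled simulations) or by one of the schedulers:

``gillespie_run``
    Event-driven continuous-time dynamics (exact sampling of the Markov
    chain via uniformization).  Valid for model variants whose rates are
    state-independent: pure one-sided, two-sided, mixtures, switching and
    pushing.  The semi-diffusive model (loop-size-dependent rates) is
    refused; use ``fixed_step_run``.

``fixed_step_run``
    The discrete-time chain in which each candidate event fires
    independently with probability ``k_i * dt`` per step.  ``method="sweep"``
    runs the literal per-step Bernoulli sweep (also the hook for 3D
    coupling and the bacterial deterministic-extruder mode);
    ``method="events"`` runs the identical chain law via per-slot geometric
    waiting times, with cost proportional to the number of events (the only
    practical option for long semi-diffusive runs).

All randomness flows through one seeded generator; identical
(config, params, seed) reproduce identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import ConfigurationError, LatticeConfig, LEFParams, derived_scales

__all__ = [
    "SimState",
    "Trajectory",
    "init_simulation",
    "bind_lef",
    "unbind_lef",
    "translocate_active",
    "diffusive_rates",
    "diffusive_step",
    "switch_roles",
    "gillespie_run",
    "fixed_step_run",
]


@dataclass
class Trajectory:
    """Snapshots of all LEFs at the sampling times of a run.

    Positions are -1 for unbound LEFs.  ``loops(i)`` returns the bound-loop
    intervals ``[(left, right), ...]`` of snapshot ``i``.
    """

    times: np.ndarray
    left: np.ndarray  # (n_samples, N)
    right: np.ndarray
    active_left: np.ndarray
    active_right: np.ndarray
    stalled_left: np.ndarray
    stalled_right: np.ndarray
    bound: np.ndarray
    n_sites: int
    site_size_kb: float = 0.5

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def n_lefs(self) -> int:
        return self.left.shape[1]

    def loops(self, i: int) -> list[tuple[int, int]]:
        m = self.bound[i] == 1
        return list(zip(self.left[i, m].tolist(), self.right[i, m].tolist()))

    def bound_fraction(self) -> np.ndarray:
        return self.bound.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (snapshot, bound LEF)."""
        rows = []
        for i, t in enumerate(self.times):
            for j in range(self.n_lefs):
                if self.bound[i, j]:
                    rows.append(
                        (
                            t,
                            j,
                            int(self.left[i, j]),
                            int(self.right[i, j]),
                            "both"
                            if self.active_left[i, j] and self.active_right[i, j]
                            else ("left" if self.active_left[i, j] else "right"),
                            int(self.stalled_left[i, j]),
                            int(self.stalled_right[i, j]),
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "time",
                "lef_id",
                "left_pos",
                "right_pos",
                "active_side",
                "stalled_left",
                "stalled_right",
            ],
        )


@dataclass
class SimState:
    """Mutable simulation state: LEF arrays, occupancy and the clock."""

    config: LatticeConfig
    params: LEFParams
    seed: int
    time: float = 0.0
    # per-LEF arrays
    left: np.ndarray = field(default=None, repr=False)
    right: np.ndarray = field(default=None, repr=False)
    act_l: np.ndarray = field(default=None, repr=False)
    act_r: np.ndarray = field(default=None, repr=False)
    stall_l: np.ndarray = field(default=None, repr=False)
    stall_r: np.ndarray = field(default=None, repr=False)
    bound: np.ndarray = field(default=None, repr=False)
    two_s: np.ndarray = field(default=None, repr=False)
    # lattice arrays
    occ: np.ndarray = field(default=None, repr=False)
    occ_side: np.ndarray = field(default=None, repr=False)
    stallp_l: np.ndarray = field(default=None, repr=False)
    stallp_r: np.ndarray = field(default=None, repr=False)
    bar_id_l: np.ndarray = field(default=None, repr=False)
    bar_id_r: np.ndarray = field(default=None, repr=False)
    passed: np.ndarray = field(default=None, repr=False)
    unload: np.ndarray = field(default=None, repr=False)
    load_cdf: np.ndarray = field(default=None, repr=False)
    uniform_load: bool = True
    orient: np.ndarray = field(default=None, repr=False)

    @property
    def n_bound(self) -> int:
        return int(self.bound.sum())

    def loops(self) -> list[tuple[int, int]]:
        m = self.bound == 1
        return list(zip(self.left[m].tolist(), self.right[m].tolist()))

    def check_occupancy(self) -> bool:
        """Audit that the occupancy table mirrors the LEF arrays exactly."""
        if self.params.traversal:
            return True
        occ = np.zeros(self.config.n_sites, dtype=np.int64)
        for i in range(self.params.n_lefs):
            if self.bound[i]:
                for pos in (self.left[i], self.right[i]):
                    if occ[pos] != 0:
                        return False
                    occ[pos] = i + 1
        return bool(np.array_equal(occ, self.occ))

    def _kernel_args(self):
        p = self.params
        push = {"none": 0, "weak": 1, "strong": 2}[p.pushing]
        return (
            self.left, self.right, self.act_l, self.act_r,
            self.stall_l, self.stall_r, self.bound, self.two_s,
            self.occ, self.occ_side,
            self.stallp_l, self.stallp_r, self.bar_id_l, self.bar_id_r,
            self.passed, self.unload,
            self.load_cdf, self.uniform_load, self.orient,
            p.v, p.v_diff, p.k_bind, p.k_unbind, p.k_switch, p.sidedness,
            np.uint8(1 if p.traversal else 0), np.int64(push),
        )


def init_simulation(config: LatticeConfig, params: LEFParams, seed: int) -> SimState:
    """Create a fresh state: all N LEFs unbound, empty lattice, time 0."""
    L = config.n_sites
    N = params.n_lefs
    if not params.traversal and N > L / 2:
        raise ConfigurationError(
            f"cannot ever place {N} LEFs (2 sites each) on {L} sites"
        )
    st = SimState(config=config, params=params, seed=int(seed))
    st.left = np.full(N, -1, dtype=np.int64)
    st.right = np.full(N, -1, dtype=np.int64)
    for name in ("act_l", "act_r", "stall_l", "stall_r", "bound", "two_s"):
        setattr(st, name, np.zeros(N, dtype=np.uint8))
    st.occ = np.zeros(L, dtype=np.int64)
    st.occ_side = np.zeros(L, dtype=np.uint8)
    st.stallp_l = np.zeros(L, dtype=np.float64)
    st.stallp_r = np.zeros(L, dtype=np.float64)
    st.bar_id_l = np.full(L, -1, dtype=np.int64)
    st.bar_id_r = np.full(L, -1, dtype=np.int64)
    for i, b in enumerate(config.barriers):
        if b.orientation == "left-blocking":
            st.stallp_l[b.site] = b.p_stall
            st.bar_id_l[b.site] = i
        else:
            st.stallp_r[b.site] = b.p_stall
            st.bar_id_r[b.site] = i
    st.passed = np.zeros((N, 2, max(1, len(config.barriers))), dtype=np.uint8)
    st.unload = np.zeros(L, dtype=np.uint8)
    for s in config.terminal_unload_sites:
        st.unload[s] = 1
    if config.loading_weights is None:
        st.uniform_load = True
        st.load_cdf = np.ones(max(L - 1, 1), dtype=np.float64)
    else:
        st.uniform_load = False
        st.load_cdf = np.cumsum(
            np.asarray(config.loading_weights[: L - 1], dtype=np.float64)
        )
    if config.loading_orientation is None:
        st.orient = np.zeros(L, dtype=np.int8)
    else:
        st.orient = np.asarray(config.loading_orientation, dtype=np.int8)
    K.seed_rng(int(seed) & 0x7FFFFFFF)
    return st


# ---------------------------------------------------------------------------
# single-event operations
# ---------------------------------------------------------------------------

def bind_lef(state: SimState, lef_index: int) -> SimState:
    """One binding attempt: a weighted random site pair, rejected if occupied."""
    if state.bound[lef_index]:
        raise ValueError(f"LEF {lef_index} is already bound")
    a = state._kernel_args()
    K._bind_attempt(lef_index, *a[:8], a[8], a[9], a[14], a[16], a[17], a[18],
                    state.params.sidedness,
                    np.uint8(1 if state.params.traversal else 0))
    return state


def unbind_lef(state: SimState, lef_index: int) -> SimState:
    """Unbind a bound LEF: both sites freed, stall flags cleared."""
    if not state.bound[lef_index]:
        raise ValueError(f"LEF {lef_index} is not bound")
    a = state._kernel_args()
    K._do_unbind(lef_index, *a[:8], a[8], a[9],
                 np.uint8(1 if state.params.traversal else 0))
    return state


def translocate_active(state: SimState, lef_index: int, subunit: str) -> SimState:
    """One active-translocation attempt of the named subunit ('left'/'right')."""
    side = {"left": 0, "right": 1}[subunit]
    if not state.bound[lef_index]:
        raise ValueError(f"LEF {lef_index} is not bound")
    active = state.act_l[lef_index] if side == 0 else state.act_r[lef_index]
    if not active:
        raise ValueError(
            f"{subunit} subunit of LEF {lef_index} is passive-anchored"
        )
    a = state._kernel_args()
    K._try_step(lef_index, side, *a[:8], a[8], a[9], a[10], a[11], a[12],
                a[13], a[14], a[15], a[-2], a[-1])
    return state


def diffusive_rates(loop_size: float, params: LEFParams) -> tuple[float, float]:
    """Loop-entropy-biased rates (grow, shrink) of a passive diffusive subunit.

    ``rate_grow = v_diff * exp(-(3/2)/ell)``, ``rate_shrink = v_diff *
    exp(+(3/2)/ell)`` with the loop size ``ell`` in sites; sliding is biased
    toward shrinking small loops and becomes an unbiased walk as ell -> inf.
    """
    if loop_size < 1:
        raise ValueError(f"loop size must be >= 1 site, got {loop_size}")
    return (
        params.v_diff * float(np.exp(-1.5 / loop_size)),
        params.v_diff * float(np.exp(1.5 / loop_size)),
    )


def diffusive_step(state: SimState, lef_index: int, grow: bool = True) -> SimState:
    """One diffusive-step attempt of the passive subunit at its bound rate.

    The attempt is internally thinned to the current loop-size-dependent
    rate from :func:`diffusive_rates`, so callers draw attempts at the
    constant bounds ``v_diff`` (grow) and ``v_diff * e^{3/2}`` (shrink).
    """
    if not state.bound[lef_index]:
        raise ValueError(f"LEF {lef_index} is not bound")
    if state.two_s[lef_index]:
        raise ValueError("two-sided LEFs have no diffusive subunit")
    a = state._kernel_args()
    K._try_diff(lef_index, grow, *a[:8], a[8], a[9], a[10], a[11], a[12],
                a[13], a[14], a[15], a[-2])
    return state


def switch_roles(state: SimState, lef_index: int) -> SimState:
    """Exchange active and anchored subunit roles (switching model)."""
    if not state.bound[lef_index]:
        raise ValueError(f"LEF {lef_index} is not bound")
    if state.two_s[lef_index]:
        raise ValueError("switch_roles on a two-sided LEF")
    K._do_switch(lef_index, state.act_l, state.act_r, state.bound, state.two_s)
    return state


# ---------------------------------------------------------------------------
# schedulers
# ---------------------------------------------------------------------------

def _sample_times(state: SimState, t_end: float, sample_interval: float | None,
                  n_samples: int | None) -> np.ndarray:
    t0 = state.time
    if sample_interval is not None:
        return np.arange(t0 + sample_interval, t_end + 1e-9, sample_interval)
    if n_samples is None:
        n_samples = 200
    return np.linspace(t0, t_end, n_samples + 1)[1:]


def _alloc_out(n_samples: int, n_lefs: int):
    il = np.full((n_samples, n_lefs), -1, dtype=np.int64)
    ir = np.full((n_samples, n_lefs), -1, dtype=np.int64)
    u8 = [np.zeros((n_samples, n_lefs), dtype=np.uint8) for _ in range(5)]
    return il, ir, u8


def _make_trajectory(state, times, il, ir, u8) -> Trajectory:
    return Trajectory(
        times=np.asarray(times, dtype=float),
        left=il, right=ir,
        active_left=u8[0], active_right=u8[1],
        stalled_left=u8[2], stalled_right=u8[3], bound=u8[4],
        n_sites=state.config.n_sites,
        site_size_kb=state.config.site_size_kb,
    )


def gillespie_run(
    state: SimState,
    t_end: float,
    sample_interval: float | None = None,
    n_samples: int | None = None,
) -> Trajectory:
    """Exact event-driven run until ``t_end``; snapshots at the sample times.

    Refuses the semi-diffusive model (its stepping rates depend on the live
    loop sizes); use :func:`fixed_step_run` there.
    """
    if state.params.v_diff > 0:
        raise ConfigurationError(
            "gillespie_run does not support the semi-diffusive model; "
            "use fixed_step_run"
        )
    times = _sample_times(state, t_end, sample_interval, n_samples)
    il, ir, u8 = _alloc_out(len(times), state.params.n_lefs)
    K.run_events(*state._kernel_args(), np.uint8(1), 1.0, state.time,
                 float(t_end), times, il, ir, *u8)
    state.time = float(t_end)
    return _make_trajectory(state, times, il, ir, u8)


def fixed_step_run(
    state: SimState,
    dt: float,
    t_end: float,
    sample_interval: float | None = None,
    n_samples: int | None = None,
    method: str = "auto",
    deterministic: bool = False,
) -> Trajectory:
    """Fixed-time-step run: every candidate event fires w.p. ``k_i * dt``.

    ``method``: ``"sweep"`` iterates every LEF each step (random permutation,
    random subunit order); ``"events"`` realizes the identical chain via
    per-slot geometric waiting times (efficient for long runs); ``"auto"``
    picks ``"events"`` unless ``deterministic`` stepping is requested.
    ``deterministic=True`` makes active subunits step every ``dt`` with
    probability 1 (bacterial deterministic extruders); only the sweep
    supports it.
    """
    p = state.params
    if method == "auto":
        method = "sweep" if deterministic else "events"
    if deterministic and method != "sweep":
        raise ConfigurationError("deterministic stepping requires method='sweep'")
    # the sweep subdivides diffusive attempts internally, so v_diff is only
    # capped for the event-skipping method
    rate_cap = max(p.k_unbind, p.k_switch,
                   p.v_diff * K.SHRINK_BOUND if method == "events" else 0.0,
                   0.0 if deterministic else max(p.v, p.k_bind))
    if rate_cap * dt > 0.1 + 1e-12:
        raise ConfigurationError(
            f"dt={dt} too coarse: max event probability per step is "
            f"{rate_cap * dt:.3f} > 0.1"
        )
    if deterministic and p.k_bind * dt > 1.0 + 1e-12:
        raise ConfigurationError("k_bind * dt must be <= 1")
    times = _sample_times(state, t_end, sample_interval, n_samples)
    n_steps = int(round((t_end - state.time) / dt))
    sample_steps = np.ceil((times - state.time) / dt - 1e-9).astype(np.int64)
    il, ir, u8 = _alloc_out(len(times), p.n_lefs)
    if method == "events":
        K.run_events(*state._kernel_args(), np.uint8(0), float(dt),
                     state.time, float(t_end), times, il, ir, *u8)
    elif method == "sweep":
        K.run_sweep(*state._kernel_args(), float(dt), n_steps,
                    np.uint8(1 if deterministic else 0), sample_steps,
                    il, ir, *u8)
    else:
        raise ValueError(f"unknown method {method!r}")
    state.time = state.time + n_steps * dt
    return _make_trajectory(state, times, il, ir, u8)


def recommended_duration(config: LatticeConfig, params: LEFParams) -> float:
    """Simulation span 400 * max(1/k_unbind + 1/k_bind, L/v + 1/k_bind).

    The long-run default for steady-state compaction studies; statistics are
    collected over the second half.
    """
    p = params
    return 400.0 * max(
        1.0 / p.k_unbind + 1.0 / p.k_bind,
        config.n_sites / p.v + 1.0 / p.k_bind,
    )
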