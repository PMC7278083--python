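"""Runge–Kutta integration of the SCC cascade.

Two steppers are provided: the classical constant-step 4th-order
Runge–Kutta method and the embedded Cash–Karp 4(5) pair for adaptive step
sizes.  Both evaluate every stage on the full cascade in topological
order — each block sees its parents' same-stage values — so the cascade
integrator is exactly the monolithic Runge–Kutta method.

Adaptive steps are controlled on a *pilot* subsystem: the weight-0 mass
isotopomers of the smallest topological prefix of SCCs that covers at
least one EMU of every metabolite.  Because mass isotopomers of one EMU
sum to one and evolve with similar steepness, the step accepted for the
pilot set is broadcast to all SCCs.

``run_parallel`` executes the same arithmetic under a dependency-gated
scheduler contract: per-(block, stage) tasks become ready only once the
parents' previous-stage values are delivered, and a fixed reduction order
makes the result bit-for-bit identical to the serial integrator for any
worker count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "StepController",
    "rk4_step",
    "cash_karp_step",
    "integrate_constant",
    "integrate_adaptive",
    "pilot_controller",
    "run_parallel",
]


# ---------------------------------------------------------------------------
# Butcher tableaus
# ---------------------------------------------------------------------------

class _Tableau:
    def __init__(self, c, a, b, b_err=None):
        self.c = c
        self.a = a  # a[s] = coefficients of stages < s for stage-s input
        self.b = b
        self.b_err = b_err  # b - b_hat for embedded error estimate

    @property
    def stages(self) -> int:
        return len(self.c)


RK4 = _Tableau(
    c=[0.0, 0.5, 0.5, 1.0],
    a=[[], [0.5], [0.0, 0.5], [0.0, 0.0, 1.0]],
    b=[1 / 6, 1 / 3, 1 / 3, 1 / 6],
)

CASH_KARP = _Tableau(
    c=[0.0, 1 / 5, 3 / 10, 3 / 5, 1.0, 7 / 8],
    a=[
        [],
        [1 / 5],
        [3 / 40, 9 / 40],
        [3 / 10, -9 / 10, 6 / 5],
        [-11 / 54, 5 / 2, -70 / 27, 35 / 27],
        [1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096],
    ],
    b=[37 / 378, 0.0, 250 / 621, 125 / 594, 0.0, 512 / 1771],
    b_err=[
        37 / 378 - 2825 / 27648,
        0.0,
        250 / 621 - 18575 / 48384,
        125 / 594 - 13525 / 55296,
        -277 / 14336,
        512 / 1771 - 1 / 4,
    ],
)


def _combine(x, h, coeffs, ks):
    """x + h * sum_l coeffs[l] * ks[l], with a fixed accumulation order
    (zero coefficients skipped identically on full arrays and slices)."""
    acc = None
    for c, k in zip(coeffs, ks):
        if c == 0.0:
            continue
        acc = c * k if acc is None else acc + c * k
    if acc is None:
        return x.copy() if hasattr(x, "copy") else x
    return x + h * acc


def _check_finite(x):
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite state encountered during integration")


# ---------------------------------------------------------------------------
# Serial stage sweeps
# ---------------------------------------------------------------------------

def _stages_serial(system, x, t, h, tab):
    ks = []
    for s in range(tab.stages):
        y = x if s == 0 else _combine(x, h, tab.a[s], ks)
        ks.append(system.rhs(y, t + tab.c[s] * h))
    return ks


def rk4_step(system, state, t, h, ks=None):
    """One classical RK4 step on the full cascade (stage weights
    (1, 2, 2, 1)/6, stages at t, t+h/2, t+h/2, t+h)."""
    if h <= 0:
        raise ValueError("step size must be positive")
    ks = _stages_serial(system, state, t, h, RK4) if ks is None else ks
    out = _combine(state, h, RK4.b, ks)
    _check_finite(out)
    return out


def cash_karp_step(system, state, t, h, ks=None):
    """One embedded Cash–Karp 4(5) step.

    Returns (5th-order candidate state, per-component |4th - 5th| error
    estimate)."""
    if h <= 0:
        raise ValueError("step size must be positive")
    ks = _stages_serial(system, state, t, h, CASH_KARP) if ks is None else ks
    candidate = _combine(state, h, CASH_KARP.b, ks)
    err = np.abs(_combine(np.zeros_like(state), h, CASH_KARP.b_err, ks))
    _check_finite(candidate)
    return candidate, err


# ---------------------------------------------------------------------------
# Parallel scheduler contract
# ---------------------------------------------------------------------------

class _CascadeScheduler:
    """Dependency-gated list scheduler over (block, stage) tasks.

    Task (i, s) becomes ready once task (i, s-1) and every parent task
    (p, s-1) have completed — i.e. once the parents' stage-s values have
    been delivered.  ``workers`` bounds how many ready tasks are claimed
    per scheduling round.  Results are written into preallocated stage
    arrays slice by slice, with the same elementwise arithmetic as the
    serial sweep, so any schedule yields bitwise-identical slopes.
    """

    def __init__(self, system, workers: int):
        if workers < 1:
            raise ValueError("worker_count must be >= 1")
        self.system = system
        self.workers = workers
        self.parents = [system.block_parents(i) for i in range(system.n_blocks)]
        self.indices = [system.block_indices(i) for i in range(system.n_blocks)]

    def _ready(self, task, done) -> bool:
        """A (block, stage) task is ready once the block's and its parents'
        previous-stage values have been delivered."""
        i, s = task
        if s == 0:
            return True
        if not done[i, s - 1]:
            return False
        return all(done[p, s - 1] for p in self.parents[i])

    def stages(self, x, t, h, tab):
        nb = self.system.n_blocks
        S = tab.stages
        ks = [np.empty(self.system.dim) for _ in range(S)]
        ys = [x] + [np.empty(self.system.dim) for _ in range(S - 1)]
        done = np.zeros((nb, S), dtype=bool)
        pending = {(i, s) for i in range(nb) for s in range(S)}

        while pending:
            batch = sorted(t_ for t_ in pending if self._ready(t_, done))
            if not batch:
                blocked = sorted(pending)[0][0]
                raise RuntimeError(
                    f"scheduler deadlock: SCC block {blocked} waiting on parents"
                )
            for i, s in batch[: self.workers]:
                idx = self.indices[i]
                ks[s][idx] = self.system.block_rhs(i, ys[s])
                done[i, s] = True
                pending.discard((i, s))
                if s + 1 < S:
                    # deliver this block's stage-(s+1) value downstream
                    ys[s + 1][idx] = _combine(
                        x[idx], h, tab.a[s + 1], [k[idx] for k in ks[: s + 1]]
                    )
        return ks


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time grid, step sizes and states of one integration run."""

    times: np.ndarray
    states: np.ndarray  # (n_times, dim)
    steps: np.ndarray  # h_k, length n_times - 1
    system: object = None
    accepted: int = 0
    rejected: int = 0

    def final(self) -> np.ndarray:
        return self.states[-1]

    def sample(self, ts) -> np.ndarray:
        """States at arbitrary times by piecewise cubic Hermite
        interpolation (derivatives re-evaluated from the system), accurate
        to the same order as the stored grid."""
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        out = np.empty((ts.size, self.states.shape[1]))
        derivs = {}

        def d(k):
            if k not in derivs:
                derivs[k] = self.system.rhs(self.states[k], self.times[k])
            return derivs[k]

        for j, tq in enumerate(ts):
            k = int(np.searchsorted(self.times, tq, side="right") - 1)
            k = min(max(k, 0), len(self.times) - 2)
            t0, t1 = self.times[k], self.times[k + 1]
            hseg = t1 - t0
            u = (tq - t0) / hseg
            h00 = 2 * u**3 - 3 * u**2 + 1
            h10 = u**3 - 2 * u**2 + u
            h01 = -2 * u**3 + 3 * u**2
            h11 = u**3 - u**2
            out[j] = (
                h00 * self.states[k]
                + h10 * hseg * d(k)
                + h01 * self.states[k + 1]
                + h11 * hseg * d(k + 1)
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        labels = self.system.row_labels()
        frames = []
        for col, lab in enumerate(labels):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        **{k: v for k, v in lab.items()},
                        "value": self.states[:, col],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("states", data=self.states)
            fh.create_dataset("steps", data=self.steps)
            labels = self.system.row_labels()
            fh.create_dataset(
                "rows",
                data=np.array(
                    [";".join(f"{k}={v}" for k, v in lab.items()) for lab in labels],
                    dtype=h5py.string_dtype(),
                ),
            )


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _stage_fn(system, workers):
    if workers is None:
        return lambda x, t, h, tab: _stages_serial(system, x, t, h, tab)
    sched = _CascadeScheduler(system, workers)
    return sched.stages


def integrate_constant(system, step, t_end, x0=None, workers=None) -> Trajectory:
    """Constant-step RK4 over [0, t_end] on a uniform grid (final partial
    step if t_end is not a multiple of ``step``)."""
    if step <= 0 or step > t_end:
        raise ValueError("need 0 < step <= t_end")
    x = system.initial_state() if x0 is None else np.array(x0, dtype=float)
    stages = _stage_fn(system, workers)
    times = [0.0]
    states = [x]
    hs = []
    t = 0.0
    while t < t_end - 1e-12 * t_end:
        h = min(step, t_end - t)
        ks = stages(x, t, h, RK4)
        x = rk4_step(system, x, t, h, ks=ks)
        t += h
        times.append(t)
        states.append(x)
        hs.append(h)
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        steps=np.array(hs),
        system=system,
        accepted=len(hs),
    )


@dataclass
class StepController:
    """Pilot-based adaptive step control for the Cash–Karp pair.

    Per-component tolerance is ``tol_scaling * |y| + tol_addition``; the
    error ratio is maximized over the pilot node set only, and the accepted
    step is broadcast to every SCC.
    """

    tol_scaling: float = 1e-9
    tol_addition: float = 1e-7
    safety: float = 0.9
    min_factor: float = 0.2
    max_factor: float = 5.0
    h_min: float = 1e-12
    pilot: np.ndarray | None = None  # component indices; None = all

    def error_ratio(self, y, err) -> float:
        tol = self.tol_scaling * np.abs(y) + self.tol_addition
        r = err / tol
        if self.pilot is not None:
            r = r[self.pilot]
        return float(np.max(r)) if r.size else 0.0

    def next_h_accept(self, h, ratio) -> float:
        if ratio == 0.0:
            return h * self.max_factor
        return h * min(self.max_factor, self.safety * ratio ** (-0.2))

    def next_h_reject(self, h, ratio) -> float:
        return h * max(self.min_factor, self.safety * ratio ** (-0.25))


def pilot_controller(partition, system) -> np.ndarray:
    """Pilot node set: weight-0 mass isotopomers of the smallest
    topological prefix of SCCs covering >= 1 EMU of every metabolite in the
    pruned network (lightest-node fallback for metabolites with no
    weight-0 node)."""
    base = getattr(system, "base", system)  # accept augmented systems
    uncovered = set(base.met_rows)
    pilot: list[int] = []
    for scc in partition.sccs:
        if not uncovered:
            break
        for n in scc.members:
            if n.weight == 0:
                pilot.append(base.node_index[n])
                uncovered.discard(n.emu.metabolite)
    for met in sorted(uncovered):  # fallback: lightest retained node
        rows = base.met_rows[met]
        weights = [base.nodes[i].weight for i in rows]
        pilot.append(int(rows[int(np.argmin(weights))]))
    return np.array(sorted(set(pilot)), dtype=int)


def integrate_adaptive(
    system, controller: StepController, t_end, h0=0.005, x0=None, workers=None
) -> Trajectory:
    """Adaptive Cash–Karp integration over [0, t_end].

    The step size is decided on the pilot components of each trial step
    (acceptance is settled on the pilot before the step is broadcast; no
    downstream rollback is ever needed) and applied uniformly to all SCC
    blocks.
    """
    x = system.initial_state() if x0 is None else np.array(x0, dtype=float)
    stages = _stage_fn(system, workers)
    times = [0.0]
    states = [x]
    hs = []
    t = 0.0
    h = min(h0, t_end)
    accepted = rejected = 0
    while t < t_end - 1e-12 * t_end:
        h = min(h, t_end - t)
        ks = stages(x, t, h, CASH_KARP)
        candidate, err = cash_karp_step(system, x, t, h, ks=ks)
        ratio = controller.error_ratio(x, err)
        if ratio <= 1.0:
            t += h
            times.append(t)
            states.append(candidate)
            hs.append(h)
            x = candidate
            accepted += 1
            h = controller.next_h_accept(h, ratio)
        else:
            rejected += 1
            h = controller.next_h_reject(h, ratio)
            if h < controller.h_min:
                raise RuntimeError(f"adaptive step underflow at t={t}")
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        steps=np.array(hs),
        system=system,
        accepted=accepted,
        rejected=rejected,
    )


def run_parallel(
    system,
    worker_count: int,
    mode: str = "constant",
    step: float = 0.005,
    t_end: float = 10.0,
    controller: StepController | None = None,
    x0=None,
) -> Trajectory:
    """Integrate under the dependency-cascade scheduler contract.

    The numerical result is bit-for-bit identical to the serial integrator
    for any ``worker_count`` (fixed reduction order); in adaptive mode the
    pilot-chosen step sequence is likewise worker-count independent.
    """
    if mode == "constant":
        return integrate_constant(system, step, t_end, x0=x0, workers=worker_count)
    if mode == "adaptive":
        if controller is None:
            controller = StepController()
        return integrate_adaptive(
            system, controller, t_end, h0=step, x0=x0, workers=worker_count
        )
    raise ValueError(f"unknown mode {mode!r}")
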