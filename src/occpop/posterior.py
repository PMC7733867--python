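"""Posterior population size: K_t proportional to L_t * M_t, and conditioned trajectories.

Given the backward vectors L_t(i) (density of the data below t given
I_t = k_t + i) and the forward vectors M_t(i) (joint density of the data
above t and I_t), the posterior of the population size at any time is

    K_t(i) = P(I_t = k_t + i | tree, occurrences) = L_t(i) M_t(i) / P(T, O),

because conditionally on I_t the future of the Markov process is
independent of its past.  The pre-normalisation row sum recovers
P(T, O) at every grid time -- a sharp full-pipeline diagnostic.

Conditioned *trajectories* of I_t are drawn calendar-forward (origin to
present) as an inhomogeneous birth-death jump process whose rates are the
Doob h-transform of the unconditioned hidden dynamics by L:

    up:   lam (2k + j) L_t(j+1) / L_t(j)
    down: mu j        L_t(j-1) / L_t(j)

started from the deterministic state I = 1 at the origin, with the
deterministic hidden-count shifts applied at data events.  Inhomogeneity
is handled by thinning against per-step rate envelopes on a fine grid of
stored L vectors (log-linear interpolation in time).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core import ModelParams, ProbVector
from .schedule import DATA_KINDS, EventKind, EventSchedule

__all__ = [
    "PosteriorGrid",
    "Trajectory",
    "compute_K",
    "posterior_quantiles",
    "doob_rates",
    "sample_trajectory",
    "fine_grid",
]


@dataclasses.dataclass
class PosteriorGrid:
    """Posterior of the population size over a time grid.

    ``probs[s, i]`` is P(I = k[s] + i | data) at time ``times[s]``; the
    support of the total count starts at the lineage count k[s], an obvious
    lower bound.  ``log_evidence[s]`` is the log of the pre-normalisation
    row sum, which must be flat and equal to log P(T, O).
    """

    times: np.ndarray
    k: np.ndarray
    probs: np.ndarray
    log_evidence: np.ndarray

    @property
    def N(self) -> int:
        return self.probs.shape[1] - 1

    def support(self, s: int) -> np.ndarray:
        """Total-count support k[s] + {0..N} at grid index s."""
        return self.k[s] + np.arange(self.probs.shape[1])

    def mean(self) -> np.ndarray:
        return self.k + self.probs @ np.arange(self.probs.shape[1])

    def cdf_at(self, s: int) -> np.ndarray:
        return np.cumsum(self.probs[s])

    def to_frame(self):
        import pandas as pd

        rows = []
        for s, t in enumerate(self.times):
            for i, p in enumerate(self.probs[s]):
                rows.append((t, int(self.k[s]), int(self.k[s] + i), p))
        return pd.DataFrame(rows, columns=["time", "k", "n", "probability"])


@dataclasses.dataclass
class Trajectory:
    """A piecewise-constant conditioned population-size path over [0, t_or].

    ``times`` are jump instants in decreasing age order starting at t_or;
    ``states`` the total count I on [times[j+1], times[j])."""

    times: np.ndarray
    states: np.ndarray
    seed: int

    def at(self, query: np.ndarray) -> np.ndarray:
        """I at the queried ages (t-minus side at jump instants)."""
        q = np.asarray(query, dtype=float)
        idx = np.searchsorted(-self.times, -q, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]


def compute_K(
    Ls: dict[float, ProbVector], Ms: dict[float, ProbVector]
) -> PosteriorGrid:
    """Combine stored L and M vectors into the normalised posterior grid.

    L and M must be recorded at identical times, identical truncation and
    the same instant-side convention (both t-minus).
    """
    times = sorted(Ls)
    if sorted(Ms) != times:
        raise ValueError("L and M recorded at different grid times")
    S = len(times)
    N = Ls[times[0]].N
    probs = np.zeros((S, N + 1))
    ks = np.zeros(S, dtype=int)
    log_ev = np.full(S, -math.inf)
    for s, t in enumerate(times):
        L, M = Ls[t], Ms[t]
        if L.N != N or M.N != N:
            raise ValueError("inconsistent truncation between grid times")
        if L.k != M.k:
            raise ValueError(f"lineage count mismatch at t={t}: L.k={L.k}, M.k={M.k}")
        row = L.values * M.values
        tot = float(row.sum())
        if tot <= 0.0:
            raise ValueError(f"zero posterior row at t={t}: impossible data or truncation failure")
        probs[s] = row / tot
        ks[s] = L.k
        log_ev[s] = math.log(tot) + L.log_scale + M.log_scale
    return PosteriorGrid(np.array(times), ks, probs, log_ev)


def posterior_quantiles(K: PosteriorGrid, probs) -> np.ndarray:
    """Lower quantiles of the total count: smallest n with CDF >= prob.

    Returns an array of shape (len(times), len(probs)) of integer counts.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    out = np.zeros((len(K.times), len(probs)))
    for s in range(len(K.times)):
        cdf = K.cdf_at(s)
        for q, p in enumerate(probs):
            i = int(np.searchsorted(cdf, p - 1e-12, side="left"))
            out[s, q] = K.k[s] + min(i, K.N)
    return out


def doob_rates(
    vec: ProbVector, params: ModelParams, based_on: str = "L"
) -> tuple[np.ndarray, np.ndarray]:
    """Conditioned jump rates (up, down) per hidden state j for a frozen L or M vector.

    L-based rates drive the process calendar-forward (decreasing age);
    M-based rates drive it in reverse (increasing age).  With a flat
    vector both reduce to the unconditioned hidden birth/death rates.
    Zero entries inside the reachable support signal truncation or
    underflow failure and yield zero rates (the sampler resamples).
    """
    j = np.arange(vec.N + 1, dtype=float)
    v = vec.values
    k = vec.k
    up = np.zeros(vec.N + 1)
    down = np.zeros(vec.N + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if based_on == "L":
            ratio_up = np.where(v[:-1] > 0, v[1:] / v[:-1], 0.0)
            up[:-1] = params.lam * (2 * k + j[:-1]) * ratio_up
            ratio_dn = np.where(v[1:] > 0, v[:-1] / v[1:], 0.0)
            down[1:] = params.mu * j[1:] * ratio_dn
        elif based_on == "M":
            ratio_dn = np.where(v[1:] > 0, v[:-1] / v[1:], 0.0)
            down[1:] = params.lam * (2 * k + j[1:] - 1) * ratio_dn
            ratio_up = np.where(v[:-1] > 0, v[1:] / v[:-1], 0.0)
            up[:-1] = params.mu * (j[:-1] + 1) * ratio_up
        else:
            raise ValueError("based_on must be 'L' or 'M'")
    return up, down


def fine_grid(schedule: EventSchedule, max_step: float | None = None) -> np.ndarray:
    """Epoch boundaries plus intermediate points at most ``max_step`` apart (default t_or/100)."""
    if max_step is None:
        max_step = 0.01 * schedule.t_or
    times = schedule.times
    out = [0.0]
    for a, b in zip(times[:-1], times[1:]):
        n = max(1, int(math.ceil((b - a) / max_step)))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.unique(np.asarray(out))


# calendar-forward deterministic hidden-count shifts at data events
_EVENT_SHIFT = {
    EventKind.REMOVED_LEAF: 0,
    EventKind.NONREMOVED_LEAF: +1,  # the leaf individual joins the hidden pool
    EventKind.SAMPLED_ANCESTOR: 0,
    EventKind.REMOVED_OCCURRENCE: -1,  # a hidden individual is removed
    EventKind.NONREMOVED_OCCURRENCE: 0,
    EventKind.BRANCHING: 0,
}


def sample_trajectory(
    schedule: EventSchedule,
    Ls: dict[float, ProbVector],
    params: ModelParams,
    seed: int,
    n_traj: int,
    envelope_margin: float = 1.3,
) -> list[Trajectory]:
    """Draw conditioned population-size trajectories calendar-forward from the origin.

    ``Ls`` must hold L vectors on a fine grid (see :func:`fine_grid`)
    covering [0, t_or].  Within each fine step rates are obtained by
    log-linear interpolation of L and thinned against an envelope
    ``envelope_margin * max(endpoint total rates)``; trajectories hitting a
    zero-probability state (or an envelope violation beyond repair) are
    redrawn and counted -- more than ~1% of redraws indicates the L grid is
    too coarse.  Events with an unknown removal label are resolved by a
    Bernoulli(r) draw of the removal status (the posterior mixture weights
    are already encoded in L).
    """
    from .backward import update_L_event

    rng = np.random.default_rng(seed)
    grid = np.array(sorted(Ls), dtype=float)
    if grid[0] != 0.0 or grid[-1] != schedule.t_or:
        raise ValueError("L grid must span [0, t_or]")
    N = Ls[grid[0]].N

    event_at = {
        e.time: e.kind for e in schedule.entries if e.kind in DATA_KINDS
    }
    missing = [t for t in event_at if t not in Ls]
    if missing:
        raise ValueError(f"L grid must include every event time; missing {missing}")

    def logs(vec: ProbVector) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(vec.values > 0, np.log(np.maximum(vec.values, 1e-300)), -np.inf)

    # Per fine segment (grid[g], grid[g+1]): endpoint log-L vectors on the
    # *inside* of the segment (the stored vector at an event time is the
    # below-event side; the side above the event is obtained by applying the
    # backward event update), plus the segment's lineage count.
    S = len(grid) - 1
    seg_lo_log = np.empty((S, N + 1))
    seg_hi_log = np.empty((S, N + 1))
    seg_k = np.empty(S, dtype=int)
    below_log = {}  # below-event log L at event times, for unknown-label resolution
    for g in range(S):
        lo_t, hi_t = grid[g], grid[g + 1]
        lo_vec = Ls[lo_t]
        if lo_t in event_at:
            below_log[lo_t] = logs(lo_vec)
            lo_vec = update_L_event(lo_vec, event_at[lo_t], params)
        seg_lo_log[g] = logs(lo_vec)
        seg_k[g] = lo_vec.k
        seg_hi_log[g] = logs(Ls[hi_t])  # below-side of the upper endpoint
        if Ls[hi_t].k != lo_vec.k:
            raise ValueError(f"lineage count changes inside segment ({lo_t}, {hi_t})")

    trajectories: list[Trajectory] = []
    n_resampled = 0
    for _m in range(n_traj):
        for _attempt in range(1000):
            ok, times, states = _draw_one(
                rng, grid, seg_lo_log, seg_hi_log, seg_k, event_at, below_log,
                params, N, envelope_margin,
            )
            if ok:
                trajectories.append(Trajectory(np.array(times), np.array(states), seed))
                break
            n_resampled += 1
        else:
            raise RuntimeError("trajectory sampling failed 1000 times; L grid inadequate")
    if n_resampled > 0.01 * max(1, len(trajectories)):
        import warnings

        warnings.warn(
            f"{n_resampled} trajectory redraws for {n_traj} draws: "
            "consider a finer L grid or larger N",
            stacklevel=2,
        )
    return trajectories


def _interp_log(lo: np.ndarray, hi: np.ndarray, w: float) -> np.ndarray:
    """Log-linear interpolation that keeps -inf entries at -inf (no 0*inf NaNs)."""
    with np.errstate(invalid="ignore"):
        out = (1.0 - w) * lo + w * hi
    return np.where(np.isnan(out), -np.inf, out)


def _doob_updown(lv: np.ndarray, params: ModelParams, k: int, j: int, N: int):
    up = dn = 0.0
    if np.isfinite(lv[j]):
        if j < N and np.isfinite(lv[j + 1]):
            up = params.lam * (2 * k + j) * math.exp(lv[j + 1] - lv[j])
        if j > 0 and np.isfinite(lv[j - 1]):
            dn = params.mu * j * math.exp(lv[j - 1] - lv[j])
    return up, dn


def _draw_one(rng, grid, seg_lo_log, seg_hi_log, seg_k, event_at, below_log, params, N, margin):
    t = grid[-1]
    g = len(grid) - 2  # current segment (grid[g], grid[g+1])
    j = 0  # hidden count; I = k + j
    times = [t]
    states = [seg_k[g] + j]
    while True:
        k = seg_k[g]
        lo_t, hi_t = grid[g], grid[g + 1]
        span = hi_t - lo_t
        while t > lo_t:
            w = (t - lo_t) / span
            lv_t = _interp_log(seg_lo_log[g], seg_hi_log[g], w)
            up_a, dn_a = _doob_updown(lv_t, params, k, j, N)
            up_b, dn_b = _doob_updown(seg_lo_log[g], params, k, j, N)
            bound = margin * max(up_a + dn_a, up_b + dn_b)
            if bound <= 0.0:
                t = lo_t
                break
            tau = rng.exponential(1.0 / bound)
            if t - tau <= lo_t:
                t = lo_t
                break
            t -= tau
            w = (t - lo_t) / span
            lv = _interp_log(seg_lo_log[g], seg_hi_log[g], w)
            up, dn = _doob_updown(lv, params, k, j, N)
            u01 = rng.random() * bound
            if u01 < up:
                j += 1
            elif u01 < up + dn:
                j -= 1
            else:
                continue
            times.append(t)
            states.append(k + j)
        # arrived at the segment's lower end
        if lo_t in event_at:
            kind = event_at[lo_t]
            lv_b = below_log[lo_t]
            if kind is EventKind.UNKNOWN_LEAF:
                kind = (
                    EventKind.REMOVED_LEAF
                    if rng.random() < _posterior_removed_prob(lv_b, params, k, j, leaf=True)
                    else EventKind.NONREMOVED_LEAF
                )
            elif kind is EventKind.UNKNOWN_OCCURRENCE:
                kind = (
                    EventKind.REMOVED_OCCURRENCE
                    if rng.random() < _posterior_removed_prob(lv_b, params, k, j, leaf=False)
                    else EventKind.NONREMOVED_OCCURRENCE
                )
            if kind is EventKind.BRANCHING:
                k += 1
            elif kind in (EventKind.REMOVED_LEAF, EventKind.NONREMOVED_LEAF):
                k -= 1
            j_new = j + _EVENT_SHIFT[kind]
            if j_new < 0 or j_new > N:
                return False, None, None  # zero-probability state: redraw
            if kind is EventKind.NONREMOVED_OCCURRENCE and k + j == 0:
                return False, None, None
            j = j_new
            times.append(lo_t)
            states.append(k + j)
        if g == 0:
            break
        g -= 1
    return True, times, states


def _posterior_removed_prob(lv_below, params, k, j, leaf: bool) -> float:
    """P(removed | state, future data) for an unknown-label event, from L just below it.

    For a leaf at state j above the event: removed keeps i=j (weight psi*r*L(j)),
    non-removed shifts to j+1 below... going calendar-forward the branch taken
    changes the state below, so the weights are the backward update summands
    evaluated at the current state.
    """
    r = params.r
    if leaf:
        w_rem = r * math.exp(lv_below[j]) if np.isfinite(lv_below[j]) else 0.0
        w_non = (
            (1.0 - r) * math.exp(lv_below[j + 1])
            if j + 1 < len(lv_below) and np.isfinite(lv_below[j + 1])
            else 0.0
        )
    else:
        w_rem = (
            r * j * math.exp(lv_below[j - 1])
            if j >= 1 and np.isfinite(lv_below[j - 1])
            else 0.0
        )
        w_non = (1.0 - r) * (k + j) * math.exp(lv_below[j]) if np.isfinite(lv_below[j]) else 0.0
    tot = w_rem + w_non
    return w_rem / tot if tot > 0 else 0.0
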