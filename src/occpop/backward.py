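"""Backward propagation of L_t(i) = P(data below t | I_t = k_t + i).

L is initialised at present by the rho-sampling, evolved across each epoch
by the truncated tridiagonal master equation

    dL/dt (i) = -gamma (k+i) L(i) + lam (2k+i) L(i+1) + mu i L(i-1),

solved as the action of a matrix exponential, and multiplied by an event
factor at each punctual event.  Reaching the origin, L_{t_or}(0) is the
probability density of the observed (tree, occurrences) pair.

Underflow control: every vector carries an explicit ``log_scale`` which is
refreshed after each epoch and each event, so the final log density is
exact at any data size.  Truncation at ``N`` hidden individuals leaks mass
one-sidedly (the top birth flux is dropped), so increasing N monotonically
refines the density; :func:`recommend_truncation` doubles N until the
relative change of the log density is below a tolerance.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .core import ImpossibleDataError, ModelParams, ProbVector, p_of, u_of
from .schedule import LEAF_KINDS, OCCURRENCE_KINDS, DATA_KINDS, EventKind, EventSchedule

__all__ = [
    "init_L",
    "evolve_L_epoch",
    "update_L_event",
    "compute_L",
    "density_backward",
    "L_closed_form_no_omega",
    "fbd_tree_density",
    "recommend_truncation",
]


def init_L(k0: int, rho: float, N: int) -> ProbVector:
    """L at present: values[i] = rho^k0 (1-rho)^i, with rho^k0 held in the log scale."""
    if rho == 0.0 and k0 > 0:
        raise ImpossibleDataError("rho=0 but the tree has tips at present: density is zero")
    i = np.arange(N + 1)
    values = (1.0 - rho) ** i
    log_scale = k0 * math.log(rho) if k0 > 0 else 0.0
    return ProbVector(values=values, log_scale=log_scale, k=k0, t=0.0)


def _tridiag(k: int, N: int, params: ModelParams) -> sp.csr_matrix:
    i = np.arange(N + 1)
    diag = -params.gamma * (k + i)
    upper = params.lam * (2 * k + i[:-1])  # multiplies L(i+1)
    lower = params.mu * i[1:]  # multiplies L(i-1)
    return sp.diags([lower, diag, upper], offsets=[-1, 0, 1], format="csr")


def evolve_L_epoch(L: ProbVector, dt: float, params: ModelParams) -> ProbVector:
    """Propagate L backward over an event-free epoch of duration ``dt``."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0.0 or L.is_zero:
        out = L.copy()
        out.t = L.t + dt
        return out
    A = _tridiag(L.k, L.N, params)
    values = expm_multiply(A.multiply(dt), L.values)
    np.maximum(values, 0.0, out=values)  # clip roundoff negatives
    out = ProbVector(values=values, log_scale=L.log_scale, k=L.k, t=L.t + dt)
    return out.rescale()


def update_L_event(L: ProbVector, kind: EventKind, params: ModelParams) -> ProbVector:
    """Apply the backward event factor at a punctual event; updates k.

    Going backward in time, leaves increment k (the sampled lineage exists
    above the sampling time) and branchings decrement it (two lineages
    merge); sampled ancestors and occurrences leave k unchanged.  A zero
    multiplier (psi=0 at a tree event, omega=0 at an occurrence) yields a
    zero vector, i.e. a zero-density signal rather than an exception.
    """
    if kind not in DATA_KINDS:
        raise ValueError(f"{kind} is not a data event")
    psi, omega, r, lam = params.psi, params.omega, params.r, params.lam
    v = L.values
    k_new = L.k
    if kind is EventKind.REMOVED_LEAF:
        new = psi * r * v
        k_new += 1
    elif kind is EventKind.NONREMOVED_LEAF:
        new = np.empty_like(v)
        new[:-1] = psi * (1.0 - r) * v[1:]
        new[-1] = 0.0
        k_new += 1
    elif kind is EventKind.UNKNOWN_LEAF:
        new = psi * r * v
        new[:-1] += psi * (1.0 - r) * v[1:]
        k_new += 1
    elif kind is EventKind.SAMPLED_ANCESTOR:
        new = psi * (1.0 - r) * v
    elif kind is EventKind.REMOVED_OCCURRENCE:
        i = np.arange(len(v), dtype=float)
        new = np.empty_like(v)
        new[0] = 0.0
        new[1:] = omega * r * i[1:] * v[:-1]
    elif kind is EventKind.NONREMOVED_OCCURRENCE:
        i = np.arange(len(v), dtype=float)
        new = omega * (1.0 - r) * (L.k + i) * v
    elif kind is EventKind.UNKNOWN_OCCURRENCE:
        i = np.arange(len(v), dtype=float)
        new = omega * (1.0 - r) * (L.k + i) * v
        new[1:] += omega * r * i[1:] * v[:-1]
    else:  # branching
        new = lam * v
        k_new -= 1
    out = ProbVector(values=new, log_scale=L.log_scale, k=k_new, t=L.t)
    return out.rescale()


def compute_L(
    schedule: EventSchedule, params: ModelParams, N: int
) -> tuple[dict[float, ProbVector], ProbVector]:
    """Full backward sweep from present to the origin.

    Returns ``(recorded, final)`` where ``recorded`` maps each grid time to
    the L vector on its t-minus side (before the event update if the grid
    time coincides with a data event) and ``final`` is L at the origin.
    """
    if N < 1:
        raise ValueError("truncation N must be >= 1")
    recorded: dict[float, ProbVector] = {}
    L = init_L(schedule.k0, params.rho, N)
    if schedule.entries[0].is_grid:
        recorded[0.0] = L.copy()
    for h in range(1, len(schedule.entries)):
        entry = schedule.entries[h]
        L = evolve_L_epoch(L, entry.time - schedule.entries[h - 1].time, params)
        if entry.is_grid:
            recorded[entry.time] = L.copy()
        if entry.kind in DATA_KINDS:
            L = update_L_event(L, entry.kind, params)
            if L.k != (schedule.k[h] if h < len(schedule.k) else 1):
                raise AssertionError("lineage count mismatch between sweep and schedule")
    return recorded, L


def density_backward(
    schedule: EventSchedule,
    params: ModelParams,
    N: int,
    condition_on_sampling: bool = False,
) -> float:
    """log P(tree, occurrences) via the backward sweep (Algorithm 1').

    With ``condition_on_sampling``, subtracts log(1 - u(t_or, 1-rho)), the
    log probability of observing at least one sample.
    """
    _, L = compute_L(schedule, params, N)
    logp = L.log_entry(0)
    if condition_on_sampling:
        logp -= math.log1p(-u_of(params.t_or, 1.0 - params.rho, params))
    return logp


# ---------------------------------------------------------------------------
# omega = 0 closed forms
# ---------------------------------------------------------------------------


def _events_below(schedule: EventSchedule, t: float):
    """Tree events at ages <= t (occurrences are forbidden by the callers)."""
    v = 0
    W: list[float] = []
    X: list[float] = []
    Y: list[float] = []
    for e in schedule.entries:
        if e.time > t or e.kind not in DATA_KINDS:
            continue
        if e.kind in OCCURRENCE_KINDS:
            raise ValueError("closed forms require an empty occurrence record (omega=0 data)")
        if e.kind is EventKind.SAMPLED_ANCESTOR:
            v += 1
        elif e.kind is EventKind.REMOVED_LEAF:
            W.append(e.time)
        elif e.kind is EventKind.NONREMOVED_LEAF:
            Y.append(e.time)
        elif e.kind is EventKind.UNKNOWN_LEAF:
            raise ValueError("closed forms require fully labeled leaves")
        else:
            X.append(e.time)
    return v, W, X, Y


def _log_W_factor(params: ModelParams, v: int, W, X, Y, kt: int, t: float) -> float:
    """log of W_t = lam^x psi^{v+w+y} (1-r)^{v+y} r^w p_t^{kt} prod_X p prod_Y u/p prod_W 1/p."""

    def safe_log(x: float) -> float:
        return math.log(x) if x > 0 else -math.inf

    z = 1.0 - params.rho
    logw = (
        len(X) * safe_log(params.lam)
        + (v + len(W) + len(Y)) * safe_log(params.psi)
        + (v + len(Y)) * safe_log(1.0 - params.r)
        + len(W) * safe_log(params.r)
        + kt * safe_log(p_of(t, z, params))
    )
    for tj in X:
        logw += safe_log(p_of(tj, z, params))
    for tj in Y:
        logw += safe_log(u_of(tj, z, params)) - safe_log(p_of(tj, z, params))
    for tj in W:
        logw -= safe_log(p_of(tj, z, params))
    return logw


def L_closed_form_no_omega(
    schedule: EventSchedule, params: ModelParams, t: float, i_max: int
) -> ProbVector:
    """L_t(i) = u_t^i W_t for omega = 0 data (no occurrences), i <= i_max."""
    if params.omega != 0:
        raise ValueError("closed form requires omega = 0")
    v, W, X, Y = _events_below(schedule, t)
    kt = schedule.k_at(t)
    logw = _log_W_factor(params, v, W, X, Y, kt, t)
    ut = u_of(t, 1.0 - params.rho, params)
    values = ut ** np.arange(i_max + 1, dtype=float)
    if logw == -math.inf:
        return ProbVector(np.zeros(i_max + 1), 0.0, kt, t)
    return ProbVector(values=values, log_scale=logw, k=kt, t=t)


def fbd_tree_density(schedule: EventSchedule, params: ModelParams) -> float:
    """log density of a reconstructed tree without occurrences (omega = 0).

    The closed form is ``lam^{w+y+k0-1} psi^{v+w+y} (1-r)^{v+y} r^w
    prod_{X+{t_or}} p_{tj} prod_Y u_{tj}/p_{tj} prod_W 1/p_{tj}``, the
    fossilised-birth-death tree density generalised to partial removal.
    """
    if params.omega != 0:
        raise ValueError("closed form requires omega = 0")
    v, W, X, Y = _events_below(schedule, schedule.t_or)
    # the p_{t_or} factor of the X-product over X + {t_or} enters as p_t^{k_t}
    # with k = 1 on the epoch adjoining the origin
    return _log_W_factor(params, v, W, X, Y, 1, params.t_or)


def recommend_truncation(
    schedule: EventSchedule,
    params: ModelParams,
    N_start: int = 16,
    rtol: float = 1e-6,
    N_max: int = 4096,
) -> int:
    """Smallest N (doubling from ``N_start``) whose log density changes by < rtol when doubled."""
    N = N_start
    prev = density_backward(schedule, params, N)
    while N <= N_max:
        cur = density_backward(schedule, params, 2 * N)
        if prev == cur or abs(cur - prev) <= rtol * abs(cur):
            return N
        prev, N = cur, 2 * N
    raise RuntimeError(f"no adequate truncation found below N={N_max}")
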