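"""Forward propagation of M_t(i) = P(data above t, I_t = k_t + i).

M starts at the origin as a point mass on a single individual and is
propagated towards the present.  Across an event-free epoch the generating
function Mhat(t, z) = sum_i z^i M_t(i) solves a first-order PDE whose
characteristic solution is

    Mhat(t, z) = F(u(s, z)) * R(s, z)**k,      s = elapsed time in epoch,

with F the generating function at the top of the epoch, u the
no-sample probability and R(s, z) = p(s, z) / (1 - z).  The epoch step
therefore amounts to extracting Taylor coefficients at z = 0 of
R(s,z)**k * sum_l M(l) u(s,z)**l.  Both u and R have *non-negative*
Taylor coefficients,

    u_j = e (Delta/lam)**2 G**(j-1) / c**(j+1)   (j >= 1),
    u_0 = x1 x2 G / c,
    [z^j] R**k = ((Delta/lam)**2 e)**k  C(2k+j-1, j) G**j / c**(2k+j),

with e = exp(-Delta s), G = 1 - e, c = x2 - x1 e, so the truncated
power-series composition (Horner in u, then one multiplication by the R**k
series) is cancellation-free for every step size -- unlike the equivalent
explicit double-sum expansion, which degenerates as s -> 0.  Coefficients
of the R**k series are assembled in log space to tame the binomials.

A truncated-ODE path (matrix exponential action on the forward master
equation) is retained behind ``method="ode"`` as a verification route.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply
from scipy.special import gammaln

from .core import ModelParams, ProbVector, R_of, a_b_coeffs, u_of
from .schedule import DATA_KINDS, EventKind, EventSchedule, OCCURRENCE_KINDS

__all__ = [
    "init_M",
    "evolve_M_epoch",
    "update_M_event",
    "compute_M",
    "density_forward",
    "M_closed_form_no_omega",
]


def init_M(N: int, t_or: float | None = None) -> ProbVector:
    """M at the origin: a single individual with certainty (point mass at i=0, k=1)."""
    values = np.zeros(N + 1)
    values[0] = 1.0
    return ProbVector(values=values, log_scale=0.0, k=1, t=t_or if t_or is not None else 0.0)


def _u_series(params: ModelParams, e: float, G: float, c: float, N: int) -> np.ndarray:
    """Taylor coefficients of u(s, z) in z, orders 0..N (all non-negative)."""
    x1, x2 = params.x1, params.x2
    dl2 = (params.Delta / params.lam) ** 2
    j = np.arange(N + 1)
    with np.errstate(divide="ignore"):
        logs = np.log(e * dl2) + (j - 1) * np.log(G) - (j + 1) * np.log(c)
    u = np.exp(logs)
    u[0] = x1 * x2 * G / c
    return u


def _log_Rk_series(params: ModelParams, k: int, e: float, G: float, c: float, N: int) -> np.ndarray:
    """log Taylor coefficients of R(s, z)**k, orders 0..N."""
    dl2 = (params.Delta / params.lam) ** 2
    j = np.arange(N + 1)
    if k == 0:
        out = np.full(N + 1, -np.inf)
        out[0] = 0.0
        return out
    with np.errstate(divide="ignore"):
        return (
            k * math.log(dl2 * e)
            + gammaln(2 * k + j)
            - gammaln(j + 1.0)
            - gammaln(2.0 * k)
            + j * np.log(G)
            - (2 * k + j) * np.log(c)
        )


def evolve_M_epoch(
    M: ProbVector, dt: float, params: ModelParams, method: str = "gf"
) -> ProbVector:
    """Propagate M towards the present over an event-free epoch of duration ``dt``.

    ``method="gf"`` (default) uses the characteristic solution of the
    generating-function PDE; ``method="ode"`` integrates the truncated
    forward master equation as the action of a matrix exponential.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0.0 or M.is_zero:
        out = M.copy()
        out.t = M.t - dt
        return out
    if method == "ode":
        return _evolve_M_ode(M, dt, params)
    if method != "gf":
        raise ValueError(f"unknown method {method!r}")
    N = M.N
    e = math.exp(-params.Delta * dt)
    G = -math.expm1(-params.Delta * dt)
    c = params.x2 - params.x1 * e
    useries = _u_series(params, e, G, c, N)

    # Horner composition of F(x) = sum_l M(l) x^l at x = u(s, z), truncated at order N
    B = np.zeros(N + 1)
    B[0] = M.values[N]
    for l in range(N - 1, -1, -1):
        B = np.convolve(useries, B)[: N + 1]
        B[0] += M.values[l]

    logRk = _log_Rk_series(params, M.k, e, G, c, N)
    shift = float(np.max(logRk))
    Rk = np.exp(logRk - shift)
    values = np.convolve(Rk, B)[: N + 1]
    out = ProbVector(values=values, log_scale=M.log_scale + shift, k=M.k, t=M.t - dt)
    return out.rescale()


def _evolve_M_ode(M: ProbVector, dt: float, params: ModelParams) -> ProbVector:
    """Verification path: exp(dt * A_fwd) acting on M for the truncated forward system."""
    N, k = M.N, M.k
    i = np.arange(N + 1)
    # d M / d s (calendar time s = -t): inflow lam(2k+i-1) from below, mu(i+1) from above
    diag = -params.gamma * (k + i)
    lower = params.lam * (2 * k + i[1:] - 1)  # into i from i-1
    upper = params.mu * (i[:-1] + 1)  # into i from i+1
    A = sp.diags([lower, diag, upper], offsets=[-1, 0, 1], format="csr")
    values = expm_multiply(A.multiply(dt), M.values)
    np.maximum(values, 0.0, out=values)
    out = ProbVector(values=values, log_scale=M.log_scale, k=k, t=M.t - dt)
    return out.rescale()


def update_M_event(M: ProbVector, kind: EventKind, params: ModelParams) -> ProbVector:
    """Apply the forward (calendar-time) event factor; updates k for the epoch below.

    Going towards the present, leaves decrement k (the sampled lineage ends),
    branchings increment it; at a non-removed leaf the sampled individual
    joins the hidden pool (index shift up), at a removed occurrence a hidden
    individual is removed (index shift down).
    """
    if kind not in DATA_KINDS:
        raise ValueError(f"{kind} is not a data event")
    psi, omega, r, lam = params.psi, params.omega, params.r, params.lam
    v = M.values
    k_new = M.k
    if kind is EventKind.REMOVED_LEAF:
        new = psi * r * v
        k_new -= 1
    elif kind is EventKind.NONREMOVED_LEAF:
        new = np.empty_like(v)
        new[0] = 0.0
        new[1:] = psi * (1.0 - r) * v[:-1]
        k_new -= 1
    elif kind is EventKind.UNKNOWN_LEAF:
        new = psi * r * v
        new[1:] += psi * (1.0 - r) * v[:-1]
        k_new -= 1
    elif kind is EventKind.SAMPLED_ANCESTOR:
        new = psi * (1.0 - r) * v
    elif kind is EventKind.REMOVED_OCCURRENCE:
        i = np.arange(len(v), dtype=float)
        new = np.empty_like(v)
        new[:-1] = omega * r * (i[:-1] + 1) * v[1:]
        new[-1] = 0.0
    elif kind is EventKind.NONREMOVED_OCCURRENCE:
        i = np.arange(len(v), dtype=float)
        new = omega * (1.0 - r) * (M.k + i) * v
    elif kind is EventKind.UNKNOWN_OCCURRENCE:
        i = np.arange(len(v), dtype=float)
        new = omega * (1.0 - r) * (M.k + i) * v
        new[:-1] += omega * r * (i[:-1] + 1) * v[1:]
    else:  # branching
        new = lam * v
        k_new += 1
    out = ProbVector(values=new, log_scale=M.log_scale, k=k_new, t=M.t)
    return out.rescale()


def compute_M(
    schedule: EventSchedule, params: ModelParams, N: int, method: str = "gf"
) -> tuple[dict[float, ProbVector], ProbVector]:
    """Full forward sweep from the origin to the present.

    Returns ``(recorded, final)``: ``recorded`` maps grid times to M on the
    t-minus side (after the event update when the grid time coincides with
    a data event; at t=0 before the rho-update, whose factor belongs to L),
    and ``final`` is M at present *before* the rho-update.
    """
    if N < 1:
        raise ValueError("truncation N must be >= 1")
    entries = schedule.entries
    recorded: dict[float, ProbVector] = {}
    M = init_M(N, t_or=schedule.t_or)
    if entries[-1].is_grid:
        recorded[schedule.t_or] = M.copy()
    for h in range(len(entries) - 2, -1, -1):
        entry = entries[h]
        M = evolve_M_epoch(M, entries[h + 1].time - entry.time, params, method=method)
        if entry.kind in DATA_KINDS:
            M = update_M_event(M, entry.kind, params)
            if M.k != (schedule.k[h - 1] if h >= 1 else schedule.k0):
                raise AssertionError("lineage count mismatch between sweep and schedule")
        if entry.is_grid:
            recorded[entry.time] = M.copy()
    return recorded, M


def density_forward(
    schedule: EventSchedule,
    params: ModelParams,
    N: int,
    condition_on_sampling: bool = False,
    method: str = "gf",
) -> float:
    """log P(tree, occurrences) via the forward sweep (Algorithm 2')."""
    _, M = compute_M(schedule, params, N, method=method)
    i = np.arange(N + 1)
    rho = params.rho
    s = float(np.sum((1.0 - rho) ** i * M.values))
    if s <= 0.0 or (schedule.k0 > 0 and rho == 0.0):
        return -math.inf
    logp = math.log(s) + M.log_scale + schedule.k0 * (math.log(rho) if schedule.k0 else 0.0)
    if condition_on_sampling:
        logp -= math.log1p(-u_of(params.t_or, 1.0 - rho, params))
    return logp


# ---------------------------------------------------------------------------
# omega = 0 closed form (log-derivative recursion on the generating function)
# ---------------------------------------------------------------------------


def M_closed_form_no_omega(
    schedule: EventSchedule, params: ModelParams, t: float, i_max: int
) -> ProbVector:
    """M_t(i) for omega = 0 data via the closed-form recursion, i <= i_max.

    With v sampled ancestors, removed leaves at W, branchings at X and
    non-removed leaves at Y observed above t (elapsed times s_j = t_j - t),

        M_t(0) = lam^x psi^{v+w+y} r^w (1-r)^{v+y}
                 prod_{X+{t_or}} R(s_j, 0) prod_W R^{-1} prod_Y u R^{-1},
        M_t(i) = (1/i) sum_{a=1..i} M_t(i-a) C(a),
        C(a)   = 2 sum_{X+{t_or}} a_s^a - 2 sum_W a_s^a - sum_Y (a_s^a + b_s^a),

    the coefficients a_s, b_s being the z-expansions of d/dz log R and
    d/dz log u (see :func:`occpop.core.a_b_coeffs`).  Requires t strictly
    below every non-removed leaf (b_s diverges at elapsed time 0).

    The recursion is exact in exact arithmetic but numerically divergent in
    its tail whenever max_j(|a_j|, |b_j|) >= 1 (log Mhat then has a
    singularity inside the unit disc; roundoff is amplified by roughly
    |b|^i).  This happens when t lies shortly below a non-removed leaf.
    The head of the vector is always accurate; use the epoch/update sweep
    (:func:`compute_M`) wherever the two disagree.
    """
    if params.omega != 0:
        raise ValueError("closed form requires omega = 0")
    v = 0
    W: list[float] = []
    X: list[float] = []
    Y: list[float] = []
    for entry in schedule.entries:
        if entry.time <= t or entry.kind not in DATA_KINDS:
            continue
        if entry.kind in OCCURRENCE_KINDS:
            raise ValueError("closed form requires an empty occurrence record (omega=0 data)")
        if entry.kind is EventKind.SAMPLED_ANCESTOR:
            v += 1
        elif entry.kind is EventKind.REMOVED_LEAF:
            W.append(entry.time)
        elif entry.kind is EventKind.NONREMOVED_LEAF:
            Y.append(entry.time)
        elif entry.kind is EventKind.UNKNOWN_LEAF:
            raise ValueError("closed form requires fully labeled leaves")
        else:
            X.append(entry.time)
    if any(tj == t for tj in Y):
        raise ValueError("closed form is singular exactly at a non-removed leaf time")

    def safe_log(x: float) -> float:
        return math.log(x) if x > 0 else -math.inf

    Xo = X + [schedule.t_or]
    log_m0 = (
        len(X) * safe_log(params.lam)
        + (v + len(W) + len(Y)) * safe_log(params.psi)
        + len(W) * safe_log(params.r)
        + (v + len(Y)) * safe_log(1.0 - params.r)
    )
    for tj in Xo:
        log_m0 += safe_log(R_of(tj - t, 0.0, params))
    for tj in W:
        log_m0 -= safe_log(R_of(tj - t, 0.0, params))
    for tj in Y:
        log_m0 += safe_log(u_of(tj - t, 0.0, params)) - safe_log(R_of(tj - t, 0.0, params))

    kt = schedule.k_at(t) if t > 0 else schedule.k0
    if log_m0 == -math.inf:
        return ProbVector(np.zeros(i_max + 1), 0.0, kt, t)

    aX = np.array([a_b_coeffs(tj - t, params)[0] for tj in Xo])
    aW = np.array([a_b_coeffs(tj - t, params)[0] for tj in W])
    abY = np.array([a_b_coeffs(tj - t, params) for tj in Y]).reshape(-1, 2)

    values = np.zeros(i_max + 1)
    values[0] = 1.0
    C = np.empty(i_max + 1)
    for a in range(1, i_max + 1):
        C[a] = (
            2.0 * np.sum(aX**a)
            - 2.0 * np.sum(aW**a)
            - np.sum(abY[:, 0] ** a + abY[:, 1] ** a)
        )
    for i in range(1, i_max + 1):
        values[i] = np.dot(values[i - 1 :: -1], C[1 : i + 1]) / i
    out = ProbVector(values=values, log_scale=log_m0, k=kt, t=t)
    return out.rescale()
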