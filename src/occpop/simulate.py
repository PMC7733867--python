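"""Forward simulation of the full process, data reconstruction, and a particle-filter oracle.

The full process is simulated exactly by a Gillespie scheme on the
population-level aggregate rates (total event rate ``gamma * n`` with the
affected individual drawn uniformly): each individual gives birth at rate
``lam``, dies at rate ``mu``, is psi-sampled at rate ``psi`` (entering the
reconstructed tree) and omega-sampled at rate ``omega`` (entering the
occurrence record); each through-time sampling removes the individual with
probability ``r``; survivors at present are rho-sampled independently.

``reconstruct`` prunes the full genealogy down to the reconstructed tree
spanned by all psi- and rho-samples (psi-samples with later-sampled
descent become degree-2 sampled ancestors, written as zero-length-branch
child tips) and collects the omega events into the occurrence record.

``particle_filter_posterior`` is an independent sequential-Monte-Carlo
estimate of the same conditioned population size: particles carry hidden
counts, propagate calendar-forward with the hidden birth-death dynamics
(up ``lam*(2k+i)``, down ``mu*i``) under a continuous potential
``(psi+omega)*(k+i) + (mu-lam)*k`` (the part of the master-equation
outflow not covered by the jump rates), are reweighted by the event-rate
factors at punctual events, and systematically resampled; smoothing
marginals come from the surviving ancestral paths.  It validates the
analytic posterior and its marginal likelihood validates the densities.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core import ModelParams, ProbVector
from .posterior import PosteriorGrid
from .schedule import (
    DATA_KINDS,
    EventKind,
    EventSchedule,
    OccurrenceRecord,
    ReconstructedTree,
    RemovalStatus,
    build_schedule,
)

__all__ = [
    "SimOutcome",
    "NoSampleError",
    "simulate_forward",
    "reconstruct",
    "particle_filter_posterior",
]


class NoSampleError(RuntimeError):
    """The simulated process produced no sample at all (empty data)."""


@dataclasses.dataclass
class _Individual:
    parent: int  # index of the mother, -1 for the progenitor
    birth_age: float
    end_age: float = 0.0  # age at death/removal; 0.0 if alive at present
    alive_at_present: bool = False
    rho_sampled: bool = False
    psi_samples: list = dataclasses.field(default_factory=list)  # (age, removed)
    children: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class SimOutcome:
    """A simulated full process with its observable data.

    ``traj_times``/``traj_sizes`` give the true population size I_t as a
    right-continuous-in-calendar step function: I = traj_sizes[j] on the
    age interval (traj_times[j+1], traj_times[j]], starting at
    traj_times[0] = t_or with one individual.
    """

    params: ModelParams
    seed: int
    individuals: list[_Individual]
    omega_events: list  # (age, removed, individual index)
    traj_times: np.ndarray
    traj_sizes: np.ndarray
    tree: ReconstructedTree | None = None
    occurrences: OccurrenceRecord | None = None
    branch_intervals: list | None = None  # (top_age, bottom_age) per tree branch

    def true_size_at(self, t) -> np.ndarray:
        """True population size at age(s) t (t-minus side at jump instants)."""
        q = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(-self.traj_times, -q, side="right") - 1
        out = self.traj_sizes[np.clip(idx, 0, len(self.traj_sizes) - 1)]
        return out if out.size > 1 else out[0]

    @property
    def n_samples(self) -> int:
        n = sum(ind.rho_sampled for ind in self.individuals)
        n += sum(len(ind.psi_samples) for ind in self.individuals)
        return n + len(self.omega_events)


def simulate_forward(
    params: ModelParams,
    seed: int,
    require_observation: bool = False,
    max_pop: int = 100_000,
    max_tries: int = 10_000,
) -> SimOutcome:
    """Exact Gillespie simulation of the full process from the origin to present.

    With ``require_observation`` the simulation is rejection-sampled until
    at least one psi-, omega- or rho-sample exists (the empirical
    counterpart of conditioning the density on sampling).
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        sim = _simulate_once(params, rng, seed, max_pop)
        has_tree = any(ind.rho_sampled or ind.psi_samples for ind in sim.individuals)
        if has_tree:
            sim.tree, sim.occurrences = reconstruct(sim)
        if not require_observation or has_tree:
            return sim
    raise NoSampleError(f"no reconstructed tree in {max_tries} simulations")


def _simulate_once(params: ModelParams, rng, seed: int, max_pop: int) -> SimOutcome:
    lam, mu, psi, omega, r = params.lam, params.mu, params.psi, params.omega, params.r
    gamma = params.gamma
    individuals = [_Individual(parent=-1, birth_age=params.t_or)]
    alive = [0]
    omega_events: list = []
    traj_times = [params.t_or]
    traj_sizes = [1]
    t = params.t_or
    while alive:
        n = len(alive)
        if n > max_pop:
            raise RuntimeError(
                f"population exceeded {max_pop} at age {t:.3f}; "
                "lower t_or or the growth rate"
            )
        t -= rng.exponential(1.0 / (gamma * n))
        if t <= 0.0:
            break
        who = alive[rng.integers(n)]
        u = rng.random() * gamma
        if u < lam:  # birth
            child = len(individuals)
            individuals.append(_Individual(parent=who, birth_age=t))
            individuals[who].children.append(child)
            alive.append(child)
        elif u < lam + mu:  # death
            individuals[who].end_age = t
            alive.remove(who)
        elif u < lam + mu + psi:  # psi-sampling
            removed = rng.random() < r
            individuals[who].psi_samples.append((t, removed))
            if removed:
                individuals[who].end_age = t
                alive.remove(who)
        else:  # omega-sampling
            removed = rng.random() < r
            omega_events.append((t, removed, who))
            if removed:
                individuals[who].end_age = t
                alive.remove(who)
        traj_times.append(t)
        traj_sizes.append(len(alive))
    for idx in alive:
        individuals[idx].alive_at_present = True
        individuals[idx].rho_sampled = rng.random() < params.rho
    if traj_times[-1] != 0.0:
        traj_times.append(0.0)
        traj_sizes.append(len(alive))
    return SimOutcome(
        params=params,
        seed=seed,
        individuals=individuals,
        omega_events=omega_events,
        traj_times=np.array(traj_times),
        traj_sizes=np.array(traj_sizes, dtype=int),
    )


# ---------------------------------------------------------------------------
# Reconstruction of (tree, occurrences) from the full process
# ---------------------------------------------------------------------------


def reconstruct(sim: SimOutcome) -> tuple[ReconstructedTree, OccurrenceRecord]:
    """Prune the full genealogy to the reconstructed tree and collect occurrences.

    A lineage survives pruning iff it, or any of its descendants, carries a
    psi- or rho-sample.  A psi-sample whose bearer has further-sampled
    descent (through itself or its later children) becomes a sampled
    ancestor; births where only one side has sampled descent vanish; the
    present-time anchor is age 0.
    """
    inds = sim.individuals
    sampled_below: list[bool] = [False] * len(inds)
    # children were appended in decreasing age order; postorder via reversed index order
    for idx in range(len(inds) - 1, -1, -1):
        ind = inds[idx]
        own = ind.rho_sampled or bool(ind.psi_samples)
        sampled_below[idx] = own or any(sampled_below[c] for c in ind.children)

    if not sampled_below[0]:
        raise NoSampleError("no psi- or rho-sample: empty reconstructed tree")

    occ = OccurrenceRecord(
        np.array([t for t, _, _ in sim.omega_events], dtype=float),
        [RemovalStatus.REMOVED if rem else RemovalStatus.NON_REMOVED for _, rem, _ in sim.omega_events],
    )

    events: list[tuple[float, EventKind]] = []
    branch_intervals: list[tuple[float, float]] = []
    counter = [0]

    def label(kind: str) -> str:
        counter[0] += 1
        return f"{kind}{counter[0]}"

    def points_of(idx: int) -> list[tuple[float, str, object]]:
        """Relevant timeline points of individual idx, decreasing age."""
        ind = inds[idx]
        pts: list[tuple[float, str, object]] = []
        for c in ind.children:
            if sampled_below[c]:
                pts.append((inds[c].birth_age, "birth", c))
        for age, removed in ind.psi_samples:
            pts.append((age, "psi", removed))
        if ind.rho_sampled:
            pts.append((0.0, "rho", None))
        pts.sort(key=lambda p: -p[0])
        return pts

    def build(idx: int, pts: list) -> tuple[str, float, str]:
        """Newick text (without the outer branch length) of the pruned
        lineage of ``idx`` restricted to timeline points ``pts``; returns
        (text, age of the emitted node, annotation to append after the
        branch length -- dendropy reads post-length comments)."""
        for p, (age, kind, payload) in enumerate(pts):
            rest = pts[p + 1 :]
            if kind == "birth":
                child_pts = points_of(payload)
                if rest:  # true branching: both sides carry samples
                    left, la, lann = build(payload, child_pts)
                    right, ra, rann = build(idx, rest)
                    events.append((age, EventKind.BRANCHING))
                    txt = (
                        f"({left}:{age - la:.17g}{lann},"
                        f"{right}:{age - ra:.17g}{rann}){label('n')}"
                    )
                    return txt, age, ""
                return build(payload, child_pts)  # pass-through birth
            if kind == "psi":
                removed = bool(payload)
                if rest and not removed:
                    # sampled ancestor: zero-length-branch child tip encoding
                    below, ba, bann = build(idx, rest)
                    events.append((age, EventKind.SAMPLED_ANCESTOR))
                    txt = (
                        f"({label('sa')}:0[&rm=0],"
                        f"{below}:{age - ba:.17g}{bann}){label('n')}"
                    )
                    return txt, age, ""
                events.append(
                    (age, EventKind.REMOVED_LEAF if removed else EventKind.NONREMOVED_LEAF)
                )
                return f"{label('f')}", age, f"[&rm={1 if removed else 0}]"
            if kind == "rho":
                return f"{label('t')}", 0.0, ""
        raise AssertionError("pruned lineage without terminal sample")

    text, root_age, root_ann = build(0, points_of(0))
    stem = sim.params.t_or - root_age
    newick = f"({text}:{stem:.17g}{root_ann});"
    k0 = sum(1 for ind in inds if ind.rho_sampled)
    events.sort(key=lambda e: e[0])
    tree = ReconstructedTree(k0=k0, events=events, newick=newick)

    # branch intervals (top age, bottom age) for lineage-through-time checks
    tops: list[tuple[int, float, tuple]] = [(0, sim.params.t_or, tuple(points_of(0)))]
    while tops:
        idx, top, pts = tops.pop()
        for p, (age, kind, payload) in enumerate(pts):
            rest = pts[p + 1 :]
            if kind == "birth":
                if rest:
                    branch_intervals.append((top, age))
                    tops.append((payload, age, tuple(points_of(payload))))
                    tops.append((idx, age, tuple(rest)))
                    break
                idx, pts_next = payload, points_of(payload)
                tops.append((idx, top, tuple(pts_next)))
                break
            if kind == "psi":
                removed = bool(payload)
                if rest and not removed:
                    branch_intervals.append((top, age))
                    tops.append((idx, age, tuple(rest)))
                    break
                branch_intervals.append((top, age))
                break
            if kind == "rho":
                branch_intervals.append((top, 0.0))
                break
    sim.branch_intervals = branch_intervals
    return tree, occ


def particle_filter_posterior(
    tree: ReconstructedTree,
    occ: OccurrenceRecord,
    params: ModelParams,
    n_particles: int,
    seed: int,
    grid_times=(),
    N_cap: int = 10_000,
) -> tuple[PosteriorGrid, float]:
    """Bootstrap particle filter for the conditioned population size.

    Returns ``(grid, log_marginal_likelihood)``; ``grid`` holds smoothed
    marginals of the total count at ``grid_times`` obtained from the
    ancestral paths of the final particle cloud.  Independent of the
    L/M recursions except for sharing the event schedule.
    """
    rng = np.random.default_rng(seed)
    schedule = build_schedule(tree, occ, params, grid_times)
    entries = schedule.entries
    lam, mu, psi, omega, r = params.lam, params.mu, params.psi, params.omega, params.r

    n = n_particles
    state = np.zeros(n, dtype=np.int64)  # hidden counts i
    logw = np.zeros(n)
    log_ml = 0.0
    history: list[np.ndarray] = []
    hist_k: list[int] = []
    hist_t: list[float] = []

    def propagate(i0: np.ndarray, k: int, t_hi: float, t_lo: float):
        """Hidden birth-death paths from age t_hi down to t_lo; returns states and integrated potential."""
        i = i0.copy()
        pot = np.zeros(n)
        t = np.full(n, t_hi)
        active = np.ones(n, dtype=bool)
        kappa_const = (psi + omega) * k + (mu - lam) * k
        while np.any(active):
            ii = i[active]
            up = lam * (2 * k + ii)
            dn = mu * ii
            tot = up + dn
            with np.errstate(divide="ignore"):
                tau = rng.exponential(np.where(tot > 0, 1.0 / np.maximum(tot, 1e-300), np.inf))
            t_new = t[active] - tau
            seg = np.minimum(t[active], t_hi) - np.maximum(t_new, t_lo)
            pot[active] += ((psi + omega) * ii + kappa_const) * np.clip(seg, 0.0, None)
            done = t_new <= t_lo
            jump = ~done
            u = rng.random(ii.shape)
            ii_new = np.where(u < up / np.maximum(tot, 1e-300), ii + 1, ii - 1)
            i_active = np.where(jump, ii_new, ii)
            i[active] = i_active
            t[active] = np.maximum(t_new, t_lo)
            idx = np.flatnonzero(active)
            active[idx[done]] = False
            if np.any(i > N_cap):
                raise RuntimeError("particle population exploded; lower t_or or rates")
        return i, pot

    def systematic_resample():
        nonlocal state, logw, log_ml, history
        m = logw.max()
        w = np.exp(logw - m)
        W = w.sum()
        log_ml_inc = m + math.log(W / n)
        pos = (rng.random() + np.arange(n)) / n
        cdf = np.cumsum(w) / W
        idx = np.searchsorted(cdf, pos)
        state = state[idx]
        history = [h[idx] for h in history]
        logw = np.zeros(n)
        return log_ml_inc

    k = 1
    t_hi = schedule.t_or
    if entries[-1].is_grid:
        history.append(state.copy())
        hist_k.append(k)
        hist_t.append(t_hi)
    for h in range(len(entries) - 2, -1, -1):
        entry = entries[h]
        state, pot = propagate(state, k, t_hi, entry.time)
        logw -= pot
        t_hi = entry.time
        kind = entry.kind
        if kind in DATA_KINDS:
            state, logw, k = _pf_event(state, logw, k, kind, params, rng)
            # resample at every data event
            log_ml += systematic_resample()
        if entry.is_grid and entry.kind is not EventKind.PRESENT:
            history.append(state.copy())
            hist_k.append(schedule.k[h - 1] if h >= 1 else schedule.k0)
            hist_t.append(entry.time)
        if kind is EventKind.PRESENT:
            logw += state * math.log1p(-params.rho) if params.rho < 1 else np.where(state == 0, 0.0, -np.inf)
            if schedule.k0 > 0:
                logw += schedule.k0 * math.log(params.rho)
            if entry.is_grid:
                history.append(state.copy())
                hist_k.append(schedule.k0)
                hist_t.append(0.0)
    m = logw.max()
    if not np.isfinite(m):
        raise RuntimeError("all particle weights vanished")
    w = np.exp(logw - m)
    log_ml += m + math.log(w.sum() / n)

    # smoothed marginals from ancestral paths, weighted by the final weights
    Nmax = max((int(h.max()) for h in history), default=0)
    probs = np.zeros((len(history), Nmax + 1))
    order = np.argsort(hist_t)
    wnorm = w / w.sum()
    for s in range(len(history)):
        np.add.at(probs[s], history[s], wnorm)
    grid = PosteriorGrid(
        times=np.array([hist_t[o] for o in order]),
        k=np.array([hist_k[o] for o in order], dtype=int),
        probs=probs[order],
        log_evidence=np.full(len(history), log_ml),
    )
    return grid, log_ml


def _pf_event(state, logw, k, kind, params: ModelParams, rng):
    psi, omega, r = params.psi, params.omega, params.r
    if kind is EventKind.REMOVED_LEAF:
        logw = logw + math.log(psi * r) if psi * r > 0 else logw - np.inf
        k -= 1
    elif kind is EventKind.NONREMOVED_LEAF:
        logw = logw + (math.log(psi * (1 - r)) if psi * (1 - r) > 0 else -np.inf)
        state = state + 1
        k -= 1
    elif kind is EventKind.UNKNOWN_LEAF:
        # branch: removed (weight psi*r, no shift) vs non-removed (psi*(1-r), shift +1)
        p_rem = r
        rem = rng.random(state.shape) < p_rem
        state = np.where(rem, state, state + 1)
        logw = logw + (math.log(psi) if psi > 0 else -np.inf)
        k -= 1
    elif kind is EventKind.SAMPLED_ANCESTOR:
        logw = logw + (math.log(psi * (1 - r)) if psi * (1 - r) > 0 else -np.inf)
    elif kind is EventKind.REMOVED_OCCURRENCE:
        with np.errstate(divide="ignore"):
            logw = logw + np.where(state > 0, np.log(omega * r * np.maximum(state, 1)), -np.inf)
        state = np.maximum(state - 1, 0)
    elif kind is EventKind.NONREMOVED_OCCURRENCE:
        with np.errstate(divide="ignore"):
            logw = logw + np.log(omega * (1 - r) * (k + state))
    elif kind is EventKind.UNKNOWN_OCCURRENCE:
        w_rem = r * state
        w_non = (1 - r) * (k + state)
        tot = w_rem + w_non
        rem = rng.random(state.shape) * tot < w_rem
        with np.errstate(divide="ignore"):
            logw = logw + np.where(tot > 0, np.log(omega * tot), -np.inf)
        state = np.where(rem, state - 1, state)
    else:  # branching
        logw = logw + math.log(params.lam)
        k += 1
    return state, logw, k
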