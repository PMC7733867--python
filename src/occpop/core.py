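"""Closed-form building blocks of the birth-death sampling process.

The population follows a linear birth-death process (birth rate ``lam``,
death rate ``mu``) started from a single individual ``t_or`` time units
before present.  Individuals are sampled through time at rate ``psi``
(included in the reconstructed tree) or ``omega`` (recorded only as an
occurrence time), and each sampling removes the individual from the
population with probability ``r``.  Extant individuals are sampled at
present with probability ``rho``.  Time is measured as *age*: it runs from
0 at present towards the past, so "at time t" always means t units before
present.

Two classical one-lineage probabilities drive everything else:

* ``u(t, z)`` -- probability that a lineage alive at time t leaves no
  sample whatsoever by present, where each extant descendant at present
  escapes rho-sampling independently with probability ``z``;
* ``p(t, z)`` -- probability that the lineage leads to exactly one sampled
  individual at present (and no other sample).

Both have closed forms in terms of the roots ``x1 <= x2`` of the quadratic
``lam*x**2 - gamma*x + mu`` with ``gamma = lam + mu + psi + omega`` and
discriminant ``Delta = sqrt(gamma**2 - 4*lam*mu)``.  The supercritical-or-
sampled regime ``Delta > 0`` is assumed throughout; the critical boundary
``lam == mu`` with ``psi == omega == 0`` is rejected.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

__all__ = [
    "ModelParams",
    "ParameterError",
    "CriticalProcessError",
    "ImpossibleDataError",
    "ProbVector",
    "discriminant_roots",
    "u_of",
    "p_of",
    "R_of",
    "a_b_coeffs",
]


class ParameterError(ValueError):
    """Raised for invalid model parameters."""


class CriticalProcessError(ParameterError):
    """Raised for the unsupported critical case Delta == 0 (lam == mu, psi == omega == 0)."""


class ImpossibleDataError(ValueError):
    """Raised when the data has probability zero under the parameters (e.g. rho=0 with present tips)."""


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """The seven free parameters of the process plus derived constants.

    Parameters
    ----------
    lam : float
        Per-capita birth rate (1/time), > 0.
    mu : float
        Per-capita death rate, >= 0.
    psi : float
        Tree-sampling rate (samples included in the reconstructed tree).
    omega : float
        Occurrence-sampling rate (samples recorded only by their time).
    rho : float
        Present-day sampling probability, in [0, 1].
    r : float
        Removal probability upon psi- or omega-sampling, in [0, 1].
    t_or : float
        Origin time (age at which the process starts with one individual).

    Derived attributes ``gamma = lam+mu+psi+omega``,
    ``Delta = sqrt(gamma**2 - 4*lam*mu)`` and the roots ``x1 <= x2`` of
    ``lam*x**2 - gamma*x + mu`` are computed on construction.
    """

    lam: float
    mu: float
    psi: float = 0.0
    omega: float = 0.0
    rho: float = 1.0
    r: float = 0.0
    t_or: float = 1.0
    gamma: float = dataclasses.field(init=False, repr=False)
    Delta: float = dataclasses.field(init=False, repr=False)
    x1: float = dataclasses.field(init=False, repr=False)
    x2: float = dataclasses.field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ParameterError(f"birth rate lam must be > 0, got {self.lam}")
        if self.mu < 0 or self.psi < 0 or self.omega < 0:
            raise ParameterError("rates mu, psi, omega must be >= 0")
        if not 0 <= self.rho <= 1:
            raise ParameterError(f"rho must be in [0, 1], got {self.rho}")
        if not 0 <= self.r <= 1:
            raise ParameterError(f"r must be in [0, 1], got {self.r}")
        if self.t_or <= 0:
            raise ParameterError(f"origin time t_or must be > 0, got {self.t_or}")
        gamma = self.lam + self.mu + self.psi + self.omega
        disc = gamma * gamma - 4.0 * self.lam * self.mu
        if disc <= 0:
            raise CriticalProcessError(
                "Delta**2 = gamma**2 - 4*lam*mu must be > 0; the critical case "
                "lam == mu with psi == omega == 0 is not supported (perturb the rates)"
            )
        Delta = math.sqrt(disc)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "Delta", Delta)
        object.__setattr__(self, "x1", (gamma - Delta) / (2.0 * self.lam))
        object.__setattr__(self, "x2", (gamma + Delta) / (2.0 * self.lam))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lam": self.lam, "mu": self.mu, "psi": self.psi, "omega": self.omega,
            "rho": self.rho, "r": self.r, "t_or": self.t_or,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(d[k]) for k in ("lam", "mu", "psi", "omega", "rho", "r", "t_or")})

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


def discriminant_roots(params: ModelParams) -> tuple[float, float, float]:
    """Return ``(Delta, x1, x2)``, the discriminant and roots of ``lam*x**2 - gamma*x + mu``."""
    return params.Delta, params.x1, params.x2


def u_of(t, z, params: ModelParams):
    """Probability that a lineage alive at time ``t`` leaves no sample by present.

    ``z`` is the initial condition u(0, z) = z, i.e. the probability that an
    individual alive at present is not rho-sampled; the model shorthand u_t
    uses ``z = 1 - rho``.  Accepts scalar or array ``t``/``z``.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    x1, x2 = params.x1, params.x2
    e = np.exp(-params.Delta * t)
    num = x1 * (x2 - z) - x2 * (x1 - z) * e
    den = (x2 - z) - (x1 - z) * e
    out = num / den
    return out.item() if out.ndim == 0 else out


def p_of(t, z, params: ModelParams):
    """Probability that a lineage alive at time ``t`` leads to exactly one sample, at present.

    Initial condition p(0, z) = 1 - z; p(t, 1) = 0 for all t.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    out = (1.0 - z) * R_of(t, z, params, _allow_z1=True)
    return out.item() if out.ndim == 0 else out


def R_of(t, z, params: ModelParams, *, _allow_z1: bool = False):
    """``R(t, z) = p(t, z) / (1 - z)``; satisfies R(0, z) = 1.

    Well defined for all z (the 1-z factor cancels); the explicit form is
    ``(Delta/lam)**2 * exp(-Delta*t) / ((x2-z) - (x1-z)*exp(-Delta*t))**2``.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    if not _allow_z1 and np.any(z >= 1.0):
        # R is finite at z=1 too; the documented contract is z <= 1
        if np.any(z > 1.0):
            raise ValueError("R(t, z) requires z <= 1")
    e = np.exp(-params.Delta * t)
    den = (params.x2 - z) - (params.x1 - z) * e
    out = (params.Delta / params.lam) ** 2 * e / (den * den)
    return out.item() if out.ndim == 0 else out


def a_b_coeffs(t, params: ModelParams):
    """Coefficients ``(a_t, b_t)`` of the log-derivative recursions for the omega=0 closed forms.

    ``a_t = (1 - e^{-Delta t}) / (x2 - x1 e^{-Delta t})`` collects the
    z-expansion of d/dz log R, via d/dz log R = sum_a 2 a_t^a z^(a-1);
    ``b_t = (x1 - x2 e^{-Delta t}) / (x1 x2 (1 - e^{-Delta t}))`` enters
    d/dz log u = sum_a (a_t^a - b_t^a) z^(a-1).  ``b_t`` diverges as t -> 0
    because u(0, z) = z makes log u singular at z = 0; callers only evaluate
    it at strictly positive elapsed times.
    """
    t = np.asarray(t, dtype=float)
    x1, x2 = params.x1, params.x2
    e = np.exp(-params.Delta * t)
    one_me = -np.expm1(-params.Delta * t)  # 1 - e, accurate for small t
    a = one_me / (x2 - x1 * e)
    with np.errstate(divide="ignore"):
        b = (x1 - x2 * e) / (x1 * x2 * one_me)
    if a.ndim == 0:
        return a.item(), b.item()
    return a, b


# ---------------------------------------------------------------------------
# Shared truncated-vector container for the backward (L) and forward (M) sweeps
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ProbVector:
    """A truncated vector over hidden-individual counts i in {0..N} with a log scale.

    Represents either L_t(i) (backward sweep) or M_t(i) (forward sweep); the
    quantity stored is ``values * exp(log_scale)``.  ``k`` is the lineage
    count of the current epoch and ``t`` the time stamp (age).
    """

    values: np.ndarray
    log_scale: float
    k: int
    t: float

    @property
    def N(self) -> int:
        return len(self.values) - 1

    @property
    def is_zero(self) -> bool:
        return not np.any(self.values > 0.0)

    def copy(self) -> "ProbVector":
        return ProbVector(self.values.copy(), self.log_scale, self.k, self.t)

    def rescale(self) -> "ProbVector":
        """Fold the max of ``values`` into ``log_scale`` (in place); no-op on a zero vector."""
        m = float(np.max(self.values))
        if m > 0.0 and not (1e-3 <= m <= 1e3):
            self.values /= m
            self.log_scale += math.log(m)
        return self

    def log_total(self) -> float:
        """log of the represented vector's sum (-inf for a zero vector)."""
        s = float(np.sum(self.values))
        return -math.inf if s <= 0.0 else math.log(s) + self.log_scale

    def log_entry(self, i: int) -> float:
        v = float(self.values[i])
        return -math.inf if v <= 0.0 else math.log(v) + self.log_scale

    def scaled(self) -> np.ndarray:
        """The represented vector ``values * exp(log_scale)`` (may under/overflow; for display)."""
        return self.values * math.exp(self.log_scale)
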