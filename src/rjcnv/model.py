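"""Marginalized Bayesian hierarchical model for copy-number segmentation.

The genome (one analytic stretch of I retained windows) is partitioned into
M regions by breakpoint indicators B = [b_0..b_I] (b_0 = b_I = 1), each
region carrying one of K copy-number states with the neighbour-distinct
constraint s_m != s_{m+1}.  The unnormalized posterior factorizes as

    p(B, C | D)  ∝  p(B) × p(C | B) × p(D | B, C)

with

* ``p(B) = λ^(M-1) (1-λ)^(I-M)`` — independent Bernoulli(λ) breakpoints;
* ``p(C|B)`` — the first region's state is multinomial with Dirichlet(W0)
  weights and every following region's state is multinomial over the K-1
  labels distinct from its predecessor, with Dirichlet weights
  w0k/(1-w0k') shared across all regions following state k'.  Integrating
  the weights out gives a product of Pólya-urn gamma-function terms that
  depends on the sequence only through the transition counts;
* ``p(D|B,C)`` — within a region the D_i are i.i.d. normal with a
  normal–inverse-gamma prior on (mean, variance) specific to the region's
  state; the marginal is a closed-form product over regions.

Everything is evaluated in log space with ``math.lgamma``; region sums of
D and D² come from prefix sums so each region term costs O(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BoundaryVector",
    "RegionStateSequence",
    "Hyperparameters",
    "log_boundary_prior",
    "log_state_prior",
    "log_depth_likelihood",
    "log_posterior_kernel",
    "estimate_hyperparameters",
    "region_loglik",
    "state_prior_from_sequence",
]

LN_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BoundaryVector:
    """Breakpoint indicators b_0..b_I over the I+1 window boundaries."""
    b: tuple[int, ...]

    def __post_init__(self):
        if len(self.b) < 2 or self.b[0] != 1 or self.b[-1] != 1:
            raise ValueError("b_0 and b_I must both be 1")
        if any(x not in (0, 1) for x in self.b):
            raise ValueError("boundary indicators must be 0/1")

    @property
    def n_windows(self) -> int:
        return len(self.b) - 1

    @property
    def n_regions(self) -> int:
        """M = number of 1s among b_1..b_I."""
        return sum(self.b[1:])

    @property
    def region_lengths(self) -> tuple[int, ...]:
        lengths = []
        last = 0
        for i in range(1, len(self.b)):
            if self.b[i] == 1:
                lengths.append(i - last)
                last = i
        return tuple(lengths)

    @classmethod
    def from_breaks(cls, n_windows: int, interior_breaks: list[int]) -> "BoundaryVector":
        b = [0] * (n_windows + 1)
        b[0] = b[-1] = 1
        for i in interior_breaks:
            b[i] = 1
        return cls(tuple(b))


@dataclass(frozen=True)
class RegionStateSequence:
    """Region states s_1..s_M as 1-based labels in {1..K}, neighbour-distinct."""
    s: tuple[int, ...]
    k: int

    def __post_init__(self):
        if any(not (1 <= x <= self.k) for x in self.s):
            raise ValueError("state labels must lie in 1..K")
        if any(a == b for a, b in zip(self.s, self.s[1:])):
            raise ValueError("consecutive regions must have different states")


@dataclass(frozen=True)
class Hyperparameters:
    """Prior constants of the hierarchical model.

    Single-sample mode uses K=5 states meaning absolute CN 1..5 (normal is
    state 2); paired mode uses K=3 meaning loss/normal/gain (normal is
    state 2 as well).
    """
    k: int
    lam: float
    w0: tuple[float, ...]
    mu0: tuple[float, ...]
    kappa: tuple[float, ...]
    alpha: tuple[float, ...]
    beta: tuple[float, ...]

    normal_state: int = 2

    def __post_init__(self):
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lambda must lie in (0, 1)")
        for name in ("w0", "mu0", "kappa", "alpha", "beta"):
            if len(getattr(self, name)) != self.k:
                raise ValueError(f"{name} must have length K={self.k}")
        if abs(sum(self.w0) - 1.0) > 1e-9 or any(w <= 0 for w in self.w0):
            raise ValueError("w0 must be strictly positive and sum to 1")
        if list(self.mu0) != sorted(self.mu0) or len(set(self.mu0)) != self.k:
            raise ValueError("mu0 must be strictly increasing in the state label")
        if any(x <= 0 for x in self.kappa + self.alpha + self.beta):
            raise ValueError("kappa, alpha, beta must be positive")

    # -- derived tables (computed lazily, cached on the instance dict) -----

    def tables(self) -> "_HpTables":
        t = getattr(self, "_tables", None)
        if t is None:
            t = _HpTables(self)
            object.__setattr__(self, "_tables", t)
        return t

    def to_dict(self) -> dict:
        return {
            "k": self.k, "lambda": self.lam, "w0": list(self.w0),
            "mu0": list(self.mu0), "kappa": list(self.kappa),
            "alpha": list(self.alpha), "beta": list(self.beta),
            "normal_state": self.normal_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(k=d["k"], lam=d["lambda"], w0=tuple(d["w0"]),
                   mu0=tuple(d["mu0"]), kappa=tuple(d["kappa"]),
                   alpha=tuple(d["alpha"]), beta=tuple(d["beta"]),
                   normal_state=d.get("normal_state", 2))


class _HpTables:
    """Precomputed constants: log w0, transition concentrations and their
    log-gammas, per-state likelihood constants."""

    def __init__(self, hp: Hyperparameters):
        k = hp.k
        self.log_w0 = [math.log(w) for w in hp.w0]
        # a[kp][kk] = w0_kk / (1 - w0_kp), 0-based indices, diagonal unused
        self.a = [[hp.w0[kk] / (1.0 - hp.w0[kp]) if kk != kp else 0.0
                   for kk in range(k)] for kp in range(k)]
        self.lgam_a = [[math.lgamma(self.a[kp][kk]) if kk != kp else 0.0
                        for kk in range(k)] for kp in range(k)]
        # per-state constants of the NIG marginal
        self.const = [0.5 * math.log(hp.kappa[j]) + hp.alpha[j] * math.log(hp.beta[j])
                      - math.lgamma(hp.alpha[j]) for j in range(k)]
        self.kmu = [hp.kappa[j] * hp.mu0[j] for j in range(k)]
        self.kmu2 = [hp.kappa[j] * hp.mu0[j] ** 2 for j in range(k)]


# ---------------------------------------------------------------------------
# the three log factors


def log_boundary_prior(b: BoundaryVector, lam: float) -> float:
    """(M-1) ln λ + (I-M) ln(1-λ)."""
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must lie in (0, 1)")
    m = b.n_regions
    i = b.n_windows
    return (m - 1) * math.log(lam) + (i - m) * math.log(1.0 - lam)


def state_prior_from_sequence(states: list[int] | tuple[int, ...],
                              hp: Hyperparameters) -> float:
    """Log p(C|B) from a 1-based state sequence (internal fast path)."""
    t = hp.tables()
    s0 = states[0] - 1
    total = t.log_w0[s0]
    if len(states) == 1:
        return total
    # transition counts n_{k'k}
    counts: dict[tuple[int, int], int] = {}
    totals: dict[int, int] = {}
    prev = s0
    for lab in states[1:]:
        cur = lab - 1
        counts[(prev, cur)] = counts.get((prev, cur), 0) + 1
        totals[prev] = totals.get(prev, 0) + 1
        prev = cur
    for kp, n in totals.items():
        total -= math.lgamma(1.0 + n)
    for (kp, kk), n in counts.items():
        total += math.lgamma(n + t.a[kp][kk]) - t.lgam_a[kp][kk]
    return total


def log_state_prior(s: RegionStateSequence, w0) -> float:
    """Log of the marginal state-sequence prior p(C|B).

    ``w0`` may be a simplex tuple (a throwaway Hyperparameters is built with
    neutral depth constants) or a full :class:`Hyperparameters`.
    """
    if isinstance(w0, Hyperparameters):
        hp = w0
    else:
        k = len(w0)
        hp = Hyperparameters(k=k, lam=0.5, w0=tuple(w0),
                             mu0=tuple(float(j) for j in range(k)),
                             kappa=(1.0,) * k, alpha=(2.0,) * k, beta=(1.0,) * k)
    if hp.k != s.k:
        raise ValueError("K mismatch between sequence and weights")
    return state_prior_from_sequence(s.s, hp)


def region_loglik(l_m: int, sum_d: float, sum_d2: float, state: int,
                  hp: Hyperparameters) -> float:
    """Log marginal likelihood of one region's windows under one state.

    ``state`` is the 1-based label; l_m the number of windows; sum_d and
    sum_d2 the region's ΣD and ΣD².
    """
    j = state - 1
    t = hp.tables()
    kap = hp.kappa[j]
    alpha = hp.alpha[j]
    kl = kap + l_m
    inner = hp.beta[j] + 0.5 * (t.kmu2[j] + sum_d2 - (t.kmu[j] + sum_d) ** 2 / kl)
    if inner <= 0.0:
        raise FloatingPointError("posterior beta term <= 0: implementation bug")
    return (-0.5 * l_m * LN_2PI + t.const[j] - 0.5 * math.log(kl)
            + math.lgamma(alpha + 0.5 * l_m) - (alpha + 0.5 * l_m) * math.log(inner))


def _region_slices(b: BoundaryVector) -> list[tuple[int, int]]:
    out = []
    last = 0
    for i in range(1, len(b.b)):
        if b.b[i] == 1:
            out.append((last, i))
            last = i
    return out


def log_depth_likelihood(d: np.ndarray, b: BoundaryVector,
                         s: RegionStateSequence, hp: Hyperparameters) -> float:
    """Log p(D|B,C): sum of normal–inverse-gamma marginals over regions."""
    d = np.asarray(d, dtype=float)
    if len(d) != b.n_windows:
        raise ValueError("RDS length must equal the number of windows")
    slices = _region_slices(b)
    if len(slices) != len(s.s):
        raise ValueError("state sequence length must equal the region count")
    total = 0.0
    for (i0, i1), lab in zip(slices, s.s):
        seg = d[i0:i1]
        total += region_loglik(i1 - i0, float(seg.sum()),
                               float((seg * seg).sum()), lab, hp)
    return total


def log_posterior_kernel(d: np.ndarray, b: BoundaryVector,
                         s: RegionStateSequence, hp: Hyperparameters) -> float:
    """Log of the unnormalized posterior p(B)p(C|B)p(D|B,C)."""
    return (log_boundary_prior(b, hp.lam)
            + log_state_prior(s, hp)
            + log_depth_likelihood(d, b, s, hp))


# ---------------------------------------------------------------------------
# empirical hyperparameters


DEFAULT_W0 = {
    "single": (0.05, 0.80, 0.05, 0.05, 0.05),
    "paired": (0.05, 0.90, 0.05),
}
VARIANCE_FLOOR = 1e-4


def estimate_hyperparameters(d: np.ndarray, mode: str = "single",
                             k: int | None = None,
                             m_init: int = 1,
                             overrides: dict | None = None) -> Hyperparameters:
    """Empirical prior constants from the genome-wide RDS distribution.

    Location m̂ is the median of D and scale ŝ² the squared normalized MAD
    (robust to the CNV minority).  State means expect depth proportional to
    copy number: single mode μ0k = m̂ + ln(k/2) for CN k in 1..5; paired
    mode μ0 = m̂ + [ln ½, 0, ln 1.5] (a heterozygous duplication on a
    diploid raises depth 1.5-fold).  α=2 and β = ŝ²(α-1) put the prior
    variance mean at ŝ².  κ controls how tightly a region's mean is tied
    to its state's mean (prior sd ŝ/√κ); it is set so that sd equals a
    quarter of the smallest gap between adjacent state means, κ =
    (4ŝ/gap_min)², floored at 1 — a loose κ leaves the states practically
    interchangeable for long regions, because the mean-mismatch penalty
    of the marginal likelihood saturates at (x̄-μ0)²·κ/(2σ²) as the region
    grows.  λ comes from the initialization's breakpoint count:
    max((M_init-1)/(I-1), 1/I).  Every value can be overridden.

    Raises ``ValueError`` with fewer than 100 retained windows unless
    ``overrides`` supplies everything needed implicitly (call sites in
    tests construct Hyperparameters directly instead).
    """
    d = np.asarray(d, dtype=float)
    i = len(d)
    if i < 100:
        raise ValueError("need at least 100 retained windows to estimate priors")
    if mode not in ("single", "paired"):
        raise ValueError(f"unknown mode {mode!r}")
    if k is None:
        k = 5 if mode == "single" else 3
    overrides = dict(overrides or {})

    m_hat = float(np.median(d))
    mad = float(np.median(np.abs(d - m_hat)))
    s2_hat = (1.4826 * mad) ** 2
    if s2_hat < VARIANCE_FLOOR:
        import warnings
        warnings.warn("near-constant RDS; variance floored at 1e-4", RuntimeWarning,
                      stacklevel=2)
        s2_hat = VARIANCE_FLOOR

    if mode == "single":
        mu0 = tuple(m_hat + math.log(j / 2.0) for j in range(1, k + 1))
        w0 = DEFAULT_W0["single"] if k == 5 else _uniformish_w0(k)
    else:
        if k != 3:
            raise ValueError("paired mode uses K=3")
        mu0 = (m_hat + math.log(0.5), m_hat, m_hat + math.log(1.5))
        w0 = DEFAULT_W0["paired"]

    alpha = tuple(overrides.get("alpha", (2.0,) * k))
    beta_default = tuple(s2_hat * (a - 1.0) for a in alpha)
    gap_min = min(b - a for a, b in zip(mu0, mu0[1:]))
    kappa_default = max(1.0, (4.0 * math.sqrt(s2_hat) / gap_min) ** 2)
    lam = max((m_init - 1) / (i - 1), 1.0 / i)
    lam = min(lam, 1.0 - 1.0 / i)

    params = {
        "k": k,
        "lam": overrides.get("lam", lam),
        "w0": tuple(overrides.get("w0", w0)),
        "mu0": tuple(overrides.get("mu0", mu0)),
        "kappa": tuple(overrides.get("kappa", (kappa_default,) * k)),
        "alpha": alpha,
        "beta": tuple(overrides.get("beta", beta_default)),
    }
    return Hyperparameters(**params)


def _uniformish_w0(k: int) -> tuple[float, ...]:
    # normal state keeps 0.8 mass; the rest is spread evenly
    rest = 0.2 / (k - 1)
    return tuple(0.8 if j == 1 else rest for j in range(k))
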