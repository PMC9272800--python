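"""Likelihood and prior building blocks.

The observation model is a K-component mixture: component 1 ("noise") is a
zero-inflated Poisson ZIP(tau, lambda^(1)) and components k >= 2 are
Poisson(lambda^(k)).  Component means absorb the systematic Hi-C biases
through a log-linear regression,

    log lambda_s^(k) = b0 + b1*log D_s + b2*log GC_s + b3*log TE_s + b4*log ACC_s,

and the latent component labels z carry a K-state Potts prior on the pair
lattice, p(z | gamma) = C(gamma)^-1 exp(gamma * #concordant neighbour pairs),
whose partition function C(gamma) is intractable except by brute force on
tiny lattices (provided here as a test oracle).

All functions are pure; vectorized forms operate on whole label/count
arrays.  The ZIP mean is (1 - tau) * lambda and its variance is
lambda * (1 - tau) * (1 + tau * lambda).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numba
import numpy as np
from scipy.special import gammaln, logsumexp

from .lattice import PairLattice
from .observations import Observations, PairObservation

__all__ = [
    "ComponentParams",
    "ModelState",
    "LOG_LAMBDA_CAP",
    "zip_log_pmf",
    "poisson_log_pmf",
    "component_mean",
    "emission_log_probs",
    "mixture_log_density",
    "potts_log_unnormalized",
    "potts_partition_bruteforce",
    "potts_full_conditional",
    "potts_gibbs_sweep",
    "simulate_potts_field",
]

#: default cap on |log lambda|; breaching it signals a runaway regression state
LOG_LAMBDA_CAP = 50.0


@dataclass(frozen=True)
class ComponentParams:
    """Regression coefficients (b0, b1 distance, b2 GC, b3 TE, b4 accessibility)."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (5,):
            raise ValueError("beta must have 5 coefficients")
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta must be finite")
        object.__setattr__(self, "beta", beta)


@dataclass
class ModelState:
    """All unknowns of the mixture-HMRF model.

    ``alphas`` are the component proportions implied by the current labels
    (the Potts field is the sole prior on z; alphas are reported, not
    sampled separately).
    """

    K: int
    alphas: np.ndarray
    tau: float
    components: list[ComponentParams]
    gamma: float
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.shape != (self.K,) or np.any(self.alphas < 0):
            raise ValueError("alphas must be K non-negative proportions")
        if abs(self.alphas.sum() - 1.0) > 1e-9:
            raise ValueError("alphas must sum to 1")
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if len(self.components) != self.K:
            raise ValueError("need one ComponentParams per component")
        self.z = np.asarray(self.z, dtype=np.int64)
        if self.z.size and (self.z.min() < 1 or self.z.max() > self.K):
            raise ValueError("labels must lie in 1..K")

    @property
    def betas(self) -> np.ndarray:
        return np.stack([c.beta for c in self.components])


# ---------------------------------------------------------------------------
# emission distributions
# ---------------------------------------------------------------------------

def poisson_log_pmf(y, lam):
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("Poisson mean must be positive")
    return y * np.log(lam) - lam - gammaln(y + 1)


def zip_log_pmf(y, tau, lam):
    """Log pmf of the zero-inflated Poisson: log[tau*1{y=0} + (1-tau)*Pois(y; lam)].

    Stable in log space; accepts scalars or arrays (broadcast).
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    if np.any(lam <= 0):
        raise ValueError("ZIP mean parameter lam must be positive")
    with np.errstate(divide="ignore"):
        log_tau = np.log(tau)
        log_1mtau = np.log1p(-tau)
    log_pois = poisson_log_pmf(y, lam)
    zero_branch = np.logaddexp(log_tau, log_1mtau + np.broadcast_to(-lam, log_pois.shape))
    out = np.where(y == 0, zero_branch, log_1mtau + log_pois)
    return out if out.ndim else float(out)


def component_mean(params: ComponentParams, obs, cap: float = LOG_LAMBDA_CAP):
    """Mean lambda = exp(linear predictor) for one component.

    ``obs`` may be a single :class:`PairObservation` or an
    :class:`Observations` table (vectorized).  Raises if |log lambda|
    exceeds ``cap`` anywhere.
    """
    if isinstance(obs, PairObservation):
        covs = np.array([obs.D, obs.GC, obs.TE, obs.ACC], dtype=float)
        if np.any(covs <= 0):
            raise ValueError("covariates must be strictly positive")
        x = np.concatenate([[1.0], np.log(covs)])
        eta = float(x @ params.beta)
        if abs(eta) > cap:
            raise FloatingPointError(f"|log lambda| = {abs(eta):.2f} exceeds cap {cap}")
        return float(np.exp(eta))
    if isinstance(obs, Observations):
        X = obs.design
    else:
        X = np.asarray(obs, dtype=float)
    eta = X @ params.beta
    if np.any(np.abs(eta) > cap):
        s = int(np.argmax(np.abs(eta)))
        raise FloatingPointError(
            f"|log lambda| exceeds cap {cap} at site {s} (beta={params.beta})"
        )
    return np.exp(eta)


def emission_log_probs(y: np.ndarray, tau: float, lams: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log emission probabilities given each component.

    Column 0 is the ZIP noise component; columns 1..K-1 are Poisson.
    ``lams`` has shape (n, K).
    """
    y = np.asarray(y)
    n, K = lams.shape
    out = np.empty((n, K))
    out[:, 0] = zip_log_pmf(y, tau, lams[:, 0])
    for k in range(1, K):
        out[:, k] = poisson_log_pmf(y, lams[:, k])
    return out


def label_allocation_log_prob(z: np.ndarray, K: int) -> float:
    """Multinomial allocation term of the complete-data likelihood.

    sum_k n_k log(n_k / n) with the mixture weights set to their empirical
    maximizer (the label frequencies of z itself); empty components
    contribute zero.  This is the entropy cost a configuration pays for
    splitting data across components.
    """
    counts = np.bincount(np.asarray(z, dtype=np.int64), minlength=K + 1)[1: K + 1]
    n = counts.sum()
    nz = counts[counts > 0]
    return float((nz * (np.log(nz) - np.log(n))).sum())


def mixture_log_density(y, obs, state: ModelState):
    """Log of the K-term mixture density f(y) at one or many observations."""
    single = isinstance(obs, PairObservation)
    if single:
        lams = np.array([[component_mean(c, obs) for c in state.components]])
        yv = np.asarray([y])
    else:
        lams = np.column_stack([component_mean(c, obs) for c in state.components])
        yv = np.asarray(y)
    log_emis = emission_log_probs(yv, state.tau, lams)
    with np.errstate(divide="ignore"):
        log_alpha = np.log(state.alphas)
    out = logsumexp(log_emis + log_alpha, axis=1)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Potts prior
# ---------------------------------------------------------------------------

def _check_labels(z: np.ndarray, K: int | None = None) -> np.ndarray:
    z = np.asarray(z, dtype=np.int64)
    if z.min() < 1 or (K is not None and z.max() > K):
        raise ValueError("labels must lie in 1..K")
    return z


def potts_log_unnormalized(z: np.ndarray, gamma: float, lattice: PairLattice) -> float:
    """gamma times the number of concordant unordered neighbour pairs."""
    z = _check_labels(z)
    if z.shape != (lattice.n_sites,):
        raise ValueError("label vector does not match lattice")
    return float(gamma * lattice.concordant_pairs(z))


def potts_partition_bruteforce(lattice: PairLattice, gamma: float, K: int) -> float:
    """Exact partition function C(gamma) by enumerating all K^n configurations.

    Test oracle only: refuses lattices with more than 16 sites or more than
    ~1e6 configurations.
    """
    n = lattice.n_sites
    if n > 16 or K**n > 1_048_576:
        raise ValueError("lattice too large for brute-force enumeration")
    configs = np.array(list(itertools.product(range(1, K + 1), repeat=n)), dtype=np.int64)
    eq = (configs[:, lattice.edges[:, 0]] == configs[:, lattice.edges[:, 1]]).sum(axis=1) \
        if lattice.n_edges else np.zeros(len(configs), dtype=np.int64)
    return float(np.exp(gamma * eq).sum())


def potts_full_conditional(
    site: int, z: np.ndarray, gamma: float, lattice: PairLattice, K: int
) -> np.ndarray:
    """P(z_site = k | rest) over k = 1..K, proportional to exp(gamma * n_k)."""
    z = _check_labels(z, K)
    counts = np.zeros(K)
    for t in lattice.neighbors(site):
        counts[z[t] - 1] += 1
    w = np.exp(gamma * (counts - counts.max()))
    return w / w.sum()


@numba.njit(cache=True)
def _sweep_kernel(z, nbr_idx, order, gamma, K, extra, gumbel):  # pragma: no cover
    n = z.shape[0]
    for t in range(order.shape[0]):
        s = order[t]
        best_k = 0
        best_v = -1e300
        for k in range(K):
            cnt = 0
            for d in range(4):
                u = nbr_idx[s, d]
                if u < n and z[u] == k + 1:
                    cnt += 1
            v = gamma * cnt + extra[s, k] - np.log(gumbel[s, k])
            if v > best_v:
                best_v = v
                best_k = k
        z[s] = best_k + 1


def potts_gibbs_sweep(
    z: np.ndarray,
    gamma: float,
    lattice: PairLattice,
    K: int,
    rng: np.random.Generator,
    log_emissions: np.ndarray | None = None,
) -> np.ndarray:
    """One chromatic (checkerboard) Gibbs sweep, in place.

    Updates all even-coloured sites, then all odd ones; within a colour
    class sites are conditionally independent given the other class, so
    this is a valid systematic scan with the Potts (or label-posterior)
    distribution invariant.  ``log_emissions`` (n, K), when given,
    multiplies the Potts full conditional by the per-site emission
    likelihood, giving the label update of the posterior sampler.
    Categorical draws use the Gumbel-max trick with noise from ``rng``.
    """
    n = lattice.n_sites
    extra = log_emissions if log_emissions is not None else _ZERO_EXTRA.setdefault(
        (n, K), np.zeros((n, K))
    )
    noise = rng.standard_exponential((n, K))  # -log(Exp) is Gumbel noise
    _sweep_kernel(z, lattice.nbr_idx, lattice.color_order, float(gamma), K, extra, noise)
    return z


_ZERO_EXTRA: dict = {}


def simulate_potts_field(
    lattice: PairLattice,
    gamma: float,
    K: int,
    rng: np.random.Generator,
    sweeps: int,
) -> np.ndarray:
    """Gibbs-sample a Potts configuration from a uniform random start."""
    z = rng.integers(1, K + 1, size=lattice.n_sites)
    for _ in range(sweeps):
        potts_gibbs_sweep(z, gamma, lattice, K, rng)
    return z
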