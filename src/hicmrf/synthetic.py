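"""Synthetic contact-matrix data with the exact structure the model assumes.

Generates a K-component labelling (either i.i.d. multinomial with given
proportions, or a Potts field sampled by Gibbs sweeps on the pair lattice),
draws the four bias covariates from declared distributions, and emits counts
from the ZIP/Poisson mixture with log-linear component means.  Every
downstream stage (inference, model selection, calling, CLI) is testable
against the ground truth stored alongside.

The default configuration mirrors the two-component simulation study the
method was validated on: n = 2500 pair observations on a 50 x 50 lattice
with component proportions 0.7 (noise) / 0.3 (signal); presets for equal
and signal-heavy proportions and a three-component design are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import PairLattice
from .model import ComponentParams, component_mean, simulate_potts_field
from .observations import Observations, COVARIATE_NAMES

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "preset_config",
    "PRESETS",
    "simulate_labels",
    "simulate_observations",
    "simulate_dataset",
    "write_dataset",
    "read_covariate_table",
]

#: 2 kb bins, the resolution the Drosophila analyses were run at
DEFAULT_BIN_SIZE = 2000

#: minimum covariate value after drawing (logs must be finite)
COVARIATE_FLOOR = 1e-6


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution of one covariate: name + parameters.

    Supported kinds:

    - ``("uniform", lo, hi)`` with lo > 0
    - ``("uniform_grid", values)`` uniform over an explicit positive grid
    - ``("poisson_plus", rate, shift)`` Poisson(rate) + shift, shift > 0
    - ``("lognormal", mu, sigma)``
    - ``("constant", value)``
    """

    kind: str
    params: tuple

    def __post_init__(self) -> None:
        kind, p = self.kind, tuple(self.params)
        object.__setattr__(self, "params", p)
        if kind == "uniform":
            if len(p) != 2 or not (0 < p[0] < p[1]):
                raise ValueError("uniform needs 0 < lo < hi")
        elif kind == "uniform_grid":
            vals = np.asarray(p, dtype=float)
            if vals.size == 0 or np.any(vals <= 0):
                raise ValueError("uniform_grid needs positive values")
        elif kind == "poisson_plus":
            if len(p) != 2 or p[0] < 0 or p[1] <= 0:
                raise ValueError("poisson_plus needs rate >= 0 and shift > 0")
        elif kind == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError("lognormal needs sigma > 0")
        elif kind == "constant":
            if len(p) != 1 or p[0] <= 0:
                raise ValueError("constant needs a positive value")
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        kind, p = self.kind, self.params
        if kind == "uniform":
            x = rng.uniform(p[0], p[1], size=n)
        elif kind == "uniform_grid":
            x = rng.choice(np.asarray(p, dtype=float), size=n)
        elif kind == "poisson_plus":
            x = rng.poisson(p[0], size=n).astype(float) + p[1]
        elif kind == "lognormal":
            x = rng.lognormal(p[0], p[1], size=n)
        else:  # constant
            x = np.full(n, float(p[0]))
        return np.maximum(x, COVARIATE_FLOOR)


def _default_covariate_specs(bin_size: int = DEFAULT_BIN_SIZE) -> dict[str, CovariateSpec]:
    return {
        "D": CovariateSpec("uniform_grid", tuple(bin_size * np.arange(1, 101))),
        "GC": CovariateSpec("uniform", (0.3, 0.7)),
        "TE": CovariateSpec("poisson_plus", (2.0, 1.0)),
        "ACC": CovariateSpec("lognormal", (0.0, 0.5)),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset (ground-truth parameters)."""

    n_pairs: int = 2500
    lattice_shape: tuple[int, int] = (50, 50)
    K: int = 2
    alphas: tuple = (0.7, 0.3)
    tau: float = 0.3
    betas: tuple = ((2.7, -0.2, 0.3, -0.2, -0.3), (7.0, -0.3, 0.4, 0.1, 0.2))
    gamma: float = 0.0
    covariate_specs: dict = field(default_factory=_default_covariate_specs)
    use_potts_labels: bool = False
    seed: int = 0
    potts_sweeps: int = 200  # Gibbs burn-in when sampling labels from the Potts field
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        r, c = self.lattice_shape
        if r < 1 or c < 1 or r * c < self.n_pairs:
            raise ValueError("lattice_shape product must cover n_pairs")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        alphas = np.asarray(self.alphas, dtype=float)
        if alphas.shape != (self.K,) or np.any(alphas < 0):
            raise ValueError("alphas must be K non-negative proportions")
        if abs(alphas.sum() - 1.0) > 1e-12:
            raise ValueError("alphas must sum to 1 within 1e-12")
        object.__setattr__(self, "alphas", tuple(float(a) for a in alphas))
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        betas = tuple(tuple(map(float, b)) for b in self.betas)
        if len(betas) != self.K or any(len(b) != 5 for b in betas):
            raise ValueError("betas must be K vectors of 5 coefficients")
        object.__setattr__(self, "betas", betas)
        specs = dict(self.covariate_specs)
        missing = set(COVARIATE_NAMES) - set(specs)
        if missing:
            raise ValueError(f"covariate_specs missing {sorted(missing)}")
        object.__setattr__(self, "covariate_specs", specs)

    @property
    def component_params(self) -> list[ComponentParams]:
        return [ComponentParams(np.asarray(b)) for b in self.betas]

    def lattice(self) -> PairLattice:
        """Lattice over the first ``n_pairs`` row-major sites of the grid."""
        r, c = self.lattice_shape
        mask = np.zeros(r * c, dtype=bool)
        mask[: self.n_pairs] = True
        return PairLattice(r, c, mask.reshape(r, c))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_specs"] = {
            k: {"kind": v.kind, "params": list(v.params)} for k, v in self.covariate_specs.items()
        }
        return d


@dataclass(frozen=True)
class SimulatedDataset:
    observations: Observations
    true_labels: np.ndarray
    true_params: SimulationConfig

    def __post_init__(self) -> None:
        if len(self.true_labels) != len(self.observations):
            raise ValueError("labels and observations differ in length")

    @property
    def lattice(self) -> PairLattice:
        return self.true_params.lattice()

    def empirical_alphas(self) -> np.ndarray:
        return np.bincount(self.true_labels, minlength=self.true_params.K + 1)[1:] / len(
            self.true_labels
        )


# ---------------------------------------------------------------------------
# presets: the simulation-study conditions
# ---------------------------------------------------------------------------

_K3_BETAS = (
    (2.7, -0.2, 0.3, -0.2, -0.3),   # noise, mean ~ 1
    (7.0, -0.3, 0.4, 0.1, 0.2),     # signal, mean ~ 30
    (9.8, -0.35, 0.3, 0.0, -0.1),   # false signal, mean ~ 300
)

PRESETS: dict[str, dict] = {
    # noise fraction above signal, the headline two-component design
    "noise-heavy": {},
    "equal": {"alphas": (0.5, 0.5)},
    "signal-heavy": {"alphas": (0.3, 0.7)},
    "three-component": {"K": 3, "alphas": (0.6, 0.3, 0.1), "betas": _K3_BETAS},
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A named simulation design; ``overrides`` replace individual fields."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def simulate_labels(config: SimulationConfig) -> np.ndarray:
    """Draw the ground-truth labels (1..K) for every site.

    With ``use_potts_labels`` the labels come from ``potts_sweeps`` Gibbs
    sweeps of the Potts field at ``gamma`` on the full lattice; otherwise
    they are i.i.d. multinomial(``alphas``).  Labels are generated on the
    full rectangle and the first ``n_pairs`` row-major sites are kept.
    """
    rng = _rng_for(config, 0)
    r, c = config.lattice_shape
    full = PairLattice(r, c)
    if config.use_potts_labels:
        z = simulate_potts_field(full, config.gamma, config.K, rng, config.potts_sweeps)
    else:
        z = rng.choice(np.arange(1, config.K + 1), size=r * c, p=np.asarray(config.alphas))
    return z[: config.n_pairs]


def simulate_observations(config: SimulationConfig, labels: np.ndarray) -> SimulatedDataset:
    """Draw covariates and counts given the labels.

    Component 1 emits ZIP(tau, lambda): with probability tau the count is an
    extra zero, otherwise Poisson(lambda).  Components k >= 2 emit
    Poisson(lambda^(k)).  Means follow the log-linear bias regression.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (config.n_pairs,):
        raise ValueError("labels were not drawn for this configuration")
    if labels.min() < 1 or labels.max() > config.K:
        raise ValueError("labels out of range 1..K")
    rng = _rng_for(config, 1)
    n = config.n_pairs
    covs = {name: config.covariate_specs[name].draw(n, rng) for name in COVARIATE_NAMES}
    lat = config.lattice()
    obs = Observations(
        i=lat.sites_rc[:, 0].astype(np.int64),
        j=lat.sites_rc[:, 1].astype(np.int64),
        y=np.zeros(n, dtype=np.int64),
        D=covs["D"], GC=covs["GC"], TE=covs["TE"], ACC=covs["ACC"],
    )
    lams = np.empty((n, config.K))
    for k, params in enumerate(config.component_params):
        try:
            lams[:, k] = component_mean(params, obs)
        except FloatingPointError as exc:
            raise FloatingPointError(f"component {k + 1}: {exc}") from exc
    lam_z = lams[np.arange(n), labels - 1]
    y = rng.poisson(lam_z)
    noise = labels == 1
    extra_zero = noise & (rng.random(n) < config.tau)
    y[extra_zero] = 0
    obs = replace(obs, y=y.astype(np.int64))
    return SimulatedDataset(observations=obs, true_labels=labels, true_params=config)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Labels + observations in one call (deterministic under ``config.seed``)."""
    return simulate_observations(config, simulate_labels(config))


# ---------------------------------------------------------------------------
# on-disk form (same triplet dialect the IO layer reads)
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
    """Write triplets, covariate table and ground truth as plain TSV.

    Returns the mapping of role -> path.  The triplet file is readable by
    :func:`hicmrf.io.read_contact_matrix`; the covariate table feeds the
    fitting CLI directly (synthetic covariates replace the FASTA/BED/
    bedGraph tracks of a real run).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = ds.observations
    paths = {
        "matrix": outdir / f"{prefix}.matrix.tsv",
        "covariates": outdir / f"{prefix}.covariates.tsv",
        "truth": outdir / f"{prefix}.truth.tsv",
    }
    pd.DataFrame({"i": obs.i, "j": obs.j, "y": obs.y}).to_csv(
        paths["matrix"], sep="\t", header=False, index=False
    )
    cov = obs.to_frame()
    cov.insert(0, "site", np.arange(len(obs)))
    cov.to_csv(paths["covariates"], sep="\t", index=False)
    pd.DataFrame(
        {"site": np.arange(len(obs)), "i": obs.i, "j": obs.j, "true_label": ds.true_labels}
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_covariate_table(path: str | Path) -> Observations:
    """Read back a covariate table written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t")
    return Observations.from_frame(df)
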