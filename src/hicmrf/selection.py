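"""Model selection, interaction calling and call characterization.

The number of mixture components K is chosen by a deviance information
criterion adapted to latent-variable models on the complete-data
likelihood:

    DIC = -4 E_{theta,z|y}[log f(y, z | theta)] + 2 log f(y, z_hat | theta_hat)

with the expectation averaged over retained draws (labels included) and the
plug-in term evaluated at the posterior-mean parameters and the per-site
modal labels.  The complete-data likelihood couples the component
emissions with the multinomial label-allocation term (empirical mixture
weights); dropping the allocation term rewards any split of the data and
makes larger K win spuriously.  Smaller is better.

Calls are made per bin pair from the posterior label frequencies after
role mapping; a pair is a significant interaction when its most probable
role is "signal" and that probability clears a threshold (default 0.5).
Characterization tallies significant calls by genomic-distance class,
TAD co-membership, and promoter/gene/other category of the two anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import Chain, MCMCConfig, PriorConfig, ROLE_NAMES, empirical_bayes_hyperpriors, label_components, run_mcmc
from .lattice import PairLattice
from .model import (
    ComponentParams,
    component_mean,
    emission_log_probs,
    label_allocation_log_prob,
)
from .observations import Observations

__all__ = [
    "InteractionCall",
    "CallCharacterization",
    "compute_dic",
    "select_K",
    "call_interactions",
    "characterize_calls",
]


@dataclass(frozen=True)
class InteractionCall:
    i: int
    j: int
    posterior_probs: np.ndarray  # role-mapped: (noise, signal[, false_signal])
    label: str
    significant: bool

    def __post_init__(self) -> None:
        p = np.asarray(self.posterior_probs, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")
        object.__setattr__(self, "posterior_probs", p)


@dataclass(frozen=True)
class CallCharacterization:
    distance_histogram: pd.DataFrame      # columns: low, high, count
    tad_partition: dict | None            # {"inside_tad": n, "outside_tad": n}
    promoter_partition: dict | None       # unordered category pair -> count


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def compute_dic(chain: Chain, obs: Observations, lattice: PairLattice) -> float:
    """Latent-variable DIC (complete likelihood, plug-in at posterior means)."""
    if chain.n_draws < 100:
        raise ValueError("need at least 100 retained draws for DIC")
    if len(obs) != lattice.n_sites:
        raise ValueError("observations do not match lattice")
    expectation = float(chain.complete_loglik.mean())
    beta_means = chain.beta_means()
    tau_hat = float(chain.tau.mean())
    lams = np.column_stack(
        [component_mean(ComponentParams(beta_means[k]), obs) for k in range(chain.K)]
    )
    log_emis = emission_log_probs(obs.y, tau_hat, lams)
    z_mode = np.argmax(chain.label_freq, axis=1)  # 0-based component index
    plug_in = float(log_emis[np.arange(len(obs)), z_mode].sum())
    plug_in += label_allocation_log_prob(z_mode + 1, chain.K)
    return -4.0 * expectation + 2.0 * plug_in


def select_K(
    obs: Observations,
    lattice: PairLattice,
    candidate_Ks: Sequence[int],
    prior,
    cfg: MCMCConfig,
    logger=None,
) -> tuple[int, pd.DataFrame, dict[int, Chain]]:
    """Fit each candidate K and pick the smallest-DIC model.

    ``prior`` may be a :class:`PriorConfig` (used when its K matches), the
    string ``"empirical_bayes"`` (per-K priors built from the data), or a
    mapping K -> PriorConfig.
    """
    candidate_Ks = list(candidate_Ks)
    if not candidate_Ks:
        raise ValueError("need at least one candidate K")
    rows = []
    chains: dict[int, Chain] = {}
    for K in candidate_Ks:
        if isinstance(prior, PriorConfig):
            if prior.K != K:
                raise ValueError(f"fixed prior has K={prior.K}, cannot fit K={K}")
            pk = prior
        elif isinstance(prior, dict):
            pk = prior[K]
        elif prior == "empirical_bayes":
            pk = empirical_bayes_hyperpriors(obs, K)
        else:
            raise TypeError("prior must be PriorConfig, dict or 'empirical_bayes'")
        chain = run_mcmc(obs, lattice, K, pk, cfg, logger=logger)
        chains[K] = chain
        rows.append({"K": K, "DIC": compute_dic(chain, obs, lattice)})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["DIC"].idxmin(), "K"])
    return best, table, chains


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_interactions(
    chain: Chain,
    obs: Observations,
    role_map: dict | None = None,
    threshold: float = 0.5,
) -> list[InteractionCall]:
    """Turn posterior label frequencies into per-pair calls.

    Posterior probabilities are reported in role order (noise, signal
    [, false_signal]); the label is the most probable role, ties broken
    toward the lower-mean role (conservative), and a call is significant
    when the label is "signal" with probability >= ``threshold``.
    """
    if role_map is None:
        role_map = label_components(chain, obs)
    order = role_map["order"]
    roles = ROLE_NAMES[chain.K]
    probs = chain.label_freq[:, order]  # columns now in role order
    calls = []
    signal_idx = roles.index("signal")
    for s in range(probs.shape[0]):
        p = probs[s]
        best = int(np.flatnonzero(p == p.max())[0])  # lowest-mean role wins ties
        label = roles[best]
        significant = label == "signal" and p[signal_idx] >= threshold
        calls.append(
            InteractionCall(
                i=int(obs.i[s]), j=int(obs.j[s]),
                posterior_probs=p, label=label, significant=bool(significant),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

def _bin_interval(idx: int, bin_size: int) -> tuple[int, int]:
    return idx * bin_size, (idx + 1) * bin_size


def _inside_common_tad(a: tuple[int, int], b: tuple[int, int], tads: Sequence[tuple[int, int]]) -> bool:
    for ts, te in tads:
        if a[0] >= ts and a[1] <= te and b[0] >= ts and b[1] <= te:
            return True
    return False


def _category(interval: tuple[int, int], promoters, genes) -> str:
    s, e = interval
    for ps, pe in promoters:
        if ps < e and s < pe:
            return "P"
    for gs, ge in genes:
        if gs < e and s < ge:
            return "G"
    return "O"


def characterize_calls(
    calls: Sequence[InteractionCall],
    bin_size: int,
    distance_breaks: Sequence[float],
    tads: Sequence[tuple[int, int]] | None = None,
    promoters: Sequence[tuple[int, int]] | None = None,
    genes: Sequence[tuple[int, int]] | None = None,
) -> CallCharacterization:
    """Summarize the significant calls.

    ``tads``, ``promoters`` and ``genes`` are (start, end) interval lists
    (0-based half-open, single chromosome); when absent the corresponding
    partition is skipped.  A call is inside a TAD iff both bins lie within
    one common TAD interval.  Anchor categories use precedence
    promoter > gene > other, and unordered category pairs are tallied.
    """
    sig = [c for c in calls if c.significant]
    dists = np.array(
        [abs(c.j - c.i) * bin_size for c in sig], dtype=float
    )
    breaks = np.asarray(distance_breaks, dtype=float)
    counts, _ = np.histogram(dists, bins=breaks)
    hist = pd.DataFrame({"low": breaks[:-1], "high": breaks[1:], "count": counts})

    tad_partition = None
    if tads is not None:
        inside = sum(
            _inside_common_tad(
                _bin_interval(c.i, bin_size), _bin_interval(c.j, bin_size), tads
            )
            for c in sig
        )
        tad_partition = {"inside_tad": int(inside), "outside_tad": len(sig) - int(inside)}

    promoter_partition = None
    if promoters is not None and genes is not None:
        tally: dict[str, int] = {}
        for c in sig:
            ca = _category(_bin_interval(c.i, bin_size), promoters, genes)
            cb = _category(_bin_interval(c.j, bin_size), promoters, genes)
            key = "".join(sorted((ca, cb)))
            tally[key] = tally.get(key, 0) + 1
        promoter_partition = tally

    return CallCharacterization(
        distance_histogram=hist,
        tad_partition=tad_partition,
        promoter_partition=promoter_partition,
    )
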