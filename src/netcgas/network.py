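"""Gaussian-graphical-model network estimation and covariate selection.

The trait network is either supplied (a curated biochemical network) or
estimated from the trait data as a Gaussian graphical model: nodes are
traits, and an edge joins two traits whose *full-order* partial correlation
(conditioning on all remaining m - 2 traits) is significant after a
Bonferroni-style correction over all m(m-1)/2 pairs.  Covariates for a
trait of interest are its direct network neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import TraitMatrix, TraitNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PartialCorrelationResult",
    "partial_correlation_matrix",
    "ggm_edges",
    "ggm_cutoff",
    "covariate_neighbors",
]


@dataclass
class PartialCorrelationResult:
    """Full-order partial correlations with two-sided p-values.

    ``pcor[i, j]`` is the correlation between traits i and j given all
    other traits, computed from the inverse of the trait correlation
    matrix; p-values come from the t-statistic
    r * sqrt((n - 2 - gp) / (1 - r^2)) on n - 2 - gp degrees of freedom,
    with gp = m - 2 conditioning variables.
    """

    trait_names: list[str]
    pcor: np.ndarray
    p: np.ndarray
    n: int
    n_conditioned: int

    def __post_init__(self) -> None:
        m = len(self.trait_names)
        assert self.pcor.shape == (m, m) and self.p.shape == (m, m)


def partial_correlation_matrix(traits: TraitMatrix) -> PartialCorrelationResult:
    """Estimate all full-order partial correlations among the traits.

    Rows with any missing value are dropped (one coherent sample for the
    whole matrix); requires n > m + 2 complete cases and traits in state
    ``adjusted_int`` or ``standardized``.
    """
    if traits.state == "raw":
        raise ValueError("partial correlations expect adjusted (adjusted_int/standardized) traits")
    m = traits.n_traits
    if m < 2:
        raise ValueError("need at least two traits")
    complete = np.isfinite(traits.values).all(axis=1)
    n = int(complete.sum())
    n_dropped = traits.n_samples - n
    if n_dropped:
        logger.info("partial correlations: dropped %d incomplete rows (%d remain)", n_dropped, n)
    if n <= m + 2:
        raise ValueError(f"need n > m + 2 complete cases (n={n}, m={m})")
    X = traits.values[complete]

    corr = np.corrcoef(X, rowvar=False)
    # guard against numerically singular correlation matrices up front
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or logdet < -700:
        raise np.linalg.LinAlgError(
            "trait correlation matrix is singular; regularized estimation is not supported"
        )
    omega = np.linalg.inv(corr)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)

    gp = m - 2
    df = n - 2 - gp
    r = pcor.copy()
    np.fill_diagonal(r, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r**2))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    pvals = np.where(np.abs(r) >= 1.0, 0.0, pvals)
    np.fill_diagonal(pvals, 0.0)
    return PartialCorrelationResult(
        trait_names=list(traits.trait_names), pcor=pcor, p=pvals, n=n, n_conditioned=gp
    )


def ggm_cutoff(m: int, alpha_total: float = 0.01) -> float:
    """Per-edge p-value cutoff: alpha_total spread over all m(m-1)/2 pairs."""
    if m < 2:
        raise ValueError("need at least two traits")
    return alpha_total / (m * (m - 1) / 2.0)


def ggm_edges(pc: PartialCorrelationResult, alpha_total: float = 0.01) -> TraitNetwork:
    """Build the GGM: edge {i, j} iff p_ij <= alpha_total / (m(m-1)/2).

    Edge weights are the partial correlations; the applied cutoff is stored
    in the network metadata.
    """
    m = len(pc.trait_names)
    cutoff = ggm_cutoff(m, alpha_total)
    net = TraitNetwork(nodes=pc.trait_names, meta={"cutoff": cutoff, "alpha_total": alpha_total, "n": pc.n})
    for i in range(m):
        for j in range(i + 1, m):
            if pc.p[i, j] <= cutoff:
                net.add_edge(pc.trait_names[i], pc.trait_names[j],
                             weight=float(pc.pcor[i, j]), p=float(pc.p[i, j]))
    return net


def covariate_neighbors(net: TraitNetwork, trait: str) -> list[str]:
    """Covariate set for a trait: its direct neighbors, sorted by name."""
    return net.neighbors(trait)
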