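"""Synthetic genotype/trait generator and power experiments.

The generator emulates the structure of a metabolomics GWAS cohort: one
causal biallelic SNP with binomial allele dosages at a given allele
frequency, a focal trait ``y`` and covariate traits ``c_1..c_k`` that all
may load on the standardized genotype, correlated Gaussian residuals, and
an accompanying trait network (star, chain, or custom).  Three named
scenarios reproduce the canonical pleiotropy regimes:

* ``concordant``   — genotype pushes trait and covariates the same way the
  residual correlation does (the ETFDH-like regime; conditioning loses
  power through the pleiotropic term);
* ``discordant``   — genetically induced and residual trait-covariate
  covariance have opposite signs (FADS1-like; conditioning always gains);
* ``mediation``    — the genotype affects ``y`` only through a covariate,
  so the conditional null is true and conditioning removes the signal.

:func:`power_experiment` estimates empirical rejection rates of the
univariate and conditional scans over replicates and also evaluates the
noise/pleiotropic components analytically at the population parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .association import cgas_scan, decompose_from_conditional, ugas_scan
from .datatypes import GenotypeMatrix, SNPRecord, TraitMatrix, TraitNetwork

__all__ = [
    "ScenarioSpec",
    "PowerResult",
    "simulate_dataset",
    "power_experiment",
    "expected_components",
    "population_correlations",
    "CAUSAL_SNP_ID",
]

CAUSAL_SNP_ID = "snp_causal"


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulation scenario.

    ``b_direct`` and ``b_cov[i]`` are effects per standardized genotype on
    ``y`` and on covariate ``c_i`` (before trait standardization);
    ``b_med[i]`` is the effect of covariate ``c_i`` on ``y`` (mediation
    paths).  ``residual_cor`` is the residual correlation matrix of
    (y, c_1..c_k), all residual variances 1.
    """

    n: int = 2000
    maf: float = 0.3
    b_direct: float = 0.0
    b_cov: tuple[float, ...] = ()
    b_med: tuple[float, ...] = ()
    residual_cor: tuple[tuple[float, ...], ...] | None = None
    network_shape: str = "star"  # star | chain | custom
    custom_edges: tuple[tuple[str, str], ...] = ()
    n_null_snps: int = 0
    seed: int = 0
    replicates: int = 500
    alpha: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.b_med and len(self.b_med) != len(self.b_cov):
            raise ValueError("b_med must have one entry per covariate")
        R = self.residual_matrix()
        if not np.allclose(R, R.T):
            raise ValueError("residual_cor must be symmetric")
        eigmin = float(np.linalg.eigvalsh(R).min())
        if eigmin <= 0:
            raise ValueError(f"residual_cor not positive definite (min eigenvalue {eigmin:.3e})")

    @property
    def k(self) -> int:
        return len(self.b_cov)

    def residual_matrix(self) -> np.ndarray:
        if self.residual_cor is None:
            return np.eye(self.k + 1)
        return np.asarray(self.residual_cor, dtype=float)

    def med_vector(self) -> np.ndarray:
        if not self.b_med:
            return np.zeros(self.k)
        return np.asarray(self.b_med, dtype=float)

    def trait_names(self) -> list[str]:
        return ["y"] + [f"c{i + 1}" for i in range(self.k)]


def discordant_scenario(**overrides) -> ScenarioSpec:
    """FADS1-like regime: genotype effects on y and c oppose a positive
    residual correlation, so the discordance condition holds and the
    conditional scan dominates."""
    base = dict(
        n=2000, maf=0.3, b_direct=0.15, b_cov=(-0.25,),
        residual_cor=((1.0, 0.6), (0.6, 1.0)),
        network_shape="star", alpha=1e-4, replicates=500,
    )
    base.update(overrides)
    return ScenarioSpec(**base)


def concordant_scenario(**overrides) -> ScenarioSpec:
    """ETFDH-like regime: genotype effects and residual correlation agree in
    sign; the pleiotropic term is negative and conditioning can lose power."""
    base = dict(
        n=2000, maf=0.3, b_direct=0.15, b_cov=(0.25,),
        residual_cor=((1.0, 0.6), (0.6, 1.0)),
        network_shape="star", alpha=1e-4, replicates=500,
    )
    base.update(overrides)
    return ScenarioSpec(**base)


def mediation_scenario(**overrides) -> ScenarioSpec:
    """Genotype affects y only through the covariate (conditional null true)."""
    base = dict(
        n=2000, maf=0.3, b_direct=0.0, b_cov=(0.4,), b_med=(0.5,),
        network_shape="star", alpha=1e-4, replicates=500,
    )
    base.update(overrides)
    return ScenarioSpec(**base)


def null_scenario(**overrides) -> ScenarioSpec:
    """All genetic effects zero; both scans test a true null."""
    base = dict(
        n=2000, maf=0.3, b_direct=0.0, b_cov=(0.0,),
        network_shape="star", alpha=0.05, replicates=1000,
    )
    base.update(overrides)
    return ScenarioSpec(**base)


NAMED_SCENARIOS = {
    "discordant": discordant_scenario,
    "concordant": concordant_scenario,
    "mediation": mediation_scenario,
    "null": null_scenario,
}


# ---------------------------------------------------------------------------
# data generation


def _network_for(spec: ScenarioSpec) -> TraitNetwork:
    names = spec.trait_names()
    net = TraitNetwork(nodes=names)
    if spec.network_shape == "star":
        for c in names[1:]:
            net.add_edge("y", c)
    elif spec.network_shape == "chain":
        for a, b in zip(names, names[1:]):
            net.add_edge(a, b)
    elif spec.network_shape == "custom":
        for a, b in spec.custom_edges:
            net.add_edge(a, b)
    else:
        raise ValueError(f"unknown network shape {spec.network_shape!r}")
    return net


def simulate_dataset(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, TraitMatrix, TraitNetwork]:
    """Draw one dataset: causal + null genotypes, traits, and the network.

    g ~ Binomial(2, maf); traits are built on the standardized genotype
    g* = (g - 2 maf) / sqrt(2 maf (1 - maf)) as
    c_i = b_cov[i] g* + eps_i  and  y = b_direct g* + sum_i b_med[i] c_i + eps_y,
    with (eps_y, eps) ~ N(0, residual_cor), then standardized to sample
    mean 0 / variance 1.  Null SNPs are independent of all traits.
    Fully reproducible from ``spec.seed`` when ``rng`` is not given.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, k = spec.n, spec.k
    sd_g = math.sqrt(2.0 * spec.maf * (1.0 - spec.maf))

    g = rng.binomial(2, spec.maf, size=n).astype(float)
    g_std = (g - 2.0 * spec.maf) / sd_g
    L = np.linalg.cholesky(spec.residual_matrix())
    eps = rng.standard_normal(size=(n, k + 1)) @ L.T  # col 0: eps_y
    b_cov = np.asarray(spec.b_cov, dtype=float)
    b_med = spec.med_vector()
    C = g_std[:, None] * b_cov[None, :] + eps[:, 1:]
    y = spec.b_direct * g_std + C @ b_med + eps[:, 0]

    values = np.column_stack([y, C]) if k else y[:, None]
    tm = TraitMatrix([f"s{i:05d}" for i in range(n)], spec.trait_names(), values).standardized()

    snps = [
        SNPRecord(id=CAUSAL_SNP_ID, chr="1", pos=1_000_000,
                  effect_allele="A", other_allele="G", eaf=float(g.mean() / 2.0))
    ]
    cols = [g]
    for j in range(spec.n_null_snps):
        gj = rng.binomial(2, spec.maf, size=n).astype(float)
        snps.append(
            SNPRecord(id=f"snp_null_{j:04d}", chr="2", pos=1_000_000 + j * 1_000_000,
                      effect_allele="A", other_allele="G", eaf=float(gj.mean() / 2.0))
        )
        cols.append(gj)
    gm = GenotypeMatrix(tm.sample_ids, snps, np.column_stack(cols))
    return gm, tm, _network_for(spec)


# ---------------------------------------------------------------------------
# population (analytic) quantities


def population_correlations(spec: ScenarioSpec) -> dict:
    """Exact population correlations among (y, c_1..c_k, g*).

    Built from the linear structural equations of the generator; with unit
    residual variances, cov(c) = B B' + R_cc etc.  Keys: rho_yg, rho_gi,
    corr (full correlation matrix over y, covariates, g).
    """
    k = spec.k
    b_cov = np.asarray(spec.b_cov, dtype=float)
    b_med = spec.med_vector()
    R = spec.residual_matrix()
    # x = A u with u = (g*, eps_y, eps_1..eps_k), cov(u) = diag(1) + R block
    dim = k + 2
    S = np.zeros((dim, dim))
    S[0, 0] = 1.0
    S[1:, 1:] = R
    A = np.zeros((k + 2, dim))  # rows: y, c_1..c_k, g
    for i in range(k):  # c_i = b_cov_i g + eps_i
        A[1 + i, 0] = b_cov[i]
        A[1 + i, 2 + i] = 1.0
    A[0, 0] = spec.b_direct + float(b_med @ b_cov)  # y on g
    A[0, 1] = 1.0  # eps_y
    A[0, 2:] = b_med  # eps_i through mediation
    A[k + 1, 0] = 1.0  # g itself
    cov = A @ S @ A.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    return {
        "rho_yg": float(corr[0, k + 1]),
        "rho_gi": tuple(float(corr[1 + i, k + 1]) for i in range(k)),
        "rho_yc": tuple(float(corr[0, 1 + i]) for i in range(k)),
        "corr": corr,
    }


def expected_components(spec: ScenarioSpec) -> tuple[float, float]:
    """Noise and pleiotropic components evaluated at population parameters.

    Solves the population conditional model on the correlation scale
    (beta = P^{-1} s) and plugs the exact correlations into the two terms of
    the decomposition.  Returns (nan, nan) when rho_yg = 0 (degenerate).
    """
    pop = population_correlations(spec)
    k = spec.k
    corr = pop["corr"]
    rho_yg = pop["rho_yg"]
    if abs(rho_yg) < 1e-12:
        return (math.nan, math.nan)
    idx_c = list(range(1, k + 1))
    P = np.empty((k + 1, k + 1))
    P[0, 0] = 1.0
    P[0, 1:] = [corr[i, k + 1] for i in idx_c]
    P[1:, 0] = P[0, 1:]
    P[1:, 1:] = corr[np.ix_(idx_c, idx_c)]
    s = np.concatenate([[rho_yg], [corr[0, i] for i in idx_c]])
    beta = np.linalg.solve(P, s)
    sigma_c2 = float(1.0 - s @ beta)
    sigma_u2 = 1.0 - rho_yg**2
    noise = math.log10(sigma_u2 / sigma_c2)
    bracket = 1.0 - float(beta[1:] @ np.asarray(pop["rho_gi"])) / rho_yg
    pleiotropic = math.log10(bracket * bracket) if bracket != 0 else -math.inf
    return (noise, pleiotropic)


# ---------------------------------------------------------------------------
# power experiments


@dataclass
class PowerResult:
    """Empirical power of the two scans plus the analytic decomposition.

    ``power_ugas``/``power_cgas`` are rejection fractions of the causal SNP
    at ``alpha``; ``mc_se`` are their binomial Monte Carlo standard errors.
    """

    scenario: ScenarioSpec
    power_ugas: float
    power_cgas: float
    mean_chi2_ugas: float
    mean_chi2_cgas: float
    mc_se_ugas: float
    mc_se_cgas: float
    expected_noise: float
    expected_pleiotropic: float
    replicate_chi2: np.ndarray = field(repr=False, default=None)  # (replicates, 2)
    replicate_discordant: np.ndarray = field(repr=False, default=None)


def power_experiment(spec: ScenarioSpec) -> PowerResult:
    """Estimate rejection rates of uGAS and cGAS over seeded replicates.

    Each replicate draws a fresh dataset from an independent substream of
    the master seed, scans the causal SNP with both models (covariates =
    network neighbors of y) and tests at ``spec.alpha``.  Per-replicate
    statistics and the estimated discordance indicator
    (sum_i beta_i rho_gi / rho_yg < 0) are kept for property checks.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    chi2 = np.empty((spec.replicates, 2))
    discordant = np.zeros(spec.replicates, dtype=bool)
    one = replace(spec, n_null_snps=0)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        gm, tm, net = simulate_dataset(one, rng=rng)
        [u] = ugas_scan(tm, gm, trait_names=["y"])
        [c] = cgas_scan(tm, gm, net, trait_names=["y"])
        chi2[r] = (u.chi2, c.chi2)
        if abs(c.rho_yg) >= 1e-8 and c.covariate_betas:
            term = sum(b * g for b, g in zip(c.covariate_betas, c.rho_gi)) / c.rho_yg
            discordant[r] = term < 0
    crit = stats.chi2.isf(spec.alpha, df=1)
    rej = chi2 > crit
    p_u, p_c = rej.mean(axis=0)
    mc = lambda p: math.sqrt(p * (1 - p) / spec.replicates)
    noise, pleio = expected_components(spec)
    return PowerResult(
        scenario=spec,
        power_ugas=float(p_u), power_cgas=float(p_c),
        mean_chi2_ugas=float(chi2[:, 0].mean()), mean_chi2_cgas=float(chi2[:, 1].mean()),
        mc_se_ugas=mc(p_u), mc_se_cgas=mc(p_c),
        expected_noise=noise, expected_pleiotropic=pleio,
        replicate_chi2=chi2, replicate_discordant=discordant,
    )
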