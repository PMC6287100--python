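"""Core in-memory containers for the conditional association pipeline.

The pipeline operates on four kinds of objects: genotype dosages
(:class:`GenotypeMatrix`), quantitative traits (:class:`TraitMatrix`),
an undirected trait network (:class:`TraitNetwork`, a thin wrapper around
:class:`networkx.Graph`), and tables of univariate summary statistics
(:class:`SummaryStatsTable`) with their companion trait correlation matrix
(:class:`TraitCorrelations`).  Association results are carried as flat
records (:class:`AssociationRecord`, :class:`DecompositionRecord`,
:class:`Locus`).

Missing values are represented as ``numpy.nan`` throughout; identifiers are
plain strings.  All containers validate their invariants at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SNPRecord",
    "GenotypeMatrix",
    "TraitMatrix",
    "TraitNetwork",
    "SummaryStatsTable",
    "TraitCorrelations",
    "AssociationRecord",
    "DecompositionRecord",
    "Locus",
]


@dataclass(frozen=True)
class SNPRecord:
    """Per-SNP metadata.

    ``eaf`` is the effect-allele frequency; the effect allele is the ALT
    allele of the source VCF (or the ``effA`` column of a dosage table).
    QC metrics that are unknown are ``None`` and pass the corresponding
    filter untouched.
    """

    id: str
    chr: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None = None
    call_rate: float | None = None
    imputation_r2: float | None = None
    hwe_p: float | None = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"SNP {self.id}: position must be positive, got {self.pos}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            # monomorphic markers are representable but flagged downstream
            if not (0.0 <= self.eaf <= 1.0):
                raise ValueError(f"SNP {self.id}: eaf {self.eaf} outside [0, 1]")


class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix.

    Dosages count copies of the effect allele, so values lie in [0, 2]
    (``nan`` marks a missing call).  Column order of ``dosages`` follows
    ``snps``.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        snps: Sequence[SNPRecord],
        dosages: np.ndarray,
    ) -> None:
        sample_ids = list(sample_ids)
        snps = list(snps)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(sample_ids), len(snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} != "
                f"({len(sample_ids)} samples, {len(snps)} snps)"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in genotype matrix")
        ids = [s.id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in genotype matrix")
        finite = dosages[np.isfinite(dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")
        self.sample_ids = sample_ids
        self.snps = snps
        self.dosages = dosages

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    def with_eaf_from_dosages(self) -> "GenotypeMatrix":
        """Fill in missing ``eaf`` values as mean(dosage)/2 per SNP."""
        new_snps = []
        for j, rec in enumerate(self.snps):
            if rec.eaf is None:
                col = self.dosages[:, j]
                col = col[np.isfinite(col)]
                eaf = float(col.mean() / 2.0) if col.size else None
                rec = replace(rec, eaf=eaf)
            new_snps.append(rec)
        return GenotypeMatrix(self.sample_ids, new_snps, self.dosages)

    def subset_snps(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            self.sample_ids,
            [self.snps[j] for j in keep],
            self.dosages[:, keep],
        )


VALID_TRAIT_STATES = ("raw", "adjusted_int", "standardized")


class TraitMatrix:
    """Samples x traits matrix with a preprocessing-state tag.

    ``state`` tracks where the matrix sits in the adjustment pipeline:
    ``raw`` -> (residualize on nuisance covariates) -> inverse-normal
    transform -> ``adjusted_int`` -> z-scoring -> ``standardized``.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        trait_names: Sequence[str],
        values: np.ndarray,
        state: str = "raw",
    ) -> None:
        sample_ids = list(sample_ids)
        trait_names = list(trait_names)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sample_ids), len(trait_names)):
            raise ValueError(
                f"trait value shape {values.shape} != "
                f"({len(sample_ids)}, {len(trait_names)})"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in trait matrix")
        if len(set(trait_names)) != len(trait_names):
            raise ValueError("duplicate trait names in trait matrix")
        if state not in VALID_TRAIT_STATES:
            raise ValueError(f"unknown trait state {state!r}")
        self.sample_ids = sample_ids
        self.trait_names = trait_names
        self.values = values
        self.state = state

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def trait_index(self, name: str) -> int:
        try:
            return self.trait_names.index(name)
        except ValueError:
            raise KeyError(f"unknown trait {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.trait_names)

    def standardized(self) -> "TraitMatrix":
        """Z-score each trait over its non-missing values (ddof=0)."""
        out = self.values.copy()
        for j in range(out.shape[1]):
            col = out[:, j]
            mask = np.isfinite(col)
            mu = col[mask].mean()
            sd = col[mask].std(ddof=0)
            if sd == 0:
                raise ValueError(f"trait {self.trait_names[j]!r} is constant")
            out[mask, j] = (col[mask] - mu) / sd
        return TraitMatrix(self.sample_ids, self.trait_names, out, state="standardized")


class TraitNetwork:
    """Undirected network over trait names (no self-loops).

    Backed by :class:`networkx.Graph`; edges may carry ``weight``
    (partial correlation) and ``p`` attributes.  ``meta`` records
    provenance such as the per-edge p-value cutoff used to build a GGM.
    """

    def __init__(self, nodes: Iterable[str] = (), meta: dict | None = None) -> None:
        self.graph = nx.Graph()
        self.graph.add_nodes_from(nodes)
        self.meta = dict(meta or {})

    def add_edge(self, a: str, b: str, weight: float | None = None, p: float | None = None) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        attrs = {}
        if weight is not None:
            attrs["weight"] = float(weight)
        if p is not None:
            attrs["p"] = float(p)
        self.graph.add_edge(a, b, **attrs)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def neighbors(self, trait: str) -> list[str]:
        if trait not in self.graph:
            raise KeyError(f"trait {trait!r} not in network")
        return sorted(self.graph.neighbors(trait))

    def __contains__(self, trait: str) -> bool:
        return trait in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


SUMMARY_COLUMNS = [
    "snp_id", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "trait_name", "beta", "se", "n",
]


class SummaryStatsTable:
    """Per-(SNP, trait) univariate association summaries.

    ``beta`` is the per-allele effect on the standardized trait, ``se`` its
    (dof-adjusted) standard error, and ``n`` the sample count, so that the
    sample correlation is recoverable as z/sqrt(n - 2 + z^2) with
    z = beta/se.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"summary-stats table missing columns: {missing}")
        frame = frame[SUMMARY_COLUMNS].copy()
        if (frame["se"] <= 0).any():
            raise ValueError("summary-stats rows with se <= 0 must be dropped before construction")
        if (frame["n"] < 3).any():
            raise ValueError("summary-stats rows require n >= 3")
        if frame.duplicated(["snp_id", "trait_name"]).any():
            raise ValueError("duplicate (snp_id, trait_name) rows in summary stats")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, snp_id: str, trait_name: str) -> pd.Series:
        sel = self.frame[
            (self.frame["snp_id"] == snp_id) & (self.frame["trait_name"] == trait_name)
        ]
        if sel.empty:
            raise KeyError(f"no summary row for SNP {snp_id!r}, trait {trait_name!r}")
        return sel.iloc[0]


class TraitCorrelations:
    """Pairwise Pearson correlations among traits, with the sample count used."""

    def __init__(self, trait_names: Sequence[str], matrix: np.ndarray, n_effective: int) -> None:
        trait_names = list(trait_names)
        matrix = np.asarray(matrix, dtype=float)
        m = len(trait_names)
        if matrix.shape != (m, m):
            raise ValueError(f"correlation matrix shape {matrix.shape} != ({m}, {m})")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(matrix), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal not 1")
        if np.abs(matrix).max() > 1 + 1e-9:
            raise ValueError("correlation entries outside [-1, 1]")
        if np.linalg.eigvalsh(matrix).min() < -1e-8:
            raise ValueError("correlation matrix not positive semi-definite")
        self.trait_names = trait_names
        self.matrix = matrix
        self.n_effective = int(n_effective)

    def submatrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.trait_names.index(t) for t in names]
        return self.matrix[np.ix_(idx, idx)]

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.trait_names.index(a), self.trait_names.index(b)])


@dataclass
class AssociationRecord:
    """One (SNP, trait, model) association fit.

    ``beta``/``se`` are on the per-allele (raw dosage) scale; ``beta_std``/
    ``se_std`` are on the standardized-genotype scale used by the
    noise/pleiotropy decomposition.  ``sigma2`` is the residual variance of
    the standardized trait under the RSS/n convention, so that
    ``chi2 = n * beta_std**2 / sigma2 = (beta/se)**2``.
    """

    snp_id: str
    trait: str
    model: str  # "uGAS" or "cGAS"
    n: int
    beta: float
    se: float
    sigma2: float
    chi2: float
    p: float
    chr: str = ""
    pos: int = 0
    effect_allele: str = ""
    other_allele: str = ""
    eaf: float | None = None
    covariates: tuple[str, ...] = ()
    covariate_betas: tuple[float, ...] = ()
    dropped_covariates: tuple[str, ...] = ()
    p_gc: float | None = None
    beta_std: float | None = None
    se_std: float | None = None
    rho_yg: float | None = None
    rho_gi: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in ("uGAS", "cGAS"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.se <= 0 or self.sigma2 <= 0:
            raise ValueError(f"{self.snp_id}/{self.trait}: se and sigma2 must be positive")
        rel = abs(self.chi2 - (self.beta / self.se) ** 2) / max(self.chi2, 1e-300)
        if self.chi2 > 1e-12 and rel > 1e-9:
            raise ValueError(f"{self.snp_id}/{self.trait}: chi2 inconsistent with (beta/se)^2")

    @property
    def n_cov(self) -> int:
        return len(self.covariates)

    @property
    def p_best(self) -> float:
        """GC-corrected p-value when available, else the raw one."""
        return self.p if self.p_gc is None else self.p_gc


@dataclass
class DecompositionRecord:
    """Noise and pleiotropic components of log10(T_c^2 / T_u^2) for one pair.

    When not degenerate, ``noise + pleiotropic == total`` to 1e-9 and
    ``noise >= 0`` (adding regressors cannot increase the RSS).
    ``rho_star`` holds the genetically induced correlation ratios
    rho_gi / rho_yg, one per covariate.
    """

    snp_id: str
    trait: str
    noise: float
    pleiotropic: float
    total: float
    rho_yg: float
    rho_star: tuple[float, ...] = ()
    degenerate: bool = False


@dataclass
class Locus:
    """Cluster of genome-wide significant hits on one chromosome.

    Successive member positions are less than the clustering window apart;
    ``best`` is the member with the smallest p-value (ties: smaller
    position, then trait name).
    """

    chr: str
    start: int
    end: int
    members: list = field(default_factory=list)

    @property
    def best(self) -> AssociationRecord:
        return min(self.members, key=lambda r: (r.p_best, r.pos, r.trait))
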