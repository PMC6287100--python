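"""Trait adjustment and SNP quality control.

Traits are prepared for association scanning in two steps, in this order:

1. :func:`residualize` — replace each trait by its least-squares residual
   on the nuisance covariates (sex, age, batch, ...), removing known
   non-genetic structure;
2. :func:`inverse_normal_transform` — map each residual trait onto
   standard-normal quantiles by rank, so downstream Wald tests see a
   Gaussian-looking, outlier-free trait.

SNPs are filtered by :func:`snp_qc` on call rate, imputation quality,
Hardy-Weinberg equilibrium and minor-allele frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GenotypeMatrix, TraitMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "residualize",
    "inverse_normal_transform",
    "snp_qc",
    "hwe_chi2_test",
]


@dataclass(frozen=True)
class QcThresholds:
    """SNP inclusion thresholds.

    Defaults: call rate >= 0.95, imputation R^2 >= 0.3, HWE p >= 1e-6,
    MAF >= 0.01.  A metric that is absent for a SNP does not exclude it.
    """

    min_call_rate: float = 0.95
    min_imputation_r2: float = 0.3
    min_hwe_p: float = 1e-6
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.min_call_rate <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("call-rate in [0,1] and MAF threshold in [0,0.5] required")
        if not (0 <= self.min_hwe_p <= 1 and 0 <= self.min_imputation_r2 <= 1):
            raise ValueError("HWE p and imputation R^2 thresholds must lie in [0,1]")


def _encode_nuisance(nuisance: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical nuisance columns (reference level dropped)."""
    parts = []
    for col in nuisance.columns:
        s = nuisance[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique(dropna=True) > 2:
            parts.append(s.astype(float).rename(col))
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def residualize(traits: TraitMatrix, nuisance: pd.DataFrame) -> TraitMatrix:
    """Replace each trait by its OLS residual on intercept + nuisance columns.

    ``nuisance`` is indexed by sample_id; rows are aligned to the trait
    matrix by id.  Per trait, complete cases (trait and all nuisance values
    present) are fitted; samples with missing nuisance values keep a missing
    trait value.  Collinear design columns are dropped with a warning.
    """
    design_full = _encode_nuisance(nuisance).reindex(traits.sample_ids)
    X_all = sm.add_constant(design_full, has_constant="add")

    out = np.full_like(traits.values, np.nan)
    for j, name in enumerate(traits.trait_names):
        y = traits.values[:, j]
        mask = np.isfinite(y) & X_all.notna().all(axis=1).to_numpy()
        if mask.sum() < X_all.shape[1] + 1:
            raise ValueError(f"trait {name!r}: too few complete cases to residualize")
        X = X_all.to_numpy(dtype=float)[mask]
        keep = _independent_columns(X)
        if len(keep) < X.shape[1]:
            dropped = [X_all.columns[k] for k in range(X.shape[1]) if k not in keep]
            warnings.warn(f"trait {name!r}: dropping collinear nuisance columns {dropped}")
            X = X[:, keep]
        fit = sm.OLS(y[mask], X).fit()
        out[mask, j] = fit.resid
    return TraitMatrix(traits.sample_ids, traits.trait_names, out, state=traits.state)


def _independent_columns(X: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Indices of a maximal linearly independent column subset (greedy QR)."""
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for k in range(X.shape[1]):
        cand = np.column_stack([basis, X[:, k]])
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(X).max())) > basis.shape[1]:
            keep.append(k)
            basis = cand
    return keep


def inverse_normal_transform(traits: TraitMatrix, offset: float = 0.5) -> TraitMatrix:
    """Rank-based inverse-normal transform, per trait.

    Each non-missing value becomes ``Phi^{-1}((rank - offset) / m)`` over the
    ``m`` non-missing values of its trait; ties receive the average rank.
    ``offset`` 0.5 is the default; 3/8 gives a Blom-style variant.
    """
    out = traits.values.copy()
    for j, name in enumerate(traits.trait_names):
        col = out[:, j]
        mask = np.isfinite(col)
        m = int(mask.sum())
        if m < 3:
            raise ValueError(f"trait {name!r}: need >= 3 non-missing values for INT")
        vals = col[mask]
        if np.all(vals == vals[0]):
            raise ValueError(f"trait {name!r}: constant trait cannot be inverse-normal transformed")
        ranks = stats.rankdata(vals, method="average")
        out[mask, j] = stats.norm.ppf((ranks - offset) / m)
    return TraitMatrix(traits.sample_ids, traits.trait_names, out, state="adjusted_int")


def hwe_chi2_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    ``n_aa``/``n_ab``/``n_bb`` are hard-genotype counts (aa = zero effect
    alleles).  Returns 1.0 for monomorphic counts (no df to test).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_bb + n_ab) / (2.0 * n)  # effect-allele frequency
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class QcReport:
    """Per-criterion exclusion counts and the surviving SNP count."""

    n_in: int
    n_out: int
    failed: dict[str, list[str]]  # criterion -> SNP ids that failed it
    hwe_skipped: list[str]  # SNPs whose dosages were too far from integers

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.failed.items()}


def snp_qc(gm: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs on call rate, imputation R^2, HWE and MAF.

    Call rate and MAF are recomputed from the dosages; HWE is tested on
    hard genotypes obtained by rounding dosages when every non-missing
    dosage is within 0.1 of an integer (imputed, fractional dosages carry
    no genotype counts, so HWE is skipped for them with a warning).
    Stored metrics (``call_rate``, ``imputation_r2``, ``hwe_p``) take
    precedence over recomputed ones; absent metrics pass.
    """
    failed: dict[str, list[str]] = {
        "call_rate": [], "imputation_r2": [], "hwe_p": [], "maf": [],
    }
    hwe_skipped: list[str] = []
    keep: list[int] = []
    for j, snp in enumerate(gm.snps):
        col = gm.dosages[:, j]
        present = np.isfinite(col)
        ok = True

        call_rate = snp.call_rate if snp.call_rate is not None else present.mean()
        if call_rate < thresholds.min_call_rate:
            failed["call_rate"].append(snp.id)
            ok = False

        if snp.imputation_r2 is not None and snp.imputation_r2 < thresholds.min_imputation_r2:
            failed["imputation_r2"].append(snp.id)
            ok = False

        hwe_p = snp.hwe_p
        if hwe_p is None and present.any():
            vals = col[present]
            rounded = np.round(vals)
            if np.abs(vals - rounded).max() <= 0.1:
                counts = [int((rounded == k).sum()) for k in (0, 1, 2)]
                hwe_p = hwe_chi2_test(*counts)
            else:
                hwe_skipped.append(snp.id)
        if hwe_p is not None and hwe_p < thresholds.min_hwe_p:
            failed["hwe_p"].append(snp.id)
            ok = False

        eaf = snp.eaf if snp.eaf is not None else (col[present].mean() / 2 if present.any() else None)
        if eaf is not None:
            maf = min(eaf, 1 - eaf)
            if maf < thresholds.min_maf:
                failed["maf"].append(snp.id)
                ok = False

        if ok:
            keep.append(j)

    if hwe_skipped:
        logger.warning("HWE skipped for %d SNPs with fractional dosages", len(hwe_skipped))
    report = QcReport(n_in=gm.n_snps, n_out=len(keep), failed=failed, hwe_skipped=hwe_skipped)
    if not keep:
        logger.warning("snp_qc removed every SNP (%d in)", gm.n_snps)
    return gm.subset_snps(keep), report
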