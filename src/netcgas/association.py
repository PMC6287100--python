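"""Univariate and conditional Wald association scans with the
noise/pleiotropy decomposition of their test-statistic ratio.

The model is the linear regression ``y = mu + beta_g * g + sum_i beta_i * c_i + e``
for a standardized trait ``y``, allele dosage ``g`` and standardized covariate
traits ``c_i`` chosen from a trait network.  With the residual-variance
convention ``sigma^2 = RSS / n`` the test statistics are

    T_u^2 = n * rho_yg^2 / sigma_u^2          (univariate, uGAS)
    T_c^2 = n * beta_g_std^2 / sigma_c^2      (conditional, cGAS)

where ``beta_g_std`` is the genotype coefficient on the standardized-genotype
scale.  Their log10 ratio splits exactly into a "noise" term
log10(sigma_u^2 / sigma_c^2) >= 0 and a "pleiotropic" term
log10([1 - (1/rho_yg) * sum_i beta_i * rho_gi]^2), whose sign is governed by
the interplay of the genetically induced and residual trait-covariate
covariance.  The same conditional fit is reproducible from univariate
summary statistics plus a trait correlation matrix
(:func:`cgas_from_summary`).

Reported effect sizes are per allele (raw dosage scale), as is conventional
for association tables; the decomposition quantities use the
standardized-genotype scale internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AssociationRecord,
    DecompositionRecord,
    GenotypeMatrix,
    Locus,
    SummaryStatsTable,
    TraitCorrelations,
    TraitMatrix,
    TraitNetwork,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ugas_scan",
    "cgas_scan",
    "correlation_from_z",
    "records_to_summary_stats",
    "trait_correlations",
    "cgas_from_summary",
    "genomic_control",
    "decompose_log_ratio",
    "decompose_from_conditional",
    "decompose_records",
    "significance_threshold",
    "define_loci",
    "association_profile",
    "compare_scans",
    "chi2_from_p",
    "p_from_chi2",
    "MEDIAN_CHI2_1DF",
]

# median of the 1-df chi-square distribution, used by genomic control
MEDIAN_CHI2_1DF = float(stats.chi2.ppf(0.5, df=1))

_RHO_EPS = 1e-8  # |rho_yg| below this makes the decomposition degenerate


def p_from_chi2(chi2: float | np.ndarray) -> float | np.ndarray:
    """Two-sided p-value of a 1-df chi-square statistic (accurate far tails)."""
    return stats.chi2.sf(chi2, df=1)


def chi2_from_p(p: float | np.ndarray) -> float | np.ndarray:
    """1-df chi-square quantile for an upper-tail p (inverse of p_from_chi2)."""
    return stats.chi2.isf(p, df=1)


def significance_threshold(n_traits: int, base: float = 5e-8) -> float:
    """Genome-wide threshold Bonferroni-corrected over the tested traits."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return base / n_traits


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = x.mean()
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    return (x - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# individual-level scans


def _fit_pair(
    y: np.ndarray,
    g: np.ndarray,
    C: np.ndarray | None,
    se_mode: str,
) -> dict:
    """Fit standardized y on dosage g (+ standardized covariate columns C).

    Returns per-allele and standardized-scale coefficients, residual
    variance (RSS/n), the test statistic and the correlations needed by the
    decomposition.  Inputs must be complete (no missing values); y and the
    columns of C must already be standardized over this sample.
    """
    n = y.size
    sd_g = g.std(ddof=0)
    if sd_g == 0:
        raise ValueError("monomorphic genotype in analyzed subsample")
    gc = g - g.mean()
    rho_yg = float(y @ gc / (n * sd_g))

    k = 0 if C is None else C.shape[1]
    if k == 0:
        beta_raw = float(y @ gc / (gc @ gc))
        resid = y - beta_raw * gc
        rss = float(resid @ resid)
        beta_cov = np.empty(0)
        rho_gi = np.empty(0)
        n_params = 2
    else:
        X = np.column_stack([np.ones(n), g, C])
        XtX = X.T @ X
        coefs = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ coefs
        rss = float(resid @ resid)
        beta_raw = float(coefs[1])
        beta_cov = coefs[2:]
        rho_gi = (gc / (n * sd_g)) @ C  # C columns are standardized
        n_params = 2 + k

    sigma2 = rss / n
    if sigma2 <= 0:
        raise ValueError("zero residual variance (saturated fit)")
    beta_std = beta_raw * sd_g
    if se_mode == "paper":
        se_std = math.sqrt(sigma2 / n)
        se_raw = se_std / sd_g
    elif se_mode == "ols":
        if k == 0:
            inv_gg = 1.0 / (gc @ gc)
        else:
            inv_gg = float(np.linalg.inv(XtX)[1, 1])
        s2 = rss / (n - n_params)
        se_raw = math.sqrt(s2 * inv_gg)
        se_std = se_raw * sd_g
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    chi2 = (beta_raw / se_raw) ** 2
    return {
        "n": n, "beta": beta_raw, "se": se_raw, "beta_std": beta_std, "se_std": se_std,
        "sigma2": sigma2, "chi2": chi2, "p": float(p_from_chi2(chi2)),
        "rho_yg": rho_yg, "rho_gi": tuple(float(r) for r in rho_gi),
        "covariate_betas": tuple(float(b) for b in beta_cov), "sd_g": sd_g,
    }


def _make_record(snp, trait: str, model: str, covariates: tuple[str, ...], fit: dict,
                 dropped: tuple[str, ...] = ()) -> AssociationRecord:
    return AssociationRecord(
        snp_id=snp.id, trait=trait, model=model, n=fit["n"],
        beta=fit["beta"], se=fit["se"], sigma2=fit["sigma2"],
        chi2=fit["chi2"], p=fit["p"],
        chr=snp.chr, pos=snp.pos,
        effect_allele=snp.effect_allele, other_allele=snp.other_allele, eaf=snp.eaf,
        covariates=covariates, covariate_betas=fit["covariate_betas"],
        dropped_covariates=dropped,
        beta_std=fit["beta_std"], se_std=fit["se_std"],
        rho_yg=fit["rho_yg"], rho_gi=fit["rho_gi"],
    )


def ugas_scan(
    traits: TraitMatrix,
    geno: GenotypeMatrix,
    trait_names: list[str] | None = None,
    se_mode: str = "paper",
) -> list[AssociationRecord]:
    """Univariate Wald scan of every (SNP, trait) pair.

    Complete cases per pair; the trait is standardized within the analyzed
    subsample.  Monomorphic SNPs (in the subsample) are skipped and counted.
    """
    records: list[AssociationRecord] = []
    names = trait_names if trait_names is not None else traits.trait_names
    n_skipped = 0
    for trait in names:
        y_all = traits.column(trait)
        for j, snp in enumerate(geno.snps):
            g_all = geno.dosages[:, j]
            mask = np.isfinite(y_all) & np.isfinite(g_all)
            if mask.sum() < 3:
                n_skipped += 1
                continue
            y, _, _ = _standardize(y_all[mask])
            try:
                fit = _fit_pair(y, g_all[mask], None, se_mode)
            except ValueError:
                n_skipped += 1
                continue
            records.append(_make_record(snp, trait, "uGAS", (), fit))
    if n_skipped:
        logger.info("ugas_scan: skipped %d monomorphic/degenerate pairs", n_skipped)
    return records


def cgas_scan(
    traits: TraitMatrix,
    geno: GenotypeMatrix,
    net: TraitNetwork,
    trait_names: list[str] | None = None,
    se_mode: str = "paper",
) -> list[AssociationRecord]:
    """Conditional Wald scan: each trait adjusted for its network neighbors.

    Covariates are the trait's direct neighbors in ``net`` (sorted), among
    the measured traits.  A trait with no usable covariates falls back to
    the univariate fit, tagged cGAS with n_cov = 0.  Covariates collinear
    with each other are dropped (recorded on the result); SNPs collinear
    with the covariate set are skipped.
    """
    records: list[AssociationRecord] = []
    names = trait_names if trait_names is not None else traits.trait_names
    n_skipped = 0
    for trait in names:
        covs = [c for c in (net.neighbors(trait) if trait in net else []) if c in traits.trait_names]
        y_all = traits.column(trait)
        C_all = (
            np.column_stack([traits.column(c) for c in covs]) if covs else None
        )
        for j, snp in enumerate(geno.snps):
            g_all = geno.dosages[:, j]
            mask = np.isfinite(y_all) & np.isfinite(g_all)
            if C_all is not None:
                mask &= np.isfinite(C_all).all(axis=1)
            if mask.sum() < len(covs) + 3:
                n_skipped += 1
                continue
            y, _, _ = _standardize(y_all[mask])
            use_covs = list(covs)
            dropped: tuple[str, ...] = ()
            C = None
            if use_covs:
                C = np.column_stack([_standardize(C_all[mask][:, i])[0] for i in range(len(covs))])
                keep = _independent_covariates(C)
                if len(keep) < len(use_covs):
                    dropped = tuple(c for i, c in enumerate(use_covs) if i not in keep)
                    logger.warning(
                        "cgas_scan: %s/%s dropping collinear covariates %s", snp.id, trait, dropped
                    )
                    use_covs = [use_covs[i] for i in keep]
                    C = C[:, keep] if keep else None
            try:
                fit = _fit_pair(y, g_all[mask], C if use_covs else None, se_mode)
            except (ValueError, np.linalg.LinAlgError):
                n_skipped += 1
                continue
            records.append(_make_record(snp, trait, "cGAS", tuple(use_covs), fit, dropped))
    if n_skipped:
        logger.info("cgas_scan: skipped %d degenerate pairs", n_skipped)
    return records


def _independent_covariates(C: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy selection of a linearly independent covariate subset."""
    keep: list[int] = []
    for i in range(C.shape[1]):
        cols = keep + [i]
        if np.linalg.matrix_rank(C[:, cols], tol=tol * C.shape[0]) == len(cols):
            keep.append(i)
    return keep


# ---------------------------------------------------------------------------
# summary-level path


def correlation_from_z(beta: float, se: float, n: int) -> float:
    """Recover the sample correlation from a univariate effect and SE.

    Uses the t-statistic identity rho = z / sqrt(n - 2 + z^2) with
    z = beta / se, valid when the SE follows the classical OLS convention
    (RSS / (n - 2)); sign-preserving.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if n <= 2:
        raise ValueError("need n >= 3")
    z = beta / se
    return float(z / math.sqrt(n - 2 + z * z))


def records_to_summary_stats(records: list[AssociationRecord]) -> SummaryStatsTable:
    """Export univariate records as a summary-statistics table.

    SEs are converted to the classical dof-adjusted convention
    (``se * sqrt(n / (n - 2))``) so that :func:`correlation_from_z` is the
    exact inverse of the fit.
    """
    rows = []
    for r in records:
        if r.model != "uGAS":
            raise ValueError("summary stats are built from uGAS records")
        rows.append(
            {
                "snp_id": r.snp_id, "chr": r.chr, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "trait_name": r.trait,
                "beta": r.beta, "se": r.se * math.sqrt(r.n / (r.n - 2)), "n": r.n,
            }
        )
    return SummaryStatsTable(pd.DataFrame(rows))


def trait_correlations(traits: TraitMatrix) -> TraitCorrelations:
    """Pairwise Pearson correlations over complete cases of the trait matrix."""
    complete = np.isfinite(traits.values).all(axis=1)
    X = traits.values[complete]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 complete rows for trait correlations")
    corr = np.atleast_2d(np.corrcoef(X, rowvar=False))
    return TraitCorrelations(traits.trait_names, corr, int(complete.sum()))


def cgas_from_summary(
    stats_table: SummaryStatsTable,
    R: TraitCorrelations,
    snp_id: str,
    trait: str,
    covariates: list[str],
    se_mode: str = "paper",
) -> AssociationRecord:
    """Conditional association of one SNP with one trait from summary data.

    Each univariate row (SNP vs target trait, SNP vs each covariate) is
    converted to a correlation; together with the trait correlation matrix
    this determines the conditional fit exactly: solve P beta = s where P is
    the predictor correlation matrix [[1, rho_g.], [rho_g., R_cc]] and
    s = (rho_yg, rho_yc.).  The per-allele effect divides the
    standardized-scale one by sd_g = sqrt(2 * eaf * (1 - eaf)).
    """
    target = stats_table.row(snp_id, trait)
    cov_rows = [stats_table.row(snp_id, c) for c in covariates]
    rho_yg = correlation_from_z(target["beta"], target["se"], int(target["n"]))
    rho_g = np.array(
        [correlation_from_z(r["beta"], r["se"], int(r["n"])) for r in cov_rows]
    )
    rho_yc = np.array([R.value(trait, c) for c in covariates])
    k = len(covariates)

    P = np.empty((k + 1, k + 1))
    P[0, 0] = 1.0
    P[0, 1:] = rho_g
    P[1:, 0] = rho_g
    P[1:, 1:] = R.submatrix(covariates) if k else np.empty((0, 0))
    eigmin = float(np.linalg.eigvalsh(P).min()) if k else 1.0
    if eigmin <= 0:
        raise ValueError(
            f"predictor correlation matrix not positive definite (min eigenvalue {eigmin:.3e}); "
            "summary inputs are mutually incompatible"
        )
    s = np.concatenate([[rho_yg], rho_yc])
    beta_vec = np.linalg.solve(P, s)
    sigma_c2 = float(1.0 - s @ beta_vec)
    if sigma_c2 <= 0:
        raise ValueError("implied conditional residual variance is not positive")

    n = int(min([target["n"]] + [r["n"] for r in cov_rows]))
    beta_std = float(beta_vec[0])
    if se_mode == "paper":
        se_std = math.sqrt(sigma_c2 / n)
    elif se_mode == "ols":
        pinv11 = float(np.linalg.inv(P)[0, 0])
        se_std = math.sqrt(sigma_c2 * n / (n - k - 2) * pinv11 / n)
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    chi2 = (beta_std / se_std) ** 2
    eaf = float(target["eaf"])
    sd_g = math.sqrt(2.0 * eaf * (1.0 - eaf))
    return AssociationRecord(
        snp_id=snp_id, trait=trait, model="cGAS", n=n,
        beta=beta_std / sd_g, se=se_std / sd_g, sigma2=sigma_c2,
        chi2=chi2, p=float(p_from_chi2(chi2)),
        chr=str(target["chr"]), pos=int(target["pos"]),
        effect_allele=str(target["effect_allele"]), other_allele=str(target["other_allele"]),
        eaf=eaf, covariates=tuple(covariates),
        covariate_betas=tuple(float(b) for b in beta_vec[1:]),
        beta_std=beta_std, se_std=se_std,
        rho_yg=rho_yg, rho_gi=tuple(float(r) for r in rho_g),
    )


# ---------------------------------------------------------------------------
# genomic control


def genomic_control(
    records: list[AssociationRecord],
) -> tuple[list[AssociationRecord], dict[tuple[str, str], float]]:
    """Genomic-control correction, per (trait, model) scan.

    lambda = median(chi2) / median of the 1-df chi-square; statistics are
    divided by lambda only when lambda > 1 (deflated scans are left alone).
    Returns corrected copies of the records and the lambda per group.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault((r.trait, r.model), []).append(i)
    lambdas: dict[tuple[str, str], float] = {}
    out = list(records)
    for key, idx in groups.items():
        if len(idx) < 100:
            logger.warning("genomic_control: group %s has only %d records; lambda is noisy", key, len(idx))
        lam = float(np.median([records[i].chi2 for i in idx]) / MEDIAN_CHI2_1DF)
        lambdas[key] = lam
        for i in idx:
            r = records[i]
            p_gc = float(p_from_chi2(r.chi2 / lam)) if lam > 1.0 else r.p
            out[i] = replace(r, p_gc=p_gc)
    return out, lambdas


# ---------------------------------------------------------------------------
# decomposition


def decompose_log_ratio(
    u: AssociationRecord,
    c: AssociationRecord,
    rho_yg: float | None = None,
    rho_gi: tuple[float, ...] | None = None,
    beta_i: tuple[float, ...] | None = None,
) -> DecompositionRecord:
    """Split log10(T_c^2 / T_u^2) into noise and pleiotropic components.

    ``u`` and ``c`` must be the univariate and conditional fits of the same
    (SNP, trait) pair on the same sample.  The correlation inputs default to
    the values stored on the conditional record.  The identity
    noise + pleiotropic = total is enforced to 1e-9; a violation indicates
    mismatched samples or inconsistent conventions.
    """
    if (u.snp_id, u.trait) != (c.snp_id, c.trait):
        raise ValueError("records refer to different (SNP, trait) pairs")
    if u.model != "uGAS" or c.model != "cGAS":
        raise ValueError("expected a (uGAS, cGAS) record pair")
    rho_yg = c.rho_yg if rho_yg is None else rho_yg
    rho_gi = c.rho_gi if rho_gi is None else tuple(rho_gi)
    beta_i = c.covariate_betas if beta_i is None else tuple(beta_i)
    if rho_yg is None:
        raise ValueError("rho_yg unavailable")

    if abs(rho_yg) < _RHO_EPS or u.chi2 <= 0:
        return DecompositionRecord(
            snp_id=c.snp_id, trait=c.trait, noise=math.nan, pleiotropic=math.nan,
            total=math.nan, rho_yg=rho_yg, rho_star=(), degenerate=True,
        )
    bracket = 1.0 - sum(b * r for b, r in zip(beta_i, rho_gi)) / rho_yg
    if bracket == 0.0 or c.chi2 <= 0:
        return DecompositionRecord(
            snp_id=c.snp_id, trait=c.trait, noise=math.log10(u.sigma2 / c.sigma2),
            pleiotropic=-math.inf, total=-math.inf, rho_yg=rho_yg,
            rho_star=tuple(r / rho_yg for r in rho_gi), degenerate=True,
        )
    noise = math.log10(u.sigma2 / c.sigma2)
    pleiotropic = math.log10(bracket * bracket)
    total = math.log10(c.chi2 / u.chi2)
    if abs(noise + pleiotropic - total) > 1e-9:
        raise ValueError(
            f"{c.snp_id}/{c.trait}: decomposition identity violated "
            f"({noise:+.3e} + {pleiotropic:+.3e} != {total:+.3e}); "
            "were the two models fitted on the same sample?"
        )
    return DecompositionRecord(
        snp_id=c.snp_id, trait=c.trait, noise=noise, pleiotropic=pleiotropic,
        total=total, rho_yg=rho_yg,
        rho_star=tuple(r / rho_yg for r in rho_gi), degenerate=False,
    )


def decompose_from_conditional(c: AssociationRecord) -> DecompositionRecord:
    """Decompose using the matched univariate fit implied by the conditional record.

    The conditional record carries rho_yg for its own analysis sample, which
    determines the univariate fit on that sample exactly
    (sigma_u^2 = 1 - rho_yg^2, T_u^2 = n rho_yg^2 / sigma_u^2); this
    guarantees the same-sample requirement of the identity even when the
    full-sample univariate scan used a different complete-case set.
    """
    if c.model != "cGAS" or c.rho_yg is None:
        raise ValueError("need a cGAS record carrying rho_yg")
    rho = c.rho_yg
    if abs(rho) < _RHO_EPS:
        return DecompositionRecord(
            snp_id=c.snp_id, trait=c.trait, noise=math.nan, pleiotropic=math.nan,
            total=math.nan, rho_yg=rho, rho_star=(), degenerate=True,
        )
    sigma_u2 = 1.0 - rho * rho
    chi2_u = c.n * rho * rho / sigma_u2
    u = AssociationRecord(
        snp_id=c.snp_id, trait=c.trait, model="uGAS", n=c.n,
        beta=rho, se=math.sqrt(sigma_u2 / c.n), sigma2=sigma_u2,
        chi2=chi2_u, p=float(p_from_chi2(chi2_u)),
        chr=c.chr, pos=c.pos, effect_allele=c.effect_allele,
        other_allele=c.other_allele, eaf=c.eaf,
        beta_std=rho, se_std=math.sqrt(sigma_u2 / c.n), rho_yg=rho,
    )
    return decompose_log_ratio(u, c)


def decompose_records(
    c_records: list[AssociationRecord],
) -> dict[tuple[str, str], DecompositionRecord]:
    """Decompose every conditional record, keyed by (snp_id, trait)."""
    return {(r.snp_id, r.trait): decompose_from_conditional(r) for r in c_records}


# ---------------------------------------------------------------------------
# loci and scan comparison


def define_loci(
    records: list[AssociationRecord],
    threshold: float,
    window: int = 500_000,
) -> list[Locus]:
    """Cluster genome-wide significant hits into physical loci.

    Keeps records with (GC-corrected, when available) p <= threshold; on
    each chromosome, successive hits closer than ``window`` bp join one
    locus (single linkage), a gap of at least ``window`` starts a new one.
    """
    hits = [r for r in records if r.p_best <= threshold]
    by_chr: dict[str, list[AssociationRecord]] = {}
    for r in hits:
        by_chr.setdefault(r.chr, []).append(r)
    loci: list[Locus] = []
    for chrom in sorted(by_chr):
        rs = sorted(by_chr[chrom], key=lambda r: (r.pos, r.trait))
        current: list[AssociationRecord] = []
        for r in rs:
            if current and r.pos - current[-1].pos >= window:
                loci.append(Locus(chrom, current[0].pos, current[-1].pos, current))
                current = []
            current.append(r)
        if current:
            loci.append(Locus(chrom, current[0].pos, current[-1].pos, current))
    return loci


def compare_scans(
    a: list[AssociationRecord],
    b: list[AssociationRecord],
    loci: list[Locus],
) -> dict:
    """Compare two scans (e.g. uGAS vs cGAS) by their best statistic per locus.

    Within each locus, if several SNPs hit the same trait only the SNP with
    the lower p-value under scan ``a`` is kept; the locus score under each
    scan is the maximum chi2 over the kept pairs.  Reports the per-locus
    scores, the mean ratio max_b / max_a, and a two-sided paired Wilcoxon
    signed-rank p-value (1.0 when every difference is zero).
    """
    a_by = {(r.snp_id, r.trait): r for r in a}
    b_by = {(r.snp_id, r.trait): r for r in b}
    rows = []
    for locus in loci:
        per_trait: dict[str, AssociationRecord] = {}
        for r in locus.members:
            ra = a_by.get((r.snp_id, r.trait))
            if ra is None:
                continue
            prev = per_trait.get(r.trait)
            if prev is None or ra.p_best < a_by[(prev.snp_id, prev.trait)].p_best:
                per_trait[r.trait] = r
        pairs = [
            (a_by[(r.snp_id, r.trait)], b_by.get((r.snp_id, r.trait)))
            for r in per_trait.values()
        ]
        pairs = [(ra, rb) for ra, rb in pairs if rb is not None]
        if not pairs:
            continue
        max_a = max(ra.chi2 for ra, _ in pairs)
        max_b = max(rb.chi2 for _, rb in pairs)
        rows.append({"chr": locus.chr, "start": locus.start, "end": locus.end,
                     "max_chi2_a": max_a, "max_chi2_b": max_b,
                     "ratio": max_b / max_a, "diff": max_b - max_a})
    frame = pd.DataFrame(rows, columns=["chr", "start", "end", "max_chi2_a", "max_chi2_b", "ratio", "diff"])
    if frame.empty:
        return {"per_locus": frame, "mean_ratio": math.nan, "wilcoxon_p": math.nan, "n_loci": 0}
    diffs = frame["diff"].to_numpy()
    if np.allclose(diffs, 0.0):
        wp = 1.0
    else:
        wp = float(stats.wilcoxon(frame["max_chi2_a"], frame["max_chi2_b"]).pvalue)
    return {
        "per_locus": frame,
        "mean_ratio": float(frame["ratio"].mean()),
        "wilcoxon_p": wp,
        "n_loci": len(frame),
    }


# ---------------------------------------------------------------------------
# profile matrix (correlations + partial regression coefficients)


def association_profile(
    traits: TraitMatrix,
    geno: GenotypeMatrix,
    snp_id: str,
    trait: str,
    covariates: list[str],
    se_mode: str = "paper",
) -> pd.DataFrame:
    """Correlation/partial-regression profile of one association.

    Square matrix over (trait, SNP, covariates...): Pearson correlations
    off-diagonal, unit diagonal, with the first column replaced (below the
    diagonal) by the conditional-model partial regression coefficients of
    the trait on the SNP and the covariates.
    """
    j = geno.snp_index(snp_id)
    g_all = geno.dosages[:, j]
    y_all = traits.column(trait)
    C_all = np.column_stack([traits.column(c) for c in covariates]) if covariates else None
    mask = np.isfinite(y_all) & np.isfinite(g_all)
    if C_all is not None:
        mask &= np.isfinite(C_all).all(axis=1)
    y, _, _ = _standardize(y_all[mask])
    C = (
        np.column_stack([_standardize(C_all[mask][:, i])[0] for i in range(len(covariates))])
        if covariates else None
    )
    fit = _fit_pair(y, g_all[mask], C, se_mode)

    labels = [trait, snp_id, *covariates]
    data = np.column_stack([y, g_all[mask]] + ([C] if C is not None else []))
    M = np.corrcoef(data, rowvar=False)
    M[1, 0] = fit["beta"]
    for i, b in enumerate(fit["covariate_betas"]):
        M[2 + i, 0] = b
    return pd.DataFrame(M, index=labels, columns=labels)
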