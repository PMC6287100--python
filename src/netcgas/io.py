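"""Readers and writers for the plain-text formats the pipeline touches.

All tabular formats are tab-separated UTF-8 with ``NA`` as the missing
marker.  Genotypes come either from a VCF (biallelic SNPs; the ``DS``
FORMAT field is preferred, falling back to counting ALT alleles in ``GT``)
or from a dosage TSV with columns ``id, chr, pos, effA, refA`` followed by
one column per sample.  Every reader/writer pair round-trips losslessly on
valid data.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .datatypes import (
    SUMMARY_COLUMNS,
    AssociationRecord,
    GenotypeMatrix,
    SNPRecord,
    SummaryStatsTable,
    TraitCorrelations,
    TraitMatrix,
    TraitNetwork,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # full double precision for lossless round trips

__all__ = [
    "read_genotypes",
    "write_dosage_tsv",
    "read_traits",
    "write_traits",
    "read_network",
    "write_network",
    "read_summary_stats",
    "write_summary_stats",
    "read_trait_correlations",
    "write_trait_correlations",
    "records_to_frame",
    "write_records",
    "read_records",
]


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Load a :class:`GenotypeMatrix` from a VCF or a dosage TSV.

    VCF records that are not biallelic SNPs are skipped (the skip count is
    logged).  Dosage is the ``DS`` field when present, otherwise the ALT
    allele count from ``GT``.  Missing ``eaf`` values are filled from the
    dosage means.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        snps: list[SNPRecord] = []
        cols: list[np.ndarray] = []
        n_skipped = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            dose = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                call = rec.samples[sample]
                ds = call.get("DS")
                if ds is not None:
                    dose[i] = float(ds[0] if isinstance(ds, tuple) else ds)
                    continue
                gt = call.get("GT")
                if gt is not None and all(a is not None for a in gt):
                    dose[i] = float(sum(gt))
            try:
                info_r2 = rec.info.get("R2")
            except (KeyError, ValueError):  # R2 absent from the header
                info_r2 = None
            if isinstance(info_r2, tuple):
                info_r2 = info_r2[0]
            snps.append(
                SNPRecord(
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chr=str(rec.chrom),
                    pos=int(rec.pos),
                    effect_allele=alt,
                    other_allele=ref,
                    imputation_r2=float(info_r2) if info_r2 is not None else None,
                )
            )
            cols.append(dose)
    if not snps:
        raise ValueError(f"{path}: no usable biallelic SNPs ({n_skipped} records skipped)")
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic/non-SNP records", path, n_skipped)
    gm = GenotypeMatrix(samples, snps, np.column_stack(cols)).with_eaf_from_dosages()
    gm.n_skipped_records = n_skipped
    return gm


_DOSAGE_META = ["id", "chr", "pos", "effA", "refA", "eaf", "call_rate", "imputation_r2", "hwe_p"]


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chr": str}, na_values=["NA", "."])
    missing = [c for c in _DOSAGE_META[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage TSV missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in _DOSAGE_META]
    if not sample_cols:
        raise ValueError(f"{path}: dosage TSV has no sample columns")

    def opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    snps = [
        SNPRecord(
            id=row["id"], chr=row["chr"], pos=int(row["pos"]),
            effect_allele=row["effA"], other_allele=row["refA"],
            eaf=opt(row, "eaf"), call_rate=opt(row, "call_rate"),
            imputation_r2=opt(row, "imputation_r2"), hwe_p=opt(row, "hwe_p"),
        )
        for _, row in df.iterrows()
    ]
    dosages = df[sample_cols].to_numpy(dtype=float).T  # rows were SNPs
    gm = GenotypeMatrix(sample_cols, snps, dosages)
    return gm.with_eaf_from_dosages()


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    rows = []
    for j, s in enumerate(gm.snps):
        row = {
            "id": s.id, "chr": s.chr, "pos": s.pos,
            "effA": s.effect_allele, "refA": s.other_allele,
            "eaf": s.eaf, "call_rate": s.call_rate,
            "imputation_r2": s.imputation_r2, "hwe_p": s.hwe_p,
        }
        for i, sid in enumerate(gm.sample_ids):
            row[sid] = gm.dosages[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# traits


def read_traits(path: str | Path, state: str = "raw") -> TraitMatrix:
    """Read a trait TSV (header: ``sample_id`` then trait names)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: trait TSV must have a sample_id column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    trait_names = [c for c in df.columns if c != "sample_id"]
    for col in trait_names:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, row {bad.index[0] + 2}"
            )
    return TraitMatrix(
        df["sample_id"].tolist(), trait_names, df[trait_names].to_numpy(dtype=float), state=state
    )


def write_traits(tm: TraitMatrix, path: str | Path) -> None:
    df = tm.to_frame()
    df.insert(0, "sample_id", tm.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a nuisance-covariate TSV (sample_id plus e.g. sex/age/batch)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: covariate TSV must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in covariate table")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# network


def read_network(path: str | Path) -> TraitNetwork:
    """Read an undirected edge list (columns trait_a, trait_b[, weight[, p]]).

    Duplicate edges collapse to one; self-loop rows are skipped with a
    warning.  An empty file yields an empty network.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"trait_a": str, "trait_b": str})
    except pd.errors.EmptyDataError:
        return TraitNetwork()
    for col in ("trait_a", "trait_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: network TSV missing column {col!r}")
    net = TraitNetwork()
    for _, row in df.iterrows():
        a, b = row["trait_a"], row["trait_b"]
        if a == b:
            warnings.warn(f"{path}: skipping self-loop on {a!r}")
            continue
        w = float(row["weight"]) if "weight" in df.columns and pd.notna(row.get("weight")) else None
        p = float(row["p"]) if "p" in df.columns and pd.notna(row.get("p")) else None
        net.add_edge(a, b, weight=w, p=p)
    return net


def write_network(net: TraitNetwork, path: str | Path) -> None:
    rows = []
    for a, b in net.edges:
        attrs = net.graph.edges[a, b]
        rows.append(
            {"trait_a": a, "trait_b": b,
             "weight": attrs.get("weight", np.nan), "p": attrs.get("p", np.nan)}
        )
    pd.DataFrame(rows, columns=["trait_a", "trait_b", "weight", "p"]).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# summary statistics and trait correlations


def read_summary_stats(path: str | Path) -> SummaryStatsTable:
    """Read a univariate summary-stats TSV; rows with se <= 0 are dropped (counted)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chr": str, "trait_name": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: summary-stats TSV missing column {missing[0]!r}")
    bad = df["se"] <= 0
    if bad.any():
        logger.warning("%s: dropping %d rows with se <= 0", path, int(bad.sum()))
        df = df[~bad]
    return SummaryStatsTable(df)


def write_summary_stats(table: SummaryStatsTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_trait_correlations(path: str | Path) -> TraitCorrelations:
    """Read a trait correlation matrix TSV (first column: trait names; header
    comment ``# n_effective=<int>`` carries the sample count)."""
    path = Path(path)
    n_eff = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            n_eff = int(first.strip().split("=")[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    return TraitCorrelations(df.index.tolist(), df.to_numpy(dtype=float), n_eff)


def write_trait_correlations(tc: TraitCorrelations, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_effective={tc.n_effective}\n")
        pd.DataFrame(tc.matrix, index=tc.trait_names, columns=tc.trait_names).to_csv(
            fh, sep="\t", float_format=_FLOAT_FMT
        )


# ---------------------------------------------------------------------------
# association-result tables

RESULT_COLUMNS = [
    "snp", "chr", "pos", "effA", "refA", "eaf", "trait", "model", "n", "n_cov",
    "covariates", "beta", "se", "chi2", "p", "p_gc", "sigma2", "noise", "pleiotropic",
]


def records_to_frame(
    records: list[AssociationRecord],
    decompositions: dict[tuple[str, str], "object"] | None = None,
) -> pd.DataFrame:
    """Flatten association records (optionally with their decompositions)
    into the results-table layout."""
    decompositions = decompositions or {}
    rows = []
    for r in records:
        d = decompositions.get((r.snp_id, r.trait))
        rows.append(
            {
                "snp": r.snp_id, "chr": r.chr, "pos": r.pos,
                "effA": r.effect_allele, "refA": r.other_allele, "eaf": r.eaf,
                "trait": r.trait, "model": r.model, "n": r.n, "n_cov": r.n_cov,
                "covariates": ",".join(r.covariates) if r.covariates else "",
                "beta": r.beta, "se": r.se, "chi2": r.chi2, "p": r.p,
                "p_gc": r.p_gc if r.p_gc is not None else np.nan,
                "sigma2": r.sigma2,
                "noise": d.noise if d is not None and not d.degenerate else np.nan,
                "pleiotropic": d.pleiotropic if d is not None and not d.degenerate else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_records(frame: pd.DataFrame, path: str | Path, header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"snp": str, "chr": str, "trait": str},
                       na_values=["NA"], keep_default_na=True)
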