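"""End-to-end orchestration: QC -> adjust -> network -> scans -> GC ->
decomposition -> loci -> comparison, from a single flat YAML config.

Outputs are the tabular formats of :mod:`netcgas.io`; every table carries a
header comment with the config hash and the genomic-control lambdas, and
identical config + inputs yield byte-identical table bodies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as ncio
from .association import (
    cgas_scan,
    compare_scans,
    decompose_records,
    define_loci,
    genomic_control,
    significance_threshold,
    ugas_scan,
)
from .datatypes import TraitNetwork
from .network import covariate_neighbors, ggm_edges, partial_correlation_matrix
from .preprocess import QcThresholds, inverse_normal_transform, residualize, snp_qc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat run configuration (mirrors the YAML file key-for-key)."""

    genotypes: str
    traits: str
    out_dir: str
    covariates: str | None = None
    network: str | None = None
    mode: str = "ggm"  # "bn" (supplied network) or "ggm" (estimated)
    genotype_format: str = "vcf"
    min_call_rate: float = 0.95
    min_imputation_r2: float = 0.3
    min_hwe_p: float = 1e-6
    min_maf: float = 0.01
    int_offset: float = 0.5
    alpha_total: float = 0.01
    n_traits_threshold: int | None = None  # default: number of traits scanned
    base_threshold: float = 5e-8
    locus_window: int = 500_000
    gc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("bn", "ggm"):
            raise ValueError(f"mode must be 'bn' or 'ggm', got {self.mode!r}")
        if self.mode == "bn" and not self.network:
            raise ValueError("mode 'bn' requires a network path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        for p in (self.genotypes, self.traits, self.covariates, self.network):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def digest(self) -> str:
        """Hash of the analytical configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            min_call_rate=self.min_call_rate,
            min_imputation_r2=self.min_imputation_r2,
            min_hwe_p=self.min_hwe_p,
            min_maf=self.min_maf,
        )


def _stage(log: list[str], name: str, fn):
    try:
        return fn()
    except Exception as exc:
        log.append(f"FAILED at stage {name}: {exc}")
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full scan pipeline; returns the result bundle.

    Stage order: read -> SNP QC -> residualize -> inverse-normal transform
    -> network (read in bn mode, GGM estimation in ggm mode) -> uGAS ->
    cGAS -> genomic control -> decomposition -> loci -> scan comparison.
    Writes ugas.tsv, cgas.tsv, decomposition.tsv, loci.tsv, comparison.tsv
    and run.log under ``cfg.out_dir``.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash={cfg.digest()}"]

    geno = _stage(log, "read_genotypes", lambda: ncio.read_genotypes(cfg.genotypes, format=cfg.genotype_format))
    traits = _stage(log, "read_traits", lambda: ncio.read_traits(cfg.traits))
    log.append(f"genotypes: {geno.n_samples} samples x {geno.n_snps} SNPs")
    log.append(f"traits: {traits.n_samples} samples x {traits.n_traits} traits")

    geno, qc_report = _stage(log, "snp_qc", lambda: snp_qc(geno, cfg.qc_thresholds()))
    log.append(f"snp_qc: {qc_report.n_in} in, {qc_report.n_out} out, failures {qc_report.counts()}")

    if cfg.covariates:
        nuisance = _stage(log, "read_covariates", lambda: ncio.read_covariates(cfg.covariates))
        traits = _stage(log, "residualize", lambda: residualize(traits, nuisance))
        log.append(f"residualized on nuisance columns {list(nuisance.columns)}")
    traits = _stage(log, "inverse_normal_transform",
                    lambda: inverse_normal_transform(traits, offset=cfg.int_offset))

    if cfg.mode == "bn":
        net: TraitNetwork = _stage(log, "read_network", lambda: ncio.read_network(cfg.network))
        log.append(f"network (bn): {len(net)} nodes, {len(net.edges)} edges")
    else:
        pc = _stage(log, "partial_correlations", lambda: partial_correlation_matrix(traits))
        net = _stage(log, "ggm_edges", lambda: ggm_edges(pc, alpha_total=cfg.alpha_total))
        log.append(
            f"network (ggm): cutoff {net.meta['cutoff']:.4g}, "
            f"{len(net)} nodes, {len(net.edges)} edges, n={pc.n}"
        )

    u_records = _stage(log, "ugas_scan", lambda: ugas_scan(traits, geno))
    c_records = _stage(log, "cgas_scan", lambda: cgas_scan(traits, geno, net))
    for trait in traits.trait_names:
        covs = covariate_neighbors(net, trait) if trait in net else []
        log.append(f"covariates[{trait}]: {','.join(covs) if covs else '(none)'}")

    lambdas: dict = {}
    if cfg.gc:
        u_records, lam_u = _stage(log, "genomic_control_ugas", lambda: genomic_control(u_records))
        c_records, lam_c = _stage(log, "genomic_control_cgas", lambda: genomic_control(c_records))
        lambdas = {**lam_u, **lam_c}
        for (trait, model), lam in sorted(lambdas.items()):
            log.append(f"lambda[{trait},{model}]={lam:.4f}")

    decomp = _stage(log, "decomposition", lambda: decompose_records(c_records))

    n_traits = cfg.n_traits_threshold or traits.n_traits
    threshold = significance_threshold(n_traits, base=cfg.base_threshold)
    log.append(f"significance threshold: {threshold:.4g} ({n_traits} traits)")
    loci = _stage(log, "define_loci",
                  lambda: define_loci(u_records + c_records, threshold, window=cfg.locus_window))
    log.append(f"loci: {len(loci)}")
    comparison = _stage(log, "compare_scans", lambda: compare_scans(u_records, c_records, loci))

    header = [f"config_hash={cfg.digest()}"] + [
        f"lambda {t}/{m}={lam:.6f}" for (t, m), lam in sorted(lambdas.items())
    ]
    u_frame = ncio.records_to_frame(u_records)
    c_frame = ncio.records_to_frame(c_records, decomp)
    ncio.write_records(u_frame, out / "ugas.tsv", header)
    ncio.write_records(c_frame, out / "cgas.tsv", header)

    d_rows = [
        {"snp": d.snp_id, "trait": d.trait, "noise": d.noise, "pleiotropic": d.pleiotropic,
         "total": d.total, "rho_yg": d.rho_yg, "degenerate": int(d.degenerate)}
        for d in decomp.values()
    ]
    import pandas as pd

    ncio.write_records(pd.DataFrame(d_rows, columns=["snp", "trait", "noise", "pleiotropic",
                                                     "total", "rho_yg", "degenerate"]),
                       out / "decomposition.tsv", header)
    l_rows = [
        {"chr": l.chr, "start": l.start, "end": l.end, "n_members": len(l.members),
         "best_snp": l.best.snp_id, "best_trait": l.best.trait,
         "best_model": l.best.model, "best_p": l.best.p_best}
        for l in loci
    ]
    ncio.write_records(pd.DataFrame(l_rows, columns=["chr", "start", "end", "n_members",
                                                     "best_snp", "best_trait", "best_model", "best_p"]),
                       out / "loci.tsv", header)
    comp_frame = comparison["per_locus"].copy()
    comp_header = header + [
        f"mean_ratio={comparison['mean_ratio']}", f"wilcoxon_p={comparison['wilcoxon_p']}"
    ]
    ncio.write_records(comp_frame, out / "comparison.tsv", comp_header)
    (out / "run.log").write_text("\n".join(log) + "\n")

    return {
        "ugas": u_records, "cgas": c_records, "decomposition": decomp,
        "loci": loci, "comparison": comparison, "lambdas": lambdas,
        "network": net, "threshold": threshold, "log": log, "out_dir": out,
    }
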