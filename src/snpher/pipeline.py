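"""End-to-end study pipeline over a synthetic cohort.

Stages: simulate -> QC -> GRM -> GREML (liability h2) -> GWAS (+ inflation,
clumping) -> LD scores + LDSC h2 -> phenotypic correlations -> leave-one-out
rg grid -> stratified GxE + GxEsum -> report.  Every stage writes open
formats (TSV, PLINK, GCTA GRM) into the run directory; a completed run is
recognized by its frozen config hash and reloaded rather than recomputed, so
re-running with an identical config and seed is bit-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from ._rng import derive_seed
from .endocrine import loo_rg_grid, phenotypic_correlation
from .greml import (
    GREML,
    MetaEstimate,
    gxe_stratified,
    observed_to_liability,
    split_meta,
)
from .gwas import association_scan, clump_loci, genomic_inflation, to_sumstats
from .ldsc import compute_ld_scores, gxesum_fit, interaction_scan, ldsc_h2, ldsc_rg
from .qc import QcThresholds, apply_qc, compute_grm, pc_outlier_filter, prune_related
from .simulate import SimulationConfig, simulate_panel, simulate_phenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StudyReport",
    "run_pipeline",
    "split_indices",
    "split_sample_runner",
]


@dataclass
class RunConfig:
    out_dir: str = "snpher_run"
    master_seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    run_greml: bool = True
    run_gwas: bool = True
    run_ldsc: bool = True
    run_correlations: bool = True
    run_loo: bool = False
    run_gxe: bool = False
    gwas_model: str = "linear"
    clump_r2: float = 0.1
    clump_window_bp: int = 1_000_000
    n_jackknife_blocks: int = 200
    prevalence: float | None = None  # None: use the sample case proportion
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def freeze(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(payload, sort_keys=True, default_flow_style=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        qc = raw.pop("qc", {})
        if isinstance(sim, dict):
            for key in ("subtype_specs", "trait_specs", "gxe_spec", "covariate_spec"):
                sim.pop(key, None)
            sim = SimulationConfig(**sim)
        if isinstance(qc, dict):
            qc = QcThresholds(**qc)
        return cls(simulation=sim, qc=qc, **raw)


@dataclass
class StudyReport:
    tables: dict
    provenance: dict

    def write(self, path: Path) -> None:
        payload = {
            "provenance": self.provenance,
            "tables": {
                k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
                for k, v in self.tables.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2, default=str, sort_keys=True))


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute all toggled stages in dependency order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    report_path = out / "report.json"
    if report_path.exists():
        prior = json.loads(report_path.read_text())
        if prior.get("provenance", {}).get("config_hash") == config.config_hash():
            logger.info("found completed run with matching config hash; reusing")
            return StudyReport(tables=prior["tables"], provenance=prior["provenance"])
    config.freeze(out / "config.frozen.yaml")
    for f in dataclasses.fields(config):
        logger.info("config %s = %r", f.name, getattr(config, f.name))
    seed = config.master_seed
    tables: dict = {}

    try:
        # ---- simulate -----------------------------------------------------
        sim = dataclasses.replace(config.simulation, master_seed=seed)
        panel = simulate_panel(sim)
        pheno = simulate_phenotypes(panel, sim)
        sio.write_plink(panel, out / "cohort")
        sio.write_pheno(pheno.table, out / "cohort.pheno")
        truth = {
            "grouped_case_proportion": float(pheno.table["grouped_status"].mean()),
            "subtype_case_counts": {
                s: int(np.nansum(pheno.table[s])) for s in pheno.subtype_names
            },
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        tables["simulation"] = truth

        # ---- QC + GRM -----------------------------------------------------
        panel_qc, report = apply_qc(panel, config.qc)
        tables["qc"] = dataclasses.asdict(report)
        grm = compute_grm(panel_qc)
        # The relatedness threshold is calibrated for dense panels where the
        # off-diagonal noise SD (~1/sqrt(M)) is far below it; at small M the
        # effective cutoff is lifted to 6 noise SDs so sampling noise is not
        # mistaken for relatedness.
        iu = np.triu_indices(grm.n_samples, k=1)
        off = grm.values[iu]
        eff_cutoff = max(config.qc.relatedness_max, float(off.mean() + 6.0 * off.std()))
        kept = prune_related(grm, eff_cutoff, seed=seed)
        keep_idx = np.where(np.isin(grm.sample_ids, kept))[0]
        grm = grm.subset(keep_idx)
        kept2, pcs = pc_outlier_filter(grm, n_pcs=10, sd_limit=config.qc.pc_sd_limit)
        keep_idx2 = np.where(np.isin(grm.sample_ids, kept2))[0]
        grm = grm.subset(keep_idx2)
        pcs = pcs[keep_idx2]
        sio.write_grm_bin(out / "cohort", grm.values, grm.sample_ids, grm.n_snps)
        sample_mask = pd.Index(pheno.table.index).get_indexer(grm.sample_ids)
        tab = pheno.table.iloc[sample_mask]
        panel_fit = panel_qc.subset(
            sample_idx=pd.Index(panel_qc.sample_ids).get_indexer(grm.sample_ids)
        )
        y = tab["grouped_status"].to_numpy().astype(float)
        covs = np.column_stack(
            [
                (tab["sex"] == "female").to_numpy(float),
                tab["age"].to_numpy(float),
                pcs[:, : min(10, pcs.shape[1])],
            ]
        )
        K = config.prevalence if config.prevalence is not None else float(y.mean())

        # ---- GREML --------------------------------------------------------
        if config.run_greml:
            est = GREML().fit(y, covs, grm=grm).estimate_
            lia = observed_to_liability(est, K, float(y.mean()))
            df = pd.DataFrame(
                [
                    ("h2_observed", est.h2_observed, est.h2_se, est.p_value,
                     "observed", est.n, est.converged),
                    ("h2_liability", lia.h2_liability, lia.se, lia.p_value,
                     "liability", est.n, est.converged),
                ],
                columns=["parameter", "estimate", "SE", "p", "scale", "n", "converged"],
            )
            df.to_csv(out / "greml.tsv", sep="\t", index=False)
            tables["greml"] = df

        # ---- GWAS ---------------------------------------------------------
        if config.run_gwas:
            assoc = association_scan(panel_fit, y, covs, model=config.gwas_model)
            assoc.write(out / "gwas.tsv")
            infl = genomic_inflation(
                assoc, int(y.sum()), int((y == 0).sum())
            )
            infl.qq.to_csv(out / "gwas.qq.tsv", sep="\t", index=False)
            loci = clump_loci(
                assoc, panel_fit, clump_r2=config.clump_r2,
                window_bp=config.clump_window_bp,
            )
            loci.table.to_csv(out / "gwas.loci.tsv", sep="\t", index=False)
            tables["gwas"] = {
                "n_significant": int((assoc.table["P"] < 5e-8).sum()),
                "n_loci": int(len(loci.table)),
                "lambda_observed": infl.lambda_observed,
                "lambda_1000": infl.lambda_1000,
            }

        # ---- LDSC ---------------------------------------------------------
        if config.run_ldsc and config.run_gwas:
            ld = compute_ld_scores(panel_fit)
            sio.write_ldscore(ld.table, out / "cohort.l2.ldscore", m_total=panel_fit.n_variants)
            ss = to_sumstats(assoc)
            sio.write_sumstats(ss, out / "cohort.sumstats")
            fit = ldsc_h2(
                ss, ld, M=panel_fit.n_variants, K=K, P=float(y.mean()),
                n_blocks=config.n_jackknife_blocks,
            )
            tables["ldsc"] = dataclasses.asdict(fit)
            pd.DataFrame([dataclasses.asdict(fit)]).to_csv(
                out / "ldsc.tsv", sep="\t", index=False
            )

        # ---- phenotypic correlations --------------------------------------
        if config.run_correlations:
            rows = []
            for tspec in sim.trait_specs:
                pc = phenotypic_correlation(
                    tab[tspec.name], y, names=(tspec.name, "grouped")
                )
                rows.append(
                    (pc.trait_x, pc.r, pc.se, pc.p_value, pc.n)
                )
            df = pd.DataFrame(rows, columns=["trait", "r_p", "SE", "p", "n"])
            df.to_csv(out / "pheno_corr.tsv", sep="\t", index=False)
            tables["phenotypic_correlation"] = df

        # ---- leave-one-out rg grid ----------------------------------------
        if config.run_loo and config.run_ldsc and config.run_gwas:
            def rg_cell(status_a, grouped_b):
                ok = np.isfinite(status_a)
                scan_a = association_scan(
                    panel_fit.subset(sample_idx=np.where(ok)[0]),
                    status_a[ok], covs[ok], model="linear",
                )
                scan_b = association_scan(panel_fit, grouped_b, covs, model="linear")
                est = ldsc_rg(
                    to_sumstats(scan_a), to_sumstats(scan_b), ld,
                    M=panel_fit.n_variants, n_blocks=config.n_jackknife_blocks,
                )
                if est.rg is None:
                    raise ValueError(est.reason)
                return est.rg, est.se

            grid = loo_rg_grid(list(pheno.subtype_names), tab, rg_cell)
            grid.to_csv(out / "loo_rg.tsv", sep="\t", index=False)
            tables["loo"] = grid

        # ---- GxE ----------------------------------------------------------
        if config.run_gxe:
            try:
                res = gxe_stratified(
                    y, tab["env_binary"].to_numpy(), grm, covariates=covs,
                    prevalence=K,
                )
                tables["gxe_stratified"] = {
                    "h2_obs_stratum0": res["h2_observed"][0].h2_observed,
                    "h2_obs_stratum1": res["h2_observed"][1].h2_observed,
                    "rg": res["rg"].rg,
                    "rg_se": res["rg"].se,
                    "p_rg_one": res["p_rg_one"],
                }
            except ValueError as exc:
                logger.warning("stratified GxE skipped: %s", exc)
                tables["gxe_stratified"] = {"skipped": str(exc)}
            iscan = interaction_scan(
                panel_fit, tab["gxe_trait"].to_numpy(),
                tab["env_quant"].to_numpy(), covs,
            )
            gfit = gxesum_fit(
                iscan, ld if config.run_ldsc else compute_ld_scores(panel_fit),
                N=len(y), M=panel_fit.n_variants,
                n_blocks=config.n_jackknife_blocks,
            )
            tables["gxesum"] = dataclasses.asdict(gfit)

    except Exception as exc:
        logger.error("stage failed: %s", exc)
        raise

    report = StudyReport(
        tables=tables,
        provenance={
            "config_hash": config.config_hash(),
            "master_seed": seed,
        },
    )
    report.write(out / "report.json")
    return report


def split_indices(n: int, k_splits: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded random partition of ``range(n)`` into k near-equal splits
    (sizes differ by at most 1)."""
    if k_splits < 2:
        raise ValueError("need at least 2 splits")
    rng = np.random.default_rng(derive_seed(seed, "split_sample"))
    return [np.sort(s) for s in np.array_split(rng.permutation(n), k_splits)]


def split_sample_runner(
    y, covariates, grm, k_splits: int, seed: int = 0, K: float | None = None
) -> tuple[MetaEstimate, list]:
    """Randomly partition the cohort into near-equal splits, fit GREML per
    split and pool with inverse-variance weights + Fisher's method.

    Split sizes differ by at most 1.  Returns (pooled liability-scale
    estimate, per-split estimates).
    """
    y = np.asarray(y, float).ravel()
    splits = split_indices(len(y), k_splits, seed)
    per_split = []
    for idx in splits:
        if len(idx) < 50:
            raise ValueError("split smaller than the GREML minimum n")
        sub_grm = grm.subset(idx)
        X = None if covariates is None else np.asarray(covariates)[idx]
        est = GREML().fit(y[idx], X, grm=sub_grm).estimate_
        Kk = K if K is not None else float(y[idx].mean())
        lia = observed_to_liability(est, Kk, float(y[idx].mean()))
        per_split.append(lia)
    meta = split_meta([(e.h2_liability, e.se, e.p_value) for e in per_split])
    return meta, per_split
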