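"""Pipeline driver: simulate -> QC -> distance -> GWAS -> score -> evaluate
-> diagnose, with every stage's tables written to an output directory and a
frozen copy of the resolved configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import distance as dist
from . import evaluate as ev
from . import io as pio
from . import qc as pqc
from .gwas import ClumpThresholdScorer
from .simulate import SimulationConfig, simulate_biobank

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run.  Unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "pgsport_out"
    log_level: str = "INFO"
    write_genotypes: bool = False
    run_disease: bool = True
    simulation: SimulationConfig = None
    # distance
    n_components: int = 40
    bin_size: int = 100
    ref_fraction: float = 0.1
    apply_percentile_filter: bool = False
    gwas_percentile: float = 97.5
    # gwas / pgs
    clump_p1: float = 0.01
    clump_r2: float = 0.2
    clump_kb: float = 250.0
    p_threshold: float = 1e-5
    n_gwas_pcs: int = 20
    # qc
    hwe_p_min: float = 1e-10
    maf_min: float = 1e-4
    # evaluation
    poly_degree: int = 20
    n_spline_knots: int = 8
    ve_spline_knots: int = 16
    n_bootstrap: int = 1000
    # diagnostics
    close_far_cut: float | None = None

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        elif isinstance(self.simulation, dict):
            unknown = set(self.simulation) - {
                f.name for f in dataclasses.fields(SimulationConfig)
            }
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
            self.simulation = SimulationConfig(**self.simulation)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a dict or a YAML/JSON file path."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        import yaml

        source = yaml.safe_load(Path(source).read_text()) or {}
    unknown = set(source) - {f.name for f in dataclasses.fields(PipelineConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**source)


def _gwas_covariates(pheno: pd.DataFrame, pcs: np.ndarray) -> np.ndarray:
    base = ev.build_covariates(pheno, include_array=False).to_numpy(dtype=float)
    return np.column_stack([base, pcs])


STAGE_ORDER = ("simulate", "qc", "distance", "gwas", "score", "evaluate",
               "diagnose")


def run_pipeline(config, until: str = "diagnose") -> dict:
    """Execute the pipeline through the ``until`` stage (one of STAGE_ORDER)
    and return the in-memory results dict.

    Every stage writes its tables under ``config.output_dir``; on stage
    failure, partial outputs are retained and a failure manifest is written
    before the exception propagates.
    """
    cfg = load_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in cfg.to_dict().items()
              if k not in ("output_dir", "log_level")}
    chash = pio.config_hash(hashed)
    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=str))
    logger.info("pipeline run: seed=%d config=%s", cfg.seed, chash)

    if until not in STAGE_ORDER:
        raise ValueError(f"unknown stage: {until!r}")
    last = STAGE_ORDER.index(until)

    def done(stage_name):
        return STAGE_ORDER.index(stage_name) >= last

    res: dict = {"config": cfg}
    stage = "simulate"
    try:
        G, truth, pheno = simulate_biobank(cfg.simulation)
        res.update(G=G, truth=truth, pheno=pheno)
        pio.write_phenotypes(out / "phenotypes.tsv", pheno)
        pio.write_table(out / "truth.tsv", truth.to_frame(), cfg.seed, chash)
        if cfg.write_genotypes:
            pio.write_raw(out / "genotypes.raw.tsv", G)
            pio.write_bim(out / "variants.bim", G.variant_meta)

        if done("simulate"):
            return res
        stage = "qc"
        flags = pd.DataFrame({"sample_id": G.sample_ids})
        for col in pqc.SAMPLE_FLAG_ORDER:
            flags[col] = False
        _, sample_ledger = pqc.filter_samples(
            flags, pqc.FilterConfig(hwe_p_min=cfg.hwe_p_min, maf_min=cfg.maf_min)
        )
        kept, variant_ledger = pqc.filter_variants(
            G, pqc.FilterConfig(hwe_p_min=cfg.hwe_p_min, maf_min=cfg.maf_min)
        )
        G = G.subset_variants(kept)
        res.update(G=G, sample_ledger=sample_ledger, variant_ledger=variant_ledger)
        (out / "qc_samples.json").write_text(sample_ledger.to_json())
        (out / "qc_variants.json").write_text(variant_ledger.to_json())
        pio.write_table(out / "qc_variants.tsv", variant_ledger.to_frame(),
                        cfg.seed, chash)

        if done("qc"):
            return res
        stage = "distance"
        gwas_mask = G.gwas_mask
        k = min(cfg.n_components, min(G.n_samples, G.n_variants))
        pca = dist.GeneticDistancePCA(n_components=k)
        dres = pca.fit_distances(G.dosages, gwas_mask)
        if cfg.apply_percentile_filter:
            eval_mask = dist.percentile_filter(dres, gwas_mask, cfg.gwas_percentile)
        else:
            eval_mask = ~gwas_mask
        bins = dist.assign_bins(
            dres.standardized[eval_mask], cfg.bin_size, G.sample_ids[eval_mask]
        )
        n_ref = max(1, round(cfg.ref_fraction * bins.n_bins))
        ref_bins = dist.select_reference_bins(bins, n_ref)
        res.update(pca=pca, distances=dres, eval_mask=eval_mask, bins=bins,
                   reference_bins=ref_bins)
        pio.write_table(
            out / "distances.tsv",
            pd.DataFrame({"sample_id": G.sample_ids, "deme": G.deme_label,
                          "raw": dres.raw, "standardized": dres.standardized}),
            cfg.seed, chash,
        )
        pio.write_table(
            out / "bins.tsv",
            pd.DataFrame({"bin": np.arange(bins.n_bins),
                          "median_distance": bins.bin_median_distance,
                          "is_reference": np.isin(np.arange(bins.n_bins), ref_bins)}),
            cfg.seed, chash,
        )

        if done("distance"):
            return res
        stage = "gwas"
        gpheno = pheno[gwas_mask].reset_index(drop=True)
        pcs_gwas = pca.coords_[gwas_mask][:, : cfg.n_gwas_pcs]
        covar_gwas = _gwas_covariates(gpheno, pcs_gwas)
        scorer = ClumpThresholdScorer(
            clump_p1=cfg.clump_p1, clump_r2=cfg.clump_r2, clump_kb=cfg.clump_kb,
            p_threshold=cfg.p_threshold,
        )
        scorer.fit(
            G.dosages[gwas_mask], gpheno["trait"].to_numpy(),
            covariates=covar_gwas,
            positions=G.variant_meta["pos"].to_numpy(),
            chromosomes=G.variant_meta["chrom"].to_numpy(),
            variant_ids=G.variant_meta["id"].to_numpy(),
        )
        pgs = scorer.predict(G.dosages)
        res.update(scorer=scorer, pgs=pgs)
        pio.write_table(out / "gwas_summary.tsv", scorer.summary_, cfg.seed, chash)
        pio.write_table(
            out / "pgs_model.tsv",
            pd.DataFrame({"variant": scorer.model_.index_variants,
                          "effect_allele": scorer.model_.effect_alleles,
                          "weight": scorer.model_.weights}),
            cfg.seed, chash,
        )
        pio.write_table(
            out / "pgs_scores.tsv",
            pd.DataFrame({"sample_id": G.sample_ids, "pgs": pgs}),
            cfg.seed, chash,
        )

        if not done("score"):
            stage = "evaluate"
            ev_idx = np.where(eval_mask)[0]
            y_ev = pheno["trait"].to_numpy()[ev_idx]
            ph_ev = pheno.iloc[ev_idx].reset_index(drop=True)
            d_ev = dres.standardized[ev_idx]
            profile = ev.group_profile(bins, y_ev, pgs[ev_idx], ph_ev, ref_bins)
            perr = ev.individual_error(
                y_ev, ph_ev, d_ev, bins, pgs[ev_idx], ref_bins,
                poly_degree=cfg.poly_degree,
            )
            spline = ev.fit_density_spline(
                d_ev, perr.standardized, n_knots=cfg.n_spline_knots
            )
            ve = {}
            for name, x in (("distance", d_ev),
                            ("ses_index", ph_ev["ses_index"].to_numpy()),
                            ("income_stratum", ph_ev["income_stratum"].to_numpy())):
                r2, ci = ev.variance_explained(
                    perr, x, "linear", n_bootstrap=cfg.n_bootstrap, seed=cfg.seed
                )
                ve[name] = {"r2": r2, "ci": ci}
            res.update(profile=profile, prediction_error=perr,
                       error_spline=spline, variance_explained=ve)
            pio.write_table(out / "group_profile.tsv", profile, cfg.seed, chash)
            pio.write_table(
                out / "individual_error.tsv",
                pd.DataFrame({"sample_id": G.sample_ids[ev_idx],
                              "unstandardized": perr.unstandardized,
                              "standardized": perr.standardized}),
                cfg.seed, chash,
            )
            if cfg.run_disease and "disease" in pheno:
                dscorer = ClumpThresholdScorer(
                    clump_p1=cfg.clump_p1, clump_r2=cfg.clump_r2,
                    clump_kb=cfg.clump_kb, p_threshold=cfg.p_threshold,
                    binary=True,
                )
                dscorer.fit(
                    G.dosages[gwas_mask],
                    gpheno["disease"].to_numpy(),
                    covariates=covar_gwas,
                    positions=G.variant_meta["pos"].to_numpy(),
                    chromosomes=G.variant_meta["chrom"].to_numpy(),
                    variant_ids=G.variant_meta["id"].to_numpy(),
                )
                dpgs = dscorer.predict(G.dosages)
                if dscorer.model_.n_variants and dpgs[gwas_mask].std() > 0:
                    pct = ev.choose_threshold(
                        dpgs[gwas_mask], gpheno["disease"].to_numpy()
                    )
                    pr = ev.precision_recall_profile(
                        bins, dpgs[ev_idx], pheno["disease"].to_numpy()[ev_idx],
                        pct, dpgs[gwas_mask],
                    )
                    res.update(disease_scorer=dscorer, disease_pgs=dpgs,
                               disease_threshold=pct, pr_profile=pr)
                    pio.write_table(out / "precision_recall.tsv", pr,
                                    cfg.seed, chash)

        if not done("evaluate"):
            stage = "diagnose"
            strata = diag.stratify_effects(scorer.model_)
            het = diag.het_by_bin(
                G.dosages[eval_mask], G.variant_meta["id"].to_numpy(),
                scorer.model_, bins, strata,
            )
            pvar = diag.pgs_variance_by_bin(pgs[eval_mask], bins, ref_bins)
            cut = cfg.close_far_cut
            if cut is None:
                cut = float(np.median(dres.standardized[eval_mask]))
            close = eval_mask & (dres.standardized <= cut)
            far = eval_mask & (dres.standardized > cut)
            covar_all = ev.build_covariates(pheno, include_array=False).to_numpy(float)
            ratios = {}
            for name, mask in (("close", close), ("far", far)):
                ratios[name] = diag.reestimate_effects(
                    G.dosages, pheno["trait"].to_numpy(), covar_all,
                    scorer.model_, G.variant_meta["id"].to_numpy(), mask,
                    n_pcs=cfg.n_gwas_pcs,
                )
            res.update(effect_strata=strata, het_by_bin=het,
                       pgs_variance=pvar, effect_ratios=ratios,
                       close_far_cut=cut)
            pio.write_table(out / "het_by_bin.tsv", het, cfg.seed, chash)
            pio.write_table(out / "pgs_variance.tsv", pvar, cfg.seed, chash)
            summary = {
                "close_far_cut": cut,
                "pgs_variance_slope": pvar.attrs["slope"],
                "effect_ratios": {
                    k: {kk: vv for kk, vv in v.items() if kk != "ratios"}
                    for k, v in ratios.items()
                },
            }
            if "profile" in res:
                summary["group_baseline"] = res["profile"].attrs["baseline"]
            pio.write_json(out / "diagnostics.json", summary, cfg.seed, chash)
    except Exception as exc:
        (out / "FAILED.json").write_text(json.dumps(
            {"stage": stage, "error": repr(exc)}, indent=2))
        raise
    return res
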