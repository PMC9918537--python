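"""End-to-end orchestration: simulate → QC → BSLMM → PGS → scans → report.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage; one
global seed is fanned out deterministically to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn(...)`` in a fixed stage order,
so one number reproduces a full run byte for byte.  Every defaulted
parameter is echoed into the run report, making implicit analysis choices
visible at run time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bslmm as bslmm_mod
from . import pgs as pgs_mod
from . import scan as scan_mod
from .qc import FilterConfig, apply_filters, impute_missing_mean, read_vcf
from .simulate import SimulationConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = ("simulate", "qc", "bslmm", "pgs", "scan")


@dataclass
class PipelineConfig:
    out_dir: str = "migtime_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    #: simulation parameters (ignored when a VCF is provided)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    #: externally provided inputs (enable running qc/scan without simulate)
    vcf: str | None = None
    phenotypes: str | None = None
    genes_bed: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    # BSLMM chain
    bslmm_iters: int = 10000
    bslmm_burn_in: int = 2000
    bslmm_thin: int = 8
    pip_threshold: float = 0.1
    # PGS
    pgs_reps: int = 100
    pgs_train_frac: float = 0.85
    pgs_r2_cutoff: float = 0.1
    pgs_window_kb: float = 250.0
    # scans
    window_size: int = 5000
    n_extremes: int = 10
    region_z_cutoff: float = 4.0
    region_merge_gap: int = 2

    def validate(self) -> None:
        errors = []
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            errors.append(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            if "qc" in self.stages and not self.vcf:
                errors.append("qc without simulate requires 'vcf'")
            needs_pheno = {"bslmm", "pgs", "scan"} & set(self.stages)
            if needs_pheno and not self.phenotypes:
                errors.append(f"stages {sorted(needs_pheno)} require 'phenotypes'")
        if self.pgs_reps < 1:
            errors.append("pgs_reps must be >= 1")
        if not 0 < self.pgs_train_frac < 1:
            errors.append("pgs_train_frac must lie in (0, 1)")
        if self.window_size < 1:
            errors.append("window_size must be >= 1")
        try:
            self.simulation.validate()
        except ValueError as exc:
            errors.append(str(exc))
        if errors:
            raise ValueError("invalid PipelineConfig: " + "; ".join(errors))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML (unknown keys are reported)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    sim_raw = raw.pop("simulation", {})
    filt_raw = raw.pop("filters", {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
    bad_sim = set(sim_raw) - sim_known
    if bad_sim:
        errors.append(f"unknown simulation keys: {sorted(bad_sim)}")
    filt_known = {f.name for f in dataclasses.fields(FilterConfig)}
    bad_filt = set(filt_raw) - filt_known
    if bad_filt:
        errors.append(f"unknown filter keys: {sorted(bad_filt)}")
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(errors))
    for key in ("samples_per_pop", "scaffold_lengths", "pop_latitudes",
                "pop_longitudes", "qual_range", "mq_range"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    if "sweep_region" in sim_raw and isinstance(sim_raw["sweep_region"], list):
        sim_raw["sweep_region"] = tuple(sim_raw["sweep_region"])
    if "stages" in raw and isinstance(raw["stages"], list):
        raw["stages"] = tuple(raw["stages"])
    cfg = PipelineConfig(
        simulation=SimulationConfig(**sim_raw),
        filters=FilterConfig(**filt_raw),
        **raw,
    )
    return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(STAGES, children)
    }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _covariate_matrix(pheno: pd.DataFrame, pc1: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [
            np.ones(len(pheno)),
            pheno["sex"].to_numpy(dtype=float),
            pheno["year"].to_numpy(dtype=float) - pheno["year"].mean(),
            pheno["age"].to_numpy(dtype=float),
            pc1,
        ]
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write a report.

    Returns the machine-readable run report (also written to
    ``<out_dir>/report.json``).  A stage failure raises immediately; outputs
    of completed stages stay on disk.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    report: dict = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "stages_run": [],
        "parameters": {
            "filters": dataclasses.asdict(cfg.filters),
            "simulation": dataclasses.asdict(cfg.simulation),
            "bslmm": {"n_iter": cfg.bslmm_iters, "burn_in": cfg.bslmm_burn_in,
                      "thin": cfg.bslmm_thin, "pip_threshold": cfg.pip_threshold},
            "pgs": {"reps": cfg.pgs_reps, "train_frac": cfg.pgs_train_frac,
                    "r2_cutoff": cfg.pgs_r2_cutoff, "window_kb": cfg.pgs_window_kb},
            "scan": {"window_size": cfg.window_size, "n_extremes": cfg.n_extremes,
                     "z_cutoff": cfg.region_z_cutoff,
                     "merge_gap": cfg.region_merge_gap},
        },
        "summary": {},
    }

    vcf_path = cfg.vcf
    pheno_path = cfg.phenotypes
    genes_path = cfg.genes_bed
    scaffold_lengths = None

    if "simulate" in cfg.stages:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=seeds["simulate"])
        G, var, pheno, effects = simulate_cohort(sim_cfg)
        paths = write_cohort(G, var, pheno, sim_cfg, out / "cohort")
        vcf_path, pheno_path = str(paths["vcf"]), str(paths["phenotypes"])
        genes_path = genes_path or str(paths["genes"])
        scaffold_lengths = dict(
            zip(sim_cfg.scaffold_names(), sim_cfg.scaffold_lengths)
        )
        report["stages_run"].append("simulate")
        report["summary"]["simulate"] = {
            "n_samples": G.n_samples,
            "n_variants": G.n_variants,
            "realized_pve": effects.attrs.get("realized_pve"),
        }

    pheno = pd.read_csv(pheno_path, sep="\t") if pheno_path else None

    G = var = G_imp = None
    if "qc" in cfg.stages:
        G_raw, var_raw = read_vcf(vcf_path)
        G, var, removed = apply_filters(G_raw, var_raw, cfg.filters)
        G_imp = impute_missing_mean(G)
        filt = pd.DataFrame(sorted(removed.items()), columns=["stage", "count"])
        _write_tsv(filt, out / "filter_report.tsv")
        report["stages_run"].append("qc")
        report["summary"]["qc"] = removed
    elif vcf_path:
        G, var = read_vcf(vcf_path)
        G_imp = impute_missing_mean(G)

    if pheno is not None and G is not None:
        # align phenotype rows to the genotype sample order
        pheno = pheno.set_index("sample_id").loc[G.samples].reset_index()

    y = pheno["arrival_date_ordinal"].to_numpy(dtype=float) if pheno is not None else None

    if "bslmm" in cfg.stages:
        pcs, _ = bslmm_mod.genotype_pca(G_imp.dosages, n_pcs=1)
        W = _covariate_matrix(pheno, pcs[:, 0])
        post = bslmm_mod.fit_bslmm(
            y, G_imp.dosages, W,
            n_iter=cfg.bslmm_iters, burn_in=cfg.bslmm_burn_in,
            thin=cfg.bslmm_thin, seed=seeds["bslmm"],
        )
        med, (lo, hi) = bslmm_mod.summarize_pve(post)
        pip_df = var[["scaffold", "pos"]].copy()
        pip_df["pip"] = post.pip
        _write_tsv(pip_df, out / "pip.tsv")
        samples_df = pd.DataFrame(
            {"pve": post.pve_samples, "h": post.h_samples, "rho": post.rho_samples,
             "log_pi": post.log_pi_samples, "n_gamma": post.n_gamma_samples}
        )
        _write_tsv(samples_df, out / "bslmm_samples.tsv")
        hits = bslmm_mod.pip_candidates(post, cfg.pip_threshold)
        report["stages_run"].append("bslmm")
        report["summary"]["bslmm"] = {
            "pve_median": med,
            "pve_eti89": [lo, hi],
            "rhat_pve": post.rhat_pve,
            "n_pip_candidates": int(len(hits)),
        }

    if "pgs" in cfg.stages:
        pcs, _ = bslmm_mod.genotype_pca(G_imp.dosages, n_pcs=1)
        W = _covariate_matrix(pheno, pcs[:, 0])
        cv = pgs_mod.jackknife_cv(
            y, G_imp.dosages, W, G_imp.samples,
            reps=cfg.pgs_reps, train_frac=cfg.pgs_train_frac,
            seed=seeds["pgs"], r2_cutoff=cfg.pgs_r2_cutoff,
            window_kb=cfg.pgs_window_kb, var=var,
        )
        _write_tsv(cv.reps, out / "pgs_cv.tsv")
        _write_tsv(cv.predictions, out / "pgs_predictions.tsv")
        rng_full = np.random.default_rng(seeds["pgs"] + 1)
        full_model = pgs_mod.build_pgs_model(
            y, G_imp.dosages, W, var, r2_cutoff=cfg.pgs_r2_cutoff,
            window_kb=cfg.pgs_window_kb, rng=rng_full,
        )
        full_r2 = pgs_mod._incremental_r2(full_model.score(G_imp.dosages), y, W)
        deciles = pgs_mod.decile_summary(cv, pheno)
        _write_tsv(deciles, out / "pgs_deciles.tsv")
        report["stages_run"].append("pgs")
        report["summary"]["pgs"] = {
            "cv_mean_r2": float(np.nanmean(cv.reps["r2"])),
            "full_sample_r2": float(full_r2),
            "decile_spearman": _decile_spearman(deciles),
        }

    if "scan" in cfg.stages:
        if scaffold_lengths is None:
            lengths: dict[str, int] = {}
            for scaf, grp in var.groupby("scaffold", sort=False):
                lengths[scaf] = int(grp["pos"].max())
            scaffold_lengths = lengths
        windows = scan_mod.make_windows(scaffold_lengths, cfg.window_size)
        groups = scan_mod.select_extremes(pheno, cfg.n_extremes)
        scan_pheno = scan_mod.wc_fst_window(G, groups.early, groups.late, windows, var)
        # structural contrast: southernmost vs northernmost populations
        lat_by_pop = pheno.groupby("population")["latitude"].mean()
        south = pheno.loc[pheno["population"] == lat_by_pop.idxmin(), "sample_id"]
        north = pheno.loc[pheno["population"] == lat_by_pop.idxmax(), "sample_id"]
        scan_pop = scan_mod.wc_fst_window(G, tuple(south), tuple(north), windows, var)
        delta = scan_mod.net_fst(scan_pheno, scan_pop)
        pi_early = scan_mod.pi_window(G, groups.early, windows, var)
        td_early = scan_mod.tajimas_d_window(G, groups.early, windows, var)
        for name, df in (
            ("fst_phenotype", scan_pheno), ("fst_population", scan_pop),
            ("delta_fst", delta), ("pi_early", pi_early),
            ("tajimas_d_early", td_early),
        ):
            _write_tsv(df, out / f"scan_{name}.tsv")
        regions = scan_mod.detect_region(delta, cfg.region_z_cutoff, cfg.region_merge_gap)
        _write_tsv(regions, out / "regions.tsv")
        gene_counts = []
        if genes_path and len(regions):
            genes = pd.read_csv(
                genes_path, sep="\t", header=None,
                names=["scaffold", "start", "end", "name", "score", "strand"],
            )
            overlaps = scan_mod.genes_in_region(regions, genes)
            gene_counts = [int(len(o)) for o in overlaps]
            pd.concat(
                [o.assign(region=i) for i, o in enumerate(overlaps)],
                ignore_index=True,
            ).to_csv(out / "region_genes.tsv", sep="\t", index=False)
        report["stages_run"].append("scan")
        report["summary"]["scan"] = {
            "n_windows": int(len(windows)),
            "n_regions": int(len(regions)),
            "regions": regions.to_dict(orient="records"),
            "genes_per_region": gene_counts,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _decile_spearman(deciles: pd.DataFrame) -> float:
    from scipy.stats import spearmanr

    rho = spearmanr(deciles["decile"], deciles["mean_arrival"]).statistic
    return float(rho)
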