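"""Synthetic cohort generator for migration-timing genomics.

Generates structured diploid cohorts with the statistical features the
downstream analyses assume: two or more populations with tunable background
differentiation (Balding–Nichols model), an optional localized
high-differentiation / low-diversity ("sweep") region, a polygenic arrival
phenotype with a configurable genetic variance fraction and a latitudinal
cline, covariates, and missing genotypes.  Everything is reproducible from a
single seed and written to plain-text VCF / TSV / BED so the whole pipeline
is testable without any external download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "balding_nichols_freqs",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_cohort",
    "write_cohort",
]

#: phenotype table column order shared with the rest of the pipeline
PHENOTYPE_COLUMNS = [
    "sample_id",
    "arrival_date_ordinal",
    "sex",
    "year",
    "age",
    "colony",
    "population",
    "latitude",
    "longitude",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults emulate the study design this package targets: 87 tracked
    individuals split between a southern (early-arriving, low-latitude) and a
    northern (late-arriving) breeding region, a ~131-day span of spring
    arrival dates driven by a latitudinal cline plus genetics, a 2 Mb
    phenotype-linked sweep region, ~20% missing genotypes, and a genetic
    variance fraction (PVE) of 0.74.
    """

    n_pops: int = 2
    samples_per_pop: tuple[int, ...] = (44, 43)
    n_scaffolds: int = 2
    scaffold_lengths: tuple[int, ...] = (10_000_000, 5_000_000)
    n_loci: int = 5000
    background_fst: float = 0.05
    #: (scaffold name, start bp, end bp), 0-based half-open; None disables
    sweep_region: tuple[str, int, int] | None = ("scaf_1", 4_000_000, 6_000_000)
    #: "phenotype": sweep loci track a latent haplotype with a large effect on
    #: arrival date, shared across populations.  "population": sweep loci are
    #: extra-differentiated between populations but unlinked to the phenotype.
    sweep_mode: str = "phenotype"
    sweep_fst: float = 0.5
    sweep_diversity_factor: float = 0.3
    sweep_hap_freq: float = 0.5
    sweep_flip_rate: float = 0.05
    #: share of genetic variance carried by the sweep haplotype (phenotype mode)
    sweep_pheno_share: float = 0.4
    n_causal: int = 50
    target_pve: float = 0.74
    #: share of the non-sweep genetic variance that is infinitesimal
    polygenic_frac: float = 0.3
    #: sd (days) of the structure-adjusted phenotype (genetic + noise)
    phenotype_sd: float = 20.0
    #: days of arrival delay per degree latitude
    cline_slope: float = 1.5
    baseline_arrival: float = 90.0
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 1.0, "year": 0.5, "age": 0.5}
    )
    pop_latitudes: tuple[float, ...] = (27.0, 54.0)
    pop_longitudes: tuple[float, ...] = (-81.0, -113.0)
    missing_rate: float = 0.2
    qual_range: tuple[float, float] = (30.0, 90.0)
    mq_range: tuple[float, float] = (30.0, 60.0)
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_pops < 1:
            errors.append("n_pops must be >= 1")
        if len(self.samples_per_pop) != self.n_pops:
            errors.append("samples_per_pop length must equal n_pops")
        if any(s < 2 for s in self.samples_per_pop):
            errors.append("each population needs >= 2 samples")
        if len(self.scaffold_lengths) != self.n_scaffolds:
            errors.append("scaffold_lengths length must equal n_scaffolds")
        if not 0.0 <= self.background_fst < 1.0:
            errors.append("background_fst must lie in [0, 1)")
        if not 0.0 <= self.sweep_fst < 1.0:
            errors.append("sweep_fst must lie in [0, 1)")
        if not 0.0 < self.sweep_diversity_factor <= 1.0:
            errors.append("sweep_diversity_factor must lie in (0, 1]")
        if self.sweep_region is not None:
            name, start, end = self.sweep_region
            idx = self._scaffold_index(name)
            if idx is None:
                errors.append(f"sweep scaffold {name!r} not in layout")
            elif not (0 <= start < end <= self.scaffold_lengths[idx]):
                errors.append("sweep_region must lie within its scaffold")
            if self.sweep_mode not in ("phenotype", "population"):
                errors.append("sweep_mode must be 'phenotype' or 'population'")
        if self.n_causal > self.n_loci:
            errors.append("n_causal must be <= n_loci")
        if not 0.0 <= self.target_pve <= 1.0:
            errors.append("target_pve must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            errors.append("missing_rate must lie in [0, 1)")
        if len(self.pop_latitudes) != self.n_pops:
            errors.append("pop_latitudes length must equal n_pops")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))

    def _scaffold_index(self, name: str) -> int | None:
        names = self.scaffold_names()
        return names.index(name) if name in names else None

    def scaffold_names(self) -> list[str]:
        return [f"scaf_{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_pop))


@dataclass
class GenotypeMatrix:
    """Individuals × variants dosage matrix; missing entries are NaN."""

    samples: list[str]
    dosages: np.ndarray  # (n_samples, n_variants) float, values {0,1,2,NaN}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.dosages.copy())


def balding_nichols_freqs(
    p_anc: float, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-population allele frequencies under the Balding–Nichols model.

    Frequencies follow Beta(p(1-F)/F, (1-p)(1-F)/F): mean ``p_anc`` and
    variance ``fst * p_anc * (1 - p_anc)``.  ``fst = 0`` returns ``p_anc``
    exactly for every population.
    """
    eps = 1e-6
    if not eps < p_anc < 1 - eps:
        raise ValueError(f"degenerate ancestral frequency {p_anc}")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")
    if fst == 0.0:
        return np.full(n_pops, p_anc)
    scale = (1.0 - fst) / fst
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=n_pops)


def _place_loci(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign loci to scaffolds (proportional to length) at sorted unique
    uniform positions; flag loci inside the sweep region."""
    lengths = np.asarray(config.scaffold_lengths, dtype=float)
    probs = lengths / lengths.sum()
    counts = rng.multinomial(config.n_loci, probs)
    rows = []
    names = config.scaffold_names()
    for idx, (name, count, length) in enumerate(zip(names, counts, lengths)):
        if count == 0:
            continue
        # rejection-free unique draw: sample extra then dedupe
        pos = np.unique(rng.integers(0, int(length), size=count * 2))
        while pos.size < count:
            pos = np.unique(
                np.concatenate([pos, rng.integers(0, int(length), size=count)])
            )
        pos = np.sort(rng.choice(pos, size=count, replace=False))
        for p in pos:
            rows.append((name, int(p)))
    var = pd.DataFrame(rows, columns=["scaffold", "pos0"])
    var["pos"] = var["pos0"] + 1  # 1-based, as in VCF
    var["is_sweep"] = False
    if config.sweep_region is not None:
        name, start, end = config.sweep_region
        inside = (var["scaffold"] == name) & (var["pos0"] >= start) & (var["pos0"] < end)
        var.loc[inside, "is_sweep"] = True
    return var


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the genotype matrix and variant table for a cohort.

    Background loci: ancestral frequencies uniform on [0.05, 0.95], population
    frequencies Balding–Nichols at ``background_fst``, genotypes Binomial(2, p).
    Sweep loci: see :class:`SimulationConfig.sweep_mode`.  Missing entries are
    masked at ``missing_rate``; QUAL/MQ drawn uniform from the configured
    ranges.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    var = _place_loci(config, rng)
    n_loci = len(var)
    n = config.n_samples
    pop_of = np.repeat(np.arange(config.n_pops), config.samples_per_pop)

    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    dosages = np.empty((n, n_loci), dtype=float)
    is_sweep = var["is_sweep"].to_numpy()

    # population frequencies, locus by locus
    freqs = np.empty((config.n_pops, n_loci))
    for j in range(n_loci):
        fst = config.sweep_fst if (is_sweep[j] and config.sweep_mode == "population") else config.background_fst
        freqs[:, j] = balding_nichols_freqs(p_anc[j], fst, config.n_pops, rng)

    if config.sweep_region is not None and config.sweep_mode == "population":
        # depress diversity in the designated "early" (lowest-latitude) population
        early = int(np.argmin(config.pop_latitudes))
        sweep_cols = np.where(is_sweep)[0]
        f = freqs[early, sweep_cols]
        minor = np.minimum(f, 1 - f) * config.sweep_diversity_factor
        freqs[early, sweep_cols] = np.where(f <= 0.5, minor, 1 - minor)

    dosages[:] = rng.binomial(2, freqs[pop_of, :][:, np.arange(n_loci)]).astype(float)

    sweep_hap = None
    if config.sweep_region is not None and config.sweep_mode == "phenotype":
        # sweep loci track a latent haplotype shared across populations: each
        # individual carries two haplotype indicators; a swept copy is ALT at
        # every sweep locus (minus a small flip rate, i.e. the haplotype is
        # nearly monomorphic), while an ancestral copy segregates at the
        # locus-specific ancestral frequency.  This yields tight LD, a strong
        # allele-frequency contrast between carriers and non-carriers, and
        # reduced diversity within carrier-enriched groups — the classic
        # partial-sweep signature.
        sweep_cols = np.where(is_sweep)[0]
        h = rng.binomial(1, config.sweep_hap_freq, size=(n, 2))
        sweep_hap = h.sum(axis=1)
        for j in sweep_cols:
            flips = rng.binomial(1, config.sweep_flip_rate, size=(n, 2))
            anc = rng.binomial(1, p_anc[j], size=(n, 2))
            alleles = np.where(h == 1, 1 - flips, anc)
            dosages[:, j] = alleles.sum(axis=1).astype(float)

    # record true (pre-masking) frequencies, then mask
    full = dosages.copy()
    if config.missing_rate > 0:
        mask = rng.random((n, n_loci)) < config.missing_rate
        dosages[mask] = np.nan

    var["ref"] = "A"
    var["alt"] = "T"
    var["qual"] = rng.uniform(*config.qual_range, size=n_loci).round(2)
    var["mq"] = rng.uniform(*config.mq_range, size=n_loci).round(2)
    var["p_anc"] = p_anc

    samples = [f"ind_{i + 1:03d}" for i in range(n)]
    G = GenotypeMatrix(samples, dosages)
    G.full_dosages = full  # pre-masking copy, used by simulate_phenotype
    G.sweep_hap = sweep_hap
    G.pop_of = pop_of
    return G, var


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


def simulate_phenotype(
    G: GenotypeMatrix,
    var: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spring arrival dates for a cohort.

    The phenotype is baseline + latitudinal cline + covariate terms + a
    genetic value g + Gaussian noise.  g combines sparse causal effects, an
    infinitesimal polygenic term and (in phenotype-linked sweep mode) the
    sweep-haplotype effect; g and the noise are rescaled so that the realized
    var(g) / (var(g) + var(noise)) equals ``target_pve`` exactly.  The cline
    and covariates add structured variance on top, the way breeding-site
    latitude structures arrival dates in the wild.

    Returns the phenotype/covariate table and a table of true causal effects
    (for recovery tests).
    """
    config.validate()
    n = G.n_samples
    full = getattr(G, "full_dosages", None)
    if full is None:
        full = G.dosages
    pop_of = getattr(G, "pop_of", np.zeros(n, dtype=int))

    # --- genetic value -----------------------------------------------------
    # causal loci must have no missing values in the matrix the genetic value
    # is computed from (the generator's pre-masking dosages qualify en bloc)
    complete = ~np.isnan(full).any(axis=0)
    is_sweep = var["is_sweep"].to_numpy()
    candidates = np.where(complete & ~is_sweep)[0]
    if config.n_causal > 0 and candidates.size < config.n_causal:
        raise ValueError("not enough complete non-sweep loci to draw causals from")

    sweep_share = (
        config.sweep_pheno_share
        if (config.sweep_region is not None and config.sweep_mode == "phenotype")
        else 0.0
    )
    sparse_share = (1 - sweep_share) * (1 - config.polygenic_frac)
    poly_share = (1 - sweep_share) * config.polygenic_frac

    causal_idx = (
        np.sort(rng.choice(candidates, size=config.n_causal, replace=False))
        if config.n_causal > 0
        else np.array([], dtype=int)
    )
    raw_effects = rng.normal(size=config.n_causal)
    g_sparse = full[:, causal_idx] @ raw_effects if config.n_causal else np.zeros(n)
    poly_effects = rng.normal(size=full.shape[1]) / np.sqrt(max(full.shape[1], 1))
    g_poly = full @ poly_effects
    if sweep_share > 0:
        sweep_cols = np.where(is_sweep)[0]
        # negative sign: carriers of the swept haplotype arrive earlier
        g_sweep = -full[:, sweep_cols].mean(axis=1) if sweep_cols.size else np.zeros(n)
    else:
        g_sweep = np.zeros(n)

    parts, shares = [], []
    for comp, share in ((g_sparse, sparse_share), (g_poly, poly_share), (g_sweep, sweep_share)):
        if share > 0 and comp.std() > 0:
            parts.append(_standardize(comp) * np.sqrt(share))
            shares.append(share)
    g = np.sum(parts, axis=0) if parts else np.zeros(n)

    v_g = config.target_pve * config.phenotype_sd**2
    v_e = (1 - config.target_pve) * config.phenotype_sd**2
    if config.target_pve > 0:
        if g.std() == 0:
            raise ValueError("target_pve > 0 requires non-zero genetic variance")
        g = _standardize(g) * np.sqrt(v_g)
    else:
        g = np.zeros(n)

    noise = rng.normal(size=n)
    if config.target_pve < 1:
        # residualize the noise draw against g so the realized variance ratio
        # is exact, then scale
        if g.std() > 0:
            gc = g - g.mean()
            noise = noise - gc * (noise @ gc) / (gc @ gc)
        noise = _standardize(noise) * np.sqrt(v_e)
    else:
        noise = np.zeros(n)

    # --- fixed effects -----------------------------------------------------
    latitude = np.asarray(config.pop_latitudes)[pop_of]
    longitude = np.asarray(config.pop_longitudes)[pop_of]
    sex = rng.integers(0, 2, size=n)
    year = rng.integers(2008, 2016, size=n)
    age = rng.integers(1, 6, size=n)
    fixed = config.cline_slope * (latitude - latitude.mean())
    for name, cov in (("sex", sex), ("year", year), ("age", age)):
        slope = config.covariate_effects.get(name, 0.0)
        fixed = fixed + slope * (cov - cov.mean())

    y = config.baseline_arrival + fixed + g + noise

    pheno = pd.DataFrame(
        {
            "sample_id": G.samples,
            "arrival_date_ordinal": y,
            "sex": sex,
            "year": year,
            "age": age,
            "colony": [f"colony_{p + 1}" for p in pop_of],
            "population": [f"pop_{p + 1}" for p in pop_of],
            "latitude": latitude,
            "longitude": longitude,
        }
    )[PHENOTYPE_COLUMNS]

    # per-component scaling applied to raw effects for the truth table
    effects = pd.DataFrame(
        {
            "variant_index": causal_idx,
            "scaffold": var["scaffold"].to_numpy()[causal_idx],
            "pos": var["pos"].to_numpy()[causal_idx],
            "raw_effect": raw_effects,
        }
    )
    effects.attrs["genetic_values"] = g
    effects.attrs["noise"] = noise
    effects.attrs["realized_pve"] = (
        float(g.var() / (g.var() + noise.var())) if (g.var() + noise.var()) > 0 else 0.0
    )
    return pheno, effects


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: genotypes + phenotype in one reproducible call."""
    G, var = simulate_genotypes(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pheno, effects = simulate_phenotype(G, var, config, rng)
    return G, var, pheno, effects


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def _format_gt(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]


def write_vcf(G: GenotypeMatrix, var: pd.DataFrame, path: Path,
              scaffold_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT genotypes, QUAL column and MQ INFO."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if scaffold_lengths:
            for name, length in scaffold_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, row in enumerate(var.itertuples(index=False)):
            gts = "\t".join(_format_gt(d) for d in G.dosages[:, j])
            fh.write(
                f"{row.scaffold}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:g}\t.\tMQ={row.mq:g}\tGT\t{gts}\n"
            )


def write_cohort(
    G: GenotypeMatrix,
    var: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: SimulationConfig,
    out_dir: Path,
    n_genes_in_sweep: int = 13,
) -> dict[str, Path]:
    """Write the cohort as VCF + phenotype TSV + gene BED + provenance JSON.

    The gene annotation plants ``n_genes_in_sweep`` non-overlapping genes
    inside the sweep region (if configured), mirroring the kind of candidate
    region + gene list the downstream overlap stage reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lengths = dict(zip(config.scaffold_names(), config.scaffold_lengths))

    vcf_path = out_dir / "cohort.vcf"
    write_vcf(G, var, vcf_path, lengths)

    pheno_path = out_dir / "phenotypes.tsv"
    phenotypes.to_csv(pheno_path, sep="\t", index=False, float_format="%.6f")

    bed_path = out_dir / "genes.bed"
    genes = make_gene_annotation(config, n_genes_in_sweep)
    genes.to_csv(bed_path, sep="\t", index=False, header=False)

    prov_path = out_dir / "provenance.json"
    cfg = dataclasses.asdict(config)
    with open(prov_path, "w") as fh:
        json.dump({"config": cfg}, fh, indent=2, default=str)

    return {
        "vcf": vcf_path,
        "phenotypes": pheno_path,
        "genes": bed_path,
        "provenance": prov_path,
    }


def make_gene_annotation(config: SimulationConfig, n_genes_in_sweep: int = 13) -> pd.DataFrame:
    """Deterministic BED3+name gene annotation with ``n_genes_in_sweep`` genes
    evenly spaced inside the sweep region (strand alternating)."""
    rows = []
    if config.sweep_region is not None and n_genes_in_sweep > 0:
        name, start, end = config.sweep_region
        span = end - start
        slot = span // n_genes_in_sweep
        for i in range(n_genes_in_sweep):
            gs = start + i * slot + slot // 4
            ge = gs + max(slot // 2, 1)
            rows.append((name, int(gs), int(min(ge, end)), f"gene_{i + 1:02d}",
                         0, "+" if i % 2 == 0 else "-"))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "name", "score", "strand"])
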