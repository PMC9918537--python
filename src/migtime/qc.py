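"""Variant quality control: VCF input, site filters, mean-dosage imputation.

Filters follow the conventional resequencing recipe: biallelic sites only,
QUAL > 20, MQ > 20, per-site missingness <= 20%, MAF > 0.05 (strict), and an
exact Hardy–Weinberg equilibrium test.  Mean-dosage imputation replaces
missing genotypes with twice the alt-allele frequency of the non-missing
calls, which leaves per-variant allele frequencies (and column means)
unchanged — a deterministic, LD-free stand-in for haplotype imputation that
is adequate for the downstream linear models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import GenotypeMatrix

__all__ = [
    "FilterConfig",
    "read_vcf",
    "hwe_exact_test",
    "apply_filters",
    "impute_missing_mean",
]


@dataclass(frozen=True)
class FilterConfig:
    """Site-filter thresholds. ``None`` disables the corresponding stage."""

    qual_min: float | None = 20.0
    mq_min: float | None = 20.0
    max_missing_fraction: float | None = 0.20
    maf_min: float | None = 0.05
    #: sites with exact-HWE p-value < hwe_alpha are removed; the conventional
    #: sequencing-data cutoff is used as default
    hwe_alpha: float | None = 1e-6
    biallelic_only: bool = True


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF 4.x with GT into a dosage matrix and variant table.

    Dosage is the alt-allele count (0/1/2); any genotype containing a missing
    allele (``./.`` or half-calls) is treated as missing.  Multiallelic
    records are retained in the table but flagged ``biallelic=False`` so the
    filter stage removes them.  Positions stay 1-based as in the VCF.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        reader = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(reader.samples)
    rows, dosage_rows = [], []
    for i, rec in enumerate(reader):
        try:
            alts = rec.ALT if rec.ALT else []
            # gts012: 0,1,2 = alt dosage, 3 = unknown (incl. half-calls)
            gt = rec.gt_types.astype(float)
            gt[gt == 3] = np.nan
            mq = rec.INFO.get("MQ")
            rows.append(
                (
                    rec.CHROM,
                    rec.POS,
                    rec.REF,
                    ",".join(alts) if alts else ".",
                    rec.QUAL if rec.QUAL is not None else np.nan,
                    float(mq) if mq is not None else np.nan,
                    len(alts) == 1,
                )
            )
            dosage_rows.append(gt)
        except Exception as exc:
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc

    var = pd.DataFrame(
        rows, columns=["scaffold", "pos", "ref", "alt", "qual", "mq", "biallelic"]
    )
    dosages = (
        np.asarray(dosage_rows, dtype=float).T
        if dosage_rows
        else np.empty((len(samples), 0))
    )
    G = GenotypeMatrix(samples, dosages)
    var["af"] = G.allele_freq() if len(var) else np.array([])
    return G, var


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test on one site's genotype counts.

    Conditions on the observed allele counts; the p-value sums the
    probabilities of every heterozygote count (same parity, same allele
    totals) that is no more probable than the observed one under the
    hypergeometric-type null.  Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no genotyped individuals at site")
    n_a = 2 * n_aa + n_Aa  # minor-coded allele count (either allele works)
    rare = min(n_a, 2 * n - n_a)
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | allele counts) ∝ -log(h! hom_r! hom_c!) + h log 2
    logp = hets * np.log(2.0) - (
        gammaln(hets + 1) + gammaln(hom_rare + 1) + gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size != 1:  # pragma: no cover - inconsistent counts cannot occur
        raise RuntimeError("observed heterozygote count not in support")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = col[~np.isnan(col)]
    return int((ok == 0).sum()), int((ok == 1).sum()), int((ok == 2).sum())


FILTER_ORDER = ("biallelic", "qual", "mq", "missingness", "maf", "hwe")


def apply_filters(
    G: GenotypeMatrix,
    var: pd.DataFrame,
    cfg: FilterConfig = FilterConfig(),
    order: tuple[str, ...] = FILTER_ORDER,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict[str, int]]:
    """Apply site filters in a fixed order and report removals per stage.

    Default order: biallelic → QUAL → MQ → missingness → MAF → HWE.  Each
    criterion is a per-site property of the raw input, so the surviving set
    is independent of stage order; only the attribution counts (first failing
    stage per variant) depend on it.  MAF uses non-missing calls and the
    inequality is strict (MAF must exceed the cutoff).  Records without an MQ
    value fail the MQ filter.
    """
    if set(order) != set(FILTER_ORDER):
        raise ValueError(f"order must be a permutation of {FILTER_ORDER}")
    n_var = G.n_variants
    keep = np.ones(n_var, dtype=bool)
    report: dict[str, int] = {}

    def passing_mask(name: str) -> np.ndarray | None:
        if name == "biallelic":
            if not cfg.biallelic_only:
                return None
            return var["biallelic"].to_numpy(dtype=bool)
        if name == "qual":
            if cfg.qual_min is None:
                return None
            qual = var["qual"].to_numpy(dtype=float)
            return np.nan_to_num(qual, nan=-np.inf) > cfg.qual_min
        if name == "mq":
            if cfg.mq_min is None:
                return None
            mq = var["mq"].to_numpy(dtype=float)
            return np.nan_to_num(mq, nan=-np.inf) > cfg.mq_min
        if name == "missingness":
            if cfg.max_missing_fraction is None:
                return None
            return G.missing_fraction() <= cfg.max_missing_fraction
        if name == "maf":
            if cfg.maf_min is None:
                return None
            af = G.allele_freq()
            maf = np.minimum(af, 1 - af)
            return np.nan_to_num(maf, nan=-1.0) > cfg.maf_min
        if name == "hwe":
            if cfg.hwe_alpha is None:
                return None
            pvals = np.ones(n_var)
            for j in range(n_var):
                counts = _genotype_counts(G.dosages[:, j])
                pvals[j] = hwe_exact_test(*counts) if sum(counts) else 0.0
            return pvals >= cfg.hwe_alpha
        raise AssertionError(name)

    for name in order:
        mask = passing_mask(name)
        if mask is None:
            continue
        removed = keep & ~mask
        report[name] = int(removed.sum())
        keep[removed] = False

    report["n_input"] = n_var
    report["n_pass"] = int(keep.sum())
    G_out = GenotypeMatrix(list(G.samples), G.dosages[:, keep].copy())
    var_out = var.loc[keep].reset_index(drop=True)
    var_out["af"] = G_out.allele_freq() if len(var_out) else np.array([])
    return G_out, var_out, report


def impute_missing_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by 2 × alt-allele frequency of non-missing
    calls at the variant.  Column means (hence allele frequencies) are
    preserved to machine precision."""
    dosages = G.dosages.copy()
    missing = np.isnan(dosages)
    if missing.all(axis=0).any():
        bad = int(np.flatnonzero(missing.all(axis=0))[0])
        raise ValueError(f"variant column {bad} has all calls missing")
    if missing.any():
        # 2 * allele frequency == column mean of the non-missing dosages
        fill = np.nanmean(dosages, axis=0)
        dosages[missing] = np.broadcast_to(fill, dosages.shape)[missing]
    return GenotypeMatrix(list(G.samples), dosages)
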