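"""Windowed differentiation and diversity scans.

Weir–Cockerham F_ST between phenotype-extreme groups, net differentiation
(ΔF_ST: the phenotype contrast minus a population contrast, removing
structure-driven signal), nucleotide diversity π, Tajima's D, robust-Z
elevated-region detection and gene overlap — all in non-overlapping windows
(5 kb default) tiled from coordinate 0 of each scaffold.

Window F_ST is the ratio-of-sums ("weighted") estimator: per-site variance
components a (among groups), b (among individuals within groups) and
c (within individuals) from Weir & Cockerham (1984), summed over the usable
sites of the window.  π and Tajima's D treat the 2m genotyped diploids of a
group as 2m haplotypes (Hardy–Weinberg within group; no phasing).

Coordinates: variant positions are 1-based as read from VCF; windows and all
output intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "GroupAssignment",
    "make_windows",
    "select_extremes",
    "wc_fst_sites",
    "wc_fst_window",
    "net_fst",
    "pi_window",
    "tajimas_d_window",
    "detect_region",
    "genes_in_region",
]


@dataclass(frozen=True)
class GroupAssignment:
    """Sample ids of the two contrast groups (disjoint)."""

    early: tuple[str, ...]
    late: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.early) & set(self.late):
            raise ValueError("contrast groups overlap")
        if min(len(self.early), len(self.late)) < 2:
            raise ValueError("each group needs >= 2 samples")


def select_extremes(phenotypes: pd.DataFrame, k: int = 10) -> GroupAssignment:
    """The k earliest and k latest arrivals; ties broken by sample id."""
    if 2 * k > len(phenotypes):
        raise ValueError(f"k={k} overlaps with n={len(phenotypes)} phenotyped samples")
    ordered = phenotypes.sort_values(
        ["arrival_date_ordinal", "sample_id"], kind="stable"
    )
    early = tuple(ordered["sample_id"].head(k))
    late_pool = phenotypes.sort_values(
        ["arrival_date_ordinal", "sample_id"], ascending=[False, True], kind="stable"
    )
    late = tuple(late_pool["sample_id"].head(k))
    return GroupAssignment(early=early, late=late)


def make_windows(
    scaffold_lengths: dict[str, int], size: int = 5000
) -> pd.DataFrame:
    """Non-overlapping windows tiled from 0; terminal short windows retained
    and flagged ``terminal=True``."""
    rows = []
    for name, length in scaffold_lengths.items():
        starts = np.arange(0, length, size)
        for s in starts:
            e = min(s + size, length)
            rows.append((name, int(s), int(e), e - s < size))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "terminal"])


def _subset(G: GenotypeMatrix, sample_ids) -> np.ndarray:
    index = {s: i for i, s in enumerate(G.samples)}
    missing = [s for s in sample_ids if s not in index]
    if missing:
        raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
    return G.dosages[[index[s] for s in sample_ids], :]


def _group_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n genotyped, alt freq, observed het freq) for one group."""
    ok = ~np.isnan(g)
    m = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(g, axis=0) / (2.0 * m)
        h = np.nansum(g == 1, axis=0) / m
    return m, p, h


def wc_fst_sites(g1: np.ndarray, g2: np.ndarray) -> pd.DataFrame:
    """Per-site Weir–Cockerham variance components for a two-group contrast.

    Returns a frame with columns a, b, c and ``usable`` (>= 2 genotyped
    diploids in each group).  Vectorized over sites; the ratio-of-sums
    window estimate is Σa / Σ(a+b+c).
    """
    m1, p1, h1 = _group_stats(g1)
    m2, p2, h2 = _group_stats(g2)
    usable = (m1 >= 2) & (m2 >= 2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = m1 + m2
        nbar = n_tot / r
        nc = (n_tot - (m1**2 + m2**2) / n_tot) / (r - 1)
        pbar = (m1 * p1 + m2 * p2) / n_tot
        s2 = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (m1 * h1 + m2 * h2) / n_tot
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return pd.DataFrame({"a": a, "b": b, "c": c, "usable": usable})


def _window_index(var: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Map each variant to the row index of its window (-1 if none)."""
    idx = np.full(len(var), -1, dtype=int)
    for scaf, wdf in windows.groupby("scaffold", sort=False):
        in_scaf = np.flatnonzero((var["scaffold"] == scaf).to_numpy())
        if in_scaf.size == 0:
            continue
        pos0 = var["pos"].to_numpy()[in_scaf] - 1  # 1-based VCF -> 0-based
        starts = wdf["start"].to_numpy()
        ends = wdf["end"].to_numpy()
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        idx[in_scaf[ok]] = wdf.index.to_numpy()[j[ok]]
    return idx


def _aggregate(
    windows: pd.DataFrame,
    widx: np.ndarray,
    site_ok: np.ndarray,
    numer: np.ndarray,
    denom: np.ndarray | None,
    kind: str,
    extra: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    out = windows[["scaffold", "start", "end"]].copy()
    nw = len(windows)
    ok = site_ok & (widx >= 0)
    n_sites = np.bincount(widx[ok], minlength=nw)
    num = np.bincount(widx[ok], weights=numer[ok], minlength=nw)
    out["n_variant_sites"] = n_sites
    if denom is not None:
        den = np.bincount(widx[ok], weights=denom[ok], minlength=nw)
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(den != 0, num / den, np.nan)
    else:
        value = num
    valid = n_sites > 0
    out["statistic"] = kind
    out["value"] = np.where(valid, value, np.nan)
    out["valid"] = valid & ~np.isnan(out["value"].to_numpy())
    if extra:
        for k, v in extra.items():
            out[k] = v
    return out


def wc_fst_window(
    G: GenotypeMatrix,
    group1,
    group2,
    windows: pd.DataFrame,
    var: pd.DataFrame,
) -> pd.DataFrame:
    """Ratio-of-sums Weir–Cockerham F_ST per window for two sample groups."""
    g1, g2 = _subset(G, group1), _subset(G, group2)
    if (~np.isnan(g1)).sum(axis=0).max(initial=0) < 2 or (
        (~np.isnan(g2)).sum(axis=0).max(initial=0) < 2
    ):
        raise ValueError("each group needs >= 2 genotyped individuals somewhere")
    comp = wc_fst_sites(g1, g2)
    widx = _window_index(var, windows)
    a = np.nan_to_num(comp["a"].to_numpy())
    abc = np.nan_to_num((comp["a"] + comp["b"] + comp["c"]).to_numpy())
    return _aggregate(
        windows, widx, comp["usable"].to_numpy(), a, abc, "fst"
    )


def net_fst(scan_pheno: pd.DataFrame, scan_pop: pd.DataFrame) -> pd.DataFrame:
    """ΔF_ST per window: phenotype-contrast F_ST minus population-contrast
    F_ST.  Negative values are retained; validity requires both inputs."""
    key = ["scaffold", "start", "end"]
    if len(scan_pheno) != len(scan_pop) or not (
        scan_pheno[key].reset_index(drop=True).equals(
            scan_pop[key].reset_index(drop=True)
        )
    ):
        raise ValueError("scans are not tiled on identical windows")
    out = scan_pheno[key].copy()
    out["n_variant_sites"] = np.minimum(
        scan_pheno["n_variant_sites"].to_numpy(), scan_pop["n_variant_sites"].to_numpy()
    )
    out["statistic"] = "delta_fst"
    valid = scan_pheno["valid"].to_numpy() & scan_pop["valid"].to_numpy()
    with np.errstate(invalid="ignore"):
        out["value"] = np.where(
            valid, scan_pheno["value"].to_numpy() - scan_pop["value"].to_numpy(), np.nan
        )
    out["valid"] = valid
    return out


def pi_window(
    G: GenotypeMatrix, group, windows: pd.DataFrame, var: pd.DataFrame
) -> pd.DataFrame:
    """Nucleotide diversity per window within one group.

    Per-site unbiased heterozygosity 2p(1−p)·2m/(2m−1) over the m genotyped
    diploids, summed across variant sites and divided by the window span in
    bp (invariant positions contribute length only).
    """
    g = _subset(G, group)
    if g.shape[0] < 2:
        raise ValueError("group size must be >= 2")
    m, p, _ = _group_stats(g)
    usable = m >= 2
    with np.errstate(invalid="ignore"):
        het = 2.0 * p * (1 - p) * (2 * m) / (2 * m - 1)
    het = np.nan_to_num(het)
    widx = _window_index(var, windows)
    out = _aggregate(windows, widx, usable, het, None, "pi")
    span = (windows["end"] - windows["start"]).to_numpy().astype(float)
    out["value"] = out["value"].fillna(0.0) / span
    # a window with zero variant sites has π = 0 by definition, and is valid
    out["valid"] = True
    return out


def _tajima_constants(n: int) -> dict[str, float]:
    """Standard Tajima (1989) constants for n haplotypes."""
    if n < 4:
        raise ValueError("need >= 4 haplotypes for Tajima's D")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_window(
    G: GenotypeMatrix, group, windows: pd.DataFrame, var: pd.DataFrame
) -> pd.DataFrame:
    """Tajima's D per window within one group.

    S counts sites segregating among the genotyped calls; the pairwise
    estimator is the same unbiased heterozygosity sum used for π.  The
    haplotype count n for the constants is 2 × (rounded mean number of
    genotyped diploids over the window's segregating sites); windows with
    S = 0 are flagged invalid.
    """
    g = _subset(G, group)
    if 2 * g.shape[0] < 4:
        raise ValueError("need >= 4 haplotypes (2 diploids) for Tajima's D")
    m, p, _ = _group_stats(g)
    seg = (m >= 2) & (p > 0) & (p < 1)
    with np.errstate(invalid="ignore"):
        het = 2.0 * p * (1 - p) * (2 * m) / (2 * m - 1)
    het = np.nan_to_num(het)
    widx = _window_index(var, windows)

    nw = len(windows)
    ok = seg & (widx >= 0)
    S = np.bincount(widx[ok], minlength=nw).astype(float)
    pi_sum = np.bincount(widx[ok], weights=het[ok], minlength=nw)
    m_sum = np.bincount(widx[ok], weights=m[ok], minlength=nw)

    value = np.full(nw, np.nan)
    for w in np.flatnonzero(S > 0):
        n_hap = int(round(2.0 * m_sum[w] / S[w]))
        if n_hap < 4:
            continue
        k = _tajima_constants(n_hap)
        s = S[w]
        denom = np.sqrt(k["e1"] * s + k["e2"] * s * (s - 1))
        if denom > 0:
            value[w] = (pi_sum[w] - s / k["a1"]) / denom

    out = windows[["scaffold", "start", "end"]].copy()
    out["n_variant_sites"] = S.astype(int)
    out["statistic"] = "tajimas_d"
    out["value"] = value
    out["valid"] = ~np.isnan(value)
    return out


def detect_region(
    scan: pd.DataFrame,
    z_cutoff: float = 4.0,
    merge_gap_windows: int = 2,
    min_outlier_windows: int = 2,
) -> pd.DataFrame:
    """Call elevated regions from a window scan by robust Z-score.

    Z = (value − median) / (1.4826 · MAD) over valid windows; windows above
    ``z_cutoff`` are outliers; outlier runs separated by at most
    ``merge_gap_windows`` windows are merged.  A region must be supported by
    at least ``min_outlier_windows`` outlier windows: isolated single-window
    spikes are expected under heteroskedastic window noise (high-F_ST windows
    have proportionally noisier ratio-of-sums estimates), whereas genuine
    swept regions span many consecutive windows.  MAD = 0 (e.g. a flat scan)
    yields no outliers.
    """
    scan = scan.reset_index(drop=True)
    valid_mask = scan["valid"].to_numpy(dtype=bool)
    if not valid_mask.any():
        raise ValueError("scan has no valid windows")
    values = scan["value"].to_numpy(dtype=float)
    med = float(np.median(values[valid_mask]))
    mad = float(np.median(np.abs(values[valid_mask] - med)))
    regions = []
    if mad > 0:
        with np.errstate(invalid="ignore"):
            outlier = valid_mask & ((values - med) / (1.4826 * mad) > z_cutoff)
        for scaf in scan["scaffold"].unique():
            rows = np.flatnonzero((scan["scaffold"] == scaf).to_numpy())
            hits = rows[outlier[rows]]  # positions within scan, sorted
            if hits.size == 0:
                continue
            # split outlier windows into runs allowing small gaps
            order = np.searchsorted(rows, hits)  # window offsets on scaffold
            breaks = np.flatnonzero(np.diff(order) - 1 > merge_gap_windows)
            for run in np.split(hits, breaks + 1):
                if run.size < min_outlier_windows:
                    continue
                sub = scan.iloc[run[0] : run[-1] + 1]
                sub_out = scan.iloc[run]
                peak = sub_out.loc[sub_out["value"].idxmax()]
                regions.append(
                    (
                        scaf,
                        int(sub["start"].min()),
                        int(sub["end"].max()),
                        int(len(sub_out)),
                        int(peak["start"]),
                        float(peak["value"]),
                        float(sub_out["value"].mean()),
                    )
                )
    return pd.DataFrame(
        regions,
        columns=[
            "scaffold",
            "start",
            "end",
            "n_outlier_windows",
            "peak_start",
            "peak_value",
            "mean_value",
        ],
    )


def genes_in_region(regions: pd.DataFrame, annotation: pd.DataFrame) -> list[pd.DataFrame]:
    """Genes overlapping each region by >= 1 bp (half-open intervals)."""
    out = []
    for reg in regions.itertuples(index=False):
        hit = annotation[
            (annotation["scaffold"] == reg.scaffold)
            & (annotation["start"] < reg.end)
            & (annotation["end"] > reg.start)
        ]
        out.append(hit.reset_index(drop=True))
    return out
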