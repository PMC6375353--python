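"""Genotype-pattern evidence for a sex chromosome.

An XY-patterned site is a biallelic site at which every female is homozygous
and every male heterozygous — the fixed signature of X/Y differentiation in
a male-heterogametic system (ZW is the sex-swapped mirror).  Heterozygote
excess in the heterogametic sex is quantified with the method-of-moments
inbreeding coefficient F_IS = (O_hom - E_hom)/(N - E_hom), window values
normalized per individual by the genome-wide baseline excluding the focal
contig, and correlated with male-female F_ST.  Sample structure is examined
with a Patterson-normalized genotype PCA and the unadjusted Ajk
relatedness statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import MISSING, GenotypeMatrix, window_index

NA = float("nan")


@dataclass
class XYSiteSet:
    """Sites passing the sex-patterned test, with binning helpers."""

    pattern: str  # "XY" | "ZW"
    contig: np.ndarray
    positions: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def window_counts(
        self, contig_lengths: dict[str, int], width: int = 10_000
    ) -> pd.DataFrame:
        rows = []
        for contig, length in contig_lengths.items():
            on = self.contig == contig
            widx = window_index(self.positions[on], width)
            n_windows = -(-length // width)
            counts = np.bincount(widx, minlength=n_windows) if on.any() else np.zeros(
                n_windows, dtype=int
            )
            for w in range(n_windows):
                rows.append(
                    (contig, w * width, min((w + 1) * width, length), int(counts[w]))
                )
        return pd.DataFrame(rows, columns=["contig", "start", "end", "count"])

    def contig_normalized_counts(self, matrix: GenotypeMatrix) -> pd.DataFrame:
        """Per-contig site counts normalized by the contig's total variant
        sites (the genome-scan view that ranks candidate sex contigs)."""
        contigs = list(dict.fromkeys(matrix.contig.tolist()))
        rows = []
        for c in contigs:
            total = int((matrix.contig == c).sum())
            n = int((self.contig == c).sum())
            rows.append((c, n, total, n / total if total else NA))
        return pd.DataFrame(rows, columns=["contig", "count", "total_sites", "normalized"])


def detect_sex_patterned_sites(
    matrix: GenotypeMatrix,
    males: list[str],
    females: list[str],
    pattern: str = "XY",
    mode: str = "strict",
    min_called: int = 1,
) -> XYSiteSet:
    """Select sites where the heterogametic sex is uniformly heterozygous
    and the homogametic sex uniformly homozygous.

    ``strict`` mode (default) rejects any site with a missing call in either
    sex; ``lenient`` evaluates called genotypes only, requiring at least
    ``min_called`` calls per sex.
    """
    if pattern not in ("XY", "ZW"):
        raise ValueError("pattern must be 'XY' or 'ZW'")
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    if not males or not females:
        raise ValueError("need at least one sample of each sex")
    het_group, hom_group = (males, females) if pattern == "XY" else (females, males)
    g_het = matrix.genotypes[:, matrix.sample_indices(het_group)]
    g_hom = matrix.genotypes[:, matrix.sample_indices(hom_group)]

    het_called = g_het != MISSING
    hom_called = g_hom != MISSING
    het_ok = np.where(het_called, g_het == 1, True).all(axis=1)
    hom_ok = np.where(hom_called, (g_hom == 0) | (g_hom == 2), True).all(axis=1)
    if mode == "strict":
        complete = het_called.all(axis=1) & hom_called.all(axis=1)
        keep = complete & het_ok & hom_ok
    else:
        enough = (het_called.sum(axis=1) >= min_called) & (
            hom_called.sum(axis=1) >= min_called
        )
        keep = enough & het_ok & hom_ok
    return XYSiteSet(pattern, matrix.contig[keep].copy(), matrix.positions[keep].copy())


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------


def _site_ehom_terms(
    g: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(per-site E_hom term, polymorphic mask) for a subset genotype block.

    E_hom term = 1 - 2p(1-p) * 2n/(2n-1), with p the subset allele frequency
    and n the subset's called diploid count at the site.
    """
    called = g != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), 0.0)
    poly = (alt > 0) & (alt < 2 * called.sum(axis=1)) & (n >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = 1.0 - 2.0 * p * (1 - p) * (2 * n) / np.maximum(2 * n - 1, 1)
    return term, poly


def individual_fis(
    matrix: GenotypeMatrix,
    subset: list[str],
    site_mask: np.ndarray | None = None,
) -> pd.Series:
    """Method-of-moments F_IS per individual of ``subset``.

    F = (O_hom - E_hom) / (N - E_hom) over polymorphic sites of the subset
    (optionally restricted by ``site_mask``), where O_hom and N count the
    individual's homozygous and called sites and E_hom sums the per-site
    expected-homozygosity terms with the 2n/(2n-1) small-sample correction.
    Degenerate individuals (N == E_hom) get NA.
    """
    if len(subset) < 2:
        raise ValueError("F_IS needs at least 2 individuals in the subset")
    idx = matrix.sample_indices(subset)
    g = matrix.genotypes[:, idx]
    if site_mask is not None:
        g = g[site_mask]
    term, poly = _site_ehom_terms(g)
    g = g[poly]
    term = term[poly]
    called = g != MISSING
    hom = called & ((g == 0) | (g == 2))
    n_called = called.sum(axis=0).astype(float)
    o_hom = hom.sum(axis=0).astype(float)
    e_hom = np.where(called, term[:, None], 0.0).sum(axis=0)
    denom = n_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    return pd.Series(f, index=list(subset), name="fis")


def normalized_fis_windows(
    matrix: GenotypeMatrix,
    subset: list[str],
    sexes: dict[str, str],
    focal_contig: str,
    contig_length: int,
    width: int = 10_000,
) -> pd.DataFrame:
    """Per-window, per-sex mean of baseline-normalized individual F_IS.

    The baseline is each individual's genome-wide F_IS excluding the focal
    contig; the window value minus the baseline is averaged within each sex.
    Windows without polymorphic sites get NA.
    """
    baseline = individual_fis(matrix, subset, site_mask=matrix.contig != focal_contig)
    focal = matrix.take_sites(matrix.contig == focal_contig)
    widx = window_index(focal.positions, width)
    n_windows = -(-contig_length // width)
    m_names = [s for s in subset if sexes[s] == "M"]
    f_names = [s for s in subset if sexes[s] == "F"]
    rows = []
    for w in range(n_windows):
        start, end = w * width, min((w + 1) * width, contig_length)
        mask = widx == w
        if mask.sum() == 0:
            rows.append((focal_contig, start, end, 0, NA, NA))
            continue
        fw = individual_fis(focal, subset, site_mask=mask)
        norm = fw - baseline
        rows.append(
            (
                focal_contig, start, end, int(mask.sum()),
                float(np.nanmean(norm[m_names])) if m_names else NA,
                float(np.nanmean(norm[f_names])) if f_names else NA,
            )
        )
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "n_sites", "norm_fis_m", "norm_fis_f"]
    )


def fis_fst_correlation(
    norm_fis: np.ndarray, fst: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, p) between window normalized F_IS and window
    male-female F_ST, over jointly finite windows; NA on zero variance."""
    x = np.asarray(norm_fis, dtype=float)
    y = np.asarray(fst, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly non-NA windows")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return NA, NA
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# PCA and relatedness
# ---------------------------------------------------------------------------


def pca_genotypes(
    matrix: GenotypeMatrix,
    drop_contigs: tuple[str, ...] = (),
    n_components: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotype PCA with Patterson normalization.

    Sites are centered by 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat));
    missing genotypes are mean-imputed (zero after centering); monomorphic
    sites are dropped.  Returns (coordinates indexed by sample, explained
    variance fractions).
    """
    keep = ~np.isin(matrix.contig, drop_contigs)
    g = matrix.genotypes[keep].astype(float)
    called = g != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), 0.0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    g, p, called = g[poly], p[poly], called[poly]
    z = (np.where(called, g, 2 * p[:, None]) - 2 * p[:, None]) / np.sqrt(
        2 * p[:, None] * (1 - p[:, None])
    )
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    expl = (s**2 / np.sum(s**2))[:k]
    df = pd.DataFrame(
        coords, index=matrix.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return df, expl


def ajk_relatedness(
    matrix: GenotypeMatrix, contigs: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Unadjusted Ajk pairwise relatedness over polymorphic sites.

    A_jk = mean over sites (with both calls) of
    (g_j - 2p)(g_k - 2p) / (2p(1-p)); the matrix is symmetric with NaN on
    the diagonal (the off-diagonal definition does not apply to j = k).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    keep = (
        np.isin(matrix.contig, contigs)
        if contigs is not None
        else np.ones(matrix.n_sites, dtype=bool)
    )
    g = matrix.genotypes[keep].astype(float)
    called = g != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), 0.0)
    poly = (p > 0) & (p < 1)
    g, p, called = g[poly], p[poly], called[poly]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (g - 2 * p[:, None]) / np.sqrt(2 * p[:, None] * (1 - p[:, None]))
    z = np.where(called, z, 0.0)
    num = z.T @ z
    counts = called.T.astype(float) @ called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(counts > 0, num / counts, np.nan)
    np.fill_diagonal(a, np.nan)
    return pd.DataFrame(a, index=matrix.samples, columns=matrix.samples)
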