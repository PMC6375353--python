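"""Windowed diversity and differentiation statistics.

F_ST uses the Hudson estimator with ratio-of-sums ("ratio of averages")
aggregation per window: per-site numerator
``(p_a - p_b)^2 - p_a(1-p_a)/(n_a - 1) - p_b(1-p_b)/(n_b - 1)`` and
denominator ``p_a(1-p_b) + p_b(1-p_a)`` with ``n`` the number of called
allele copies, summed over a window before the ratio is taken.  Negative
per-site numerators are retained so the window ratio stays unbiased.  At a
completely sex-differentiated site (heterogametic group at frequency 0.5,
homogametic at 1.0) the infinite-population limit of this estimator is 0.5.

pi and d_xy are summed per-site quantities divided either by window width
(default; whole-genome setting where every position is treated as callable)
or by the number of usable sites.  Net divergence follows Nei & Li:
``d_a = d_xy - (pi_a + pi_b)/2``.  Tajima's D uses the standard 1989
constants on sites with complete calls within the group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import MISSING, GenotypeMatrix

NA = float("nan")


# ---------------------------------------------------------------------------
# per-site components
# ---------------------------------------------------------------------------


def _freqs(matrix: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele frequency, called allele copies) per site; p is NaN where
    no copies are called."""
    alt, n = matrix.allele_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def hudson_site_components(
    matrix: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson F_ST numerator and denominator per site.

    Sites where either group has fewer than 2 called allele copies
    contribute (0, 0).
    """
    pa, na = _freqs(matrix, idx_a)
    pb, nb = _freqs(matrix, idx_b)
    ok = (na >= 2) & (nb >= 2)
    pa = np.where(ok, pa, 0.0)
    pb = np.where(ok, pb, 0.0)
    na_ = np.maximum(na, 2)
    nb_ = np.maximum(nb, 2)
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na_ - 1) - pb * (1 - pb) / (nb_ - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    return num, den


def hudson_fst_population_limit(p_a: float, p_b: float) -> float:
    """Hudson F_ST in the infinite-sample limit at given allele frequencies.

    The sampling corrections vanish as n -> inf, leaving
    ``(p_a - p_b)^2 / (p_a(1-p_b) + p_b(1-p_a))``.
    """
    num = (p_a - p_b) ** 2
    den = p_a * (1 - p_b) + p_b * (1 - p_a)
    return num / den if den > 0 else NA


def wc_site_components(
    matrix: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) theta components (a, a+b+c) per site for two
    populations of diploids; offered as an alternative to Hudson."""
    comps = []
    for idx in (idx_a, idx_b):
        g = matrix.genotypes[:, idx]
        called = g != MISSING
        n_i = called.sum(axis=1).astype(float)  # diploids called
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * np.maximum(n_i, 1)), 0.0)
        h_i = np.where(called, g == 1, False).sum(axis=1) / np.maximum(n_i, 1)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    n_bar = (n1 + n2) / r
    ok = (n1 >= 1) & (n2 >= 1) & (n_bar > 1)
    n_bar_ = np.maximum(n_bar, 1.0 + 1e-9)
    nc = (r * n_bar_ - (n1**2 + n2**2) / (r * n_bar_)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar_)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar_)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar_)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar_ / np.maximum(nc, 1e-12)) * (
            s2
            - (1 / (n_bar_ - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
        )
        b = (n_bar_ / (n_bar_ - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar_ - 1) / (4 * n_bar_)) * h_bar
        )
        c = h_bar / 2
    num = np.where(ok, a, 0.0)
    den = np.where(ok, a + b + c, 0.0)
    return num, den


def pi_site(matrix: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity ``(n/(n-1)) * 2p(1-p)``; 0 where
    fewer than 2 allele copies are called."""
    p, n = _freqs(matrix, idx)
    ok = n >= 2
    n_ = np.maximum(n, 2)
    val = (n_ / (n_ - 1.0)) * 2.0 * np.where(ok, p, 0.0) * (1 - np.where(ok, p, 0.0))
    return np.where(ok, val, 0.0)


def dxy_site(
    matrix: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Per-site absolute divergence ``p_a(1-p_b) + p_b(1-p_a)``."""
    pa, na = _freqs(matrix, idx_a)
    pb, nb = _freqs(matrix, idx_b)
    ok = (na >= 1) & (nb >= 1)
    pa = np.where(ok, pa, 0.0)
    pb = np.where(ok, pb, 0.0)
    return np.where(ok, pa * (1 - pb) + pb * (1 - pa), 0.0)


def da(dxy_value: float, pi_a: float, pi_b: float) -> float:
    """Nei & Li net divergence: d_xy minus mean within-group diversity."""
    return dxy_value - (pi_a + pi_b) / 2.0


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for n sequences."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alt_counts: np.ndarray, n_copies: int, min_s: int = 3) -> float:
    """Tajima's D from per-site derived-allele counts among ``n_copies``
    sequences; NA when fewer than ``min_s`` segregating sites."""
    c = np.asarray(alt_counts)
    seg = (c > 0) & (c < n_copies)
    s = int(seg.sum())
    if s < min_s:
        return NA
    cs = c[seg].astype(float)
    k = float(np.sum(cs * (n_copies - cs)) / (n_copies * (n_copies - 1) / 2.0))
    const = tajima_constants(n_copies)
    var = const["e1"] * s + const["e2"] * s * (s - 1)
    return (k - s / const["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------


def welch_test(values_a, values_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test: (t, df, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_test needs at least 2 finite values per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# window table
# ---------------------------------------------------------------------------

WINDOW_COLUMNS = [
    "contig", "start", "end", "n_sites", "fst",
    "pi_a", "pi_b", "pi_diff", "dxy", "da", "tajd_a", "tajd_b",
]


def window_statistics(
    matrix: GenotypeMatrix,
    group_a: list[str],
    group_b: list[str],
    contig_lengths: dict[str, int],
    width: int = 10_000,
    denominator_mode: str = "width",
    fst_estimator: str = "hudson",
) -> pd.DataFrame:
    """Full per-window statistics table for two groups of samples.

    Columns: contig, start, end, n_sites, fst, pi_a, pi_b, pi_diff, dxy,
    da, tajd_a, tajd_b.  pi_diff = pi_a - pi_b (group_a minus group_b; for
    the sex contrast pass males as group_a).  Empty windows carry NA.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if denominator_mode not in ("width", "sites"):
        raise ValueError("denominator_mode must be 'width' or 'sites'")
    idx_a = matrix.sample_indices(group_a)
    idx_b = matrix.sample_indices(group_b)
    if len(idx_a) * 2 < 2 or len(idx_b) * 2 < 2:
        raise ValueError("each group needs at least 2 allele copies")

    if fst_estimator == "hudson":
        num, den = hudson_site_components(matrix, idx_a, idx_b)
    elif fst_estimator == "wc":
        num, den = wc_site_components(matrix, idx_a, idx_b)
    else:
        raise ValueError(f"unknown fst estimator {fst_estimator!r}")
    pia = pi_site(matrix, idx_a)
    pib = pi_site(matrix, idx_b)
    dxy = dxy_site(matrix, idx_a, idx_b)

    rows = []
    for contig, length in contig_lengths.items():
        on = matrix.contig == contig
        pos = matrix.positions[on]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        sub = {
            "num": num[on][order],
            "den": den[on][order],
            "pia": pia[on][order],
            "pib": pib[on][order],
            "dxy": dxy[on][order],
        }
        ga = matrix.genotypes[on][order][:, idx_a]
        gb = matrix.genotypes[on][order][:, idx_b]
        n_windows = -(-length // width)
        # 1-based positions: window w covers positions [w*width+1, (w+1)*width]
        bounds = np.searchsorted(
            pos, np.arange(n_windows + 1, dtype=np.int64) * width + 1
        )
        for w in range(n_windows):
            start, end = w * width, min((w + 1) * width, length)
            lo, hi = bounds[w], bounds[w + 1]
            n_sites = int(hi - lo)
            d = (end - start) if denominator_mode == "width" else max(n_sites, 1)
            den_w = sub["den"][lo:hi].sum()
            fst = sub["num"][lo:hi].sum() / den_w if den_w > 0 else NA
            pi_a = sub["pia"][lo:hi].sum() / d
            pi_b = sub["pib"][lo:hi].sum() / d
            dxy_w = sub["dxy"][lo:hi].sum() / d
            tajd_a = _window_tajd(ga[lo:hi])
            tajd_b = _window_tajd(gb[lo:hi])
            rows.append(
                (
                    contig, start, end, n_sites, fst,
                    pi_a, pi_b, pi_a - pi_b, dxy_w, da(dxy_w, pi_a, pi_b),
                    tajd_a, tajd_b,
                )
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def _window_tajd(g: np.ndarray) -> float:
    """Tajima's D for one window's genotype block (sites x samples);
    sites with any missing call are dropped so n is fixed."""
    if g.shape[1] < 2:
        return NA
    full = (g != MISSING).all(axis=1)
    g = g[full]
    if g.shape[0] == 0:
        return NA
    return tajimas_d(g.sum(axis=1), 2 * g.shape[1])


def genome_summary(table: pd.DataFrame) -> dict[str, float]:
    """Genome-wide summaries, both as means of window values and (for F_ST)
    nothing pooled here — see `pooled_fst` for the ratio-of-sums version."""
    out = {}
    for col in ("fst", "pi_a", "pi_b", "pi_diff", "dxy", "da", "tajd_a", "tajd_b"):
        out[f"mean_{col}"] = float(np.nanmean(table[col].to_numpy(dtype=float)))
    return out


def pooled_fst(
    matrix: GenotypeMatrix,
    group_a: list[str],
    group_b: list[str],
    fst_estimator: str = "hudson",
) -> float:
    """Global ratio-of-sums F_ST over all sites of the matrix."""
    idx_a = matrix.sample_indices(group_a)
    idx_b = matrix.sample_indices(group_b)
    comp = hudson_site_components if fst_estimator == "hudson" else wc_site_components
    num, den = comp(matrix, idx_a, idx_b)
    d = den.sum()
    return float(num.sum() / d) if d > 0 else NA


def write_window_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
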