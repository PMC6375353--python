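"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal per-site / per-pair loops straight
from the defining formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def hudson_window_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Ratio-of-sums Hudson F_ST over all sites of two genotype blocks."""
    num_sum = den_sum = 0.0
    for i in range(geno_a.shape[0]):
        res = hudson_site(geno_a[i], geno_b[i])
        if res is None:
            continue
        num_sum += res[0]
        den_sum += res[1]
    return num_sum / den_sum if den_sum > 0 else float("nan")


def hudson_site(ga: np.ndarray, gb: np.ndarray):
    def freq(g):
        alt = n = 0
        for x in g:
            if x != MISSING:
                alt += x
                n += 2
        return (alt / n, n) if n else (None, 0)

    pa, na = freq(ga)
    pb, nb = freq(gb)
    if na < 2 or nb < 2:
        return None
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return num, den


def pi_sum(geno: np.ndarray) -> float:
    """Sum of per-site unbiased heterozygosity over a genotype block."""
    total = 0.0
    for i in range(geno.shape[0]):
        alt = n = 0
        for x in geno[i]:
            if x != MISSING:
                alt += x
                n += 2
        if n >= 2:
            p = alt / n
            total += (n / (n - 1)) * 2 * p * (1 - p)
    return total


def dxy_sum(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    total = 0.0
    for i in range(geno_a.shape[0]):
        def freq(g):
            alt = n = 0
            for x in g:
                if x != MISSING:
                    alt += x
                    n += 2
            return alt / n if n else None

        pa, pb = freq(geno_a[i]), freq(geno_b[i])
        if pa is None or pb is None:
            continue
        total += pa * (1 - pb) + pb * (1 - pa)
    return total


def tajimas_d_literal(geno: np.ndarray) -> float:
    """Tajima's D from the 1989 paper's formulas, via explicit pairwise
    haplotype-free computation on complete-call sites."""
    rows = [i for i in range(geno.shape[0]) if all(x != MISSING for x in geno[i])]
    g = geno[rows]
    n = 2 * g.shape[1]
    counts = [int(sum(g[i])) for i in range(g.shape[0])]
    seg = [c for c in counts if 0 < c < n]
    s = len(seg)
    if s < 3:
        return float("nan")
    k = sum(c * (n - c) for c in seg) / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def individual_fis_literal(geno: np.ndarray, samples: list[str]) -> dict[str, float]:
    """Two-pass per-individual F_IS with explicit loops."""
    n_sites, n_ind = geno.shape
    # pass 1: per-site subset frequency, called count, polymorphism
    site_info = []
    for i in range(n_sites):
        alt = n = 0
        for j in range(n_ind):
            if geno[i, j] != MISSING:
                alt += geno[i, j]
                n += 1
        if n == 0 or alt == 0 or alt == 2 * n:
            site_info.append(None)
        else:
            p = alt / (2 * n)
            e = 1 - 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
            site_info.append(e)
    out = {}
    for j, name in enumerate(samples):
        n_called = o_hom = 0
        e_hom = 0.0
        for i in range(n_sites):
            if site_info[i] is None or geno[i, j] == MISSING:
                continue
            n_called += 1
            if geno[i, j] in (0, 2):
                o_hom += 1
            e_hom += site_info[i]
        denom = n_called - e_hom
        out[name] = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else float("nan")
    return out


def xy_site_checker(male_genos, female_genos) -> bool:
    """Literal XY-pattern rule: every male het, every female homozygous,
    no missing call anywhere."""
    for g in male_genos:
        if g != 1:
            return False
    for g in female_genos:
        if g not in (0, 2):
            return False
    return True


def welch_literal(a, b):
    a, b = list(map(float, a)), list(map(float, b))
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    se2 = va / len(a) + vb / len(b)
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    return t, df
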