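"""Sex-differential sequencing-depth evidence.

In an XY male the X is hemizygous, so X-specific sequence shows ~50% male
depth — but only once cross-mapping Y reads are excluded, which is why the
depth tracks carry a filter dialect ("all" alignments vs mismatch-free
"perfect" alignments).  Normalization follows the median-of-medians scheme:
depths are scaled by the sex-wide median, per-position per-sex medians are
averaged over windows, and log2-transformed for plotting.  Y-specific
sequence, absent from females entirely, is called from male-assembly depth
as maximal runs of "male-only coverage".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DepthTrack

NA = float("nan")


def _sex_rows(track: DepthTrack, sexes: dict[str, str], code: str) -> np.ndarray:
    rows = np.array([i for i, s in enumerate(track.samples) if sexes[s] == code])
    if len(rows) == 0:
        raise ValueError(f"no samples of sex {code!r} in depth track")
    return rows


def _median_from_counts(counts: np.ndarray) -> float:
    """Exact median of a sample summarized as value -> count (values are
    the array indices); avoids materializing huge flattened depth arrays."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty depth distribution")
    cum = np.cumsum(counts)
    if total % 2 == 1:
        return float(np.searchsorted(cum, total // 2 + 1))
    lo = float(np.searchsorted(cum, total // 2))
    hi = float(np.searchsorted(cum, total // 2 + 1))
    return (lo + hi) / 2.0


def sex_median_depth(
    tracks: list[DepthTrack], sexes: dict[str, str], code: str
) -> float:
    """Median depth over all positions and all individuals of one sex."""
    counts = np.zeros(1, dtype=np.int64)
    for tr in tracks:
        rows = _sex_rows(tr, sexes, code)
        sub = tr.depth[rows]
        c = np.bincount(sub.ravel())
        if len(c) > len(counts):
            c[: len(counts)] += counts
            counts = c
        else:
            counts[: len(c)] += c
    return _median_from_counts(counts)


def normalize_and_window(
    tracks: list[DepthTrack],
    sexes: dict[str, str],
    width: int = 10_000,
) -> pd.DataFrame:
    """Median-normalized windowed coverage per sex.

    Per sex s: (1) global median M_s over all positions x individuals of
    sex s; (2) per-position median across the sex's individuals, divided by
    M_s; (3) mean of (2) per window; (4) log2 of (3), NA where the window
    average is zero.  Columns: contig, start, end, norm_m, norm_f, log2_m,
    log2_f, dialect.
    """
    med = {c: sex_median_depth(tracks, sexes, c) for c in ("M", "F")}
    for c, m in med.items():
        if m == 0:
            raise ValueError(f"degenerate input: sex {c} median depth is 0")
    rows = []
    for tr in tracks:
        persex = {}
        for c in ("M", "F"):
            r = _sex_rows(tr, sexes, c)
            persex[c] = np.median(tr.depth[r], axis=0) / med[c]
        n_windows = -(-tr.length // width)
        starts = np.arange(n_windows) * width
        for c in ("M", "F"):
            sums = np.add.reduceat(persex[c], starts)
            sizes = np.minimum(starts + width, tr.length) - starts
            persex[c] = sums / sizes
        with np.errstate(divide="ignore"):
            l2m = np.where(persex["M"] > 0, np.log2(persex["M"]), np.nan)
            l2f = np.where(persex["F"] > 0, np.log2(persex["F"]), np.nan)
        for w in range(n_windows):
            rows.append(
                (
                    tr.contig, int(starts[w]), int(min(starts[w] + width, tr.length)),
                    float(persex["M"][w]), float(persex["F"][w]),
                    float(l2m[w]), float(l2f[w]), tr.dialect,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "norm_m", "norm_f", "log2_m", "log2_f", "dialect"],
    )


@dataclass(frozen=True)
class MaleOnlyRegion:
    """Maximal run of male-only coverage on the male assembly."""

    contig: str
    start: int  # 0-based half-open
    end: int
    mean_male_depth: float
    mean_female_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


def call_male_only_regions(
    track: DepthTrack,
    sexes: dict[str, str],
    min_len: int = 1_000,
    min_males_covered: int | None = None,
    male_total_gt: int = 5,
    female_total_lt: int = 3,
) -> list[MaleOnlyRegion]:
    """Regions where consecutive positions have coverage in most males,
    pooled male depth above ``male_total_gt``, and pooled female depth
    strictly below ``female_total_lt``; runs shorter than ``min_len`` are
    discarded.  ``min_males_covered`` defaults to ceil(0.8 * n_males).
    """
    m_rows = _sex_rows(track, sexes, "M")
    f_rows = _sex_rows(track, sexes, "F")
    if min_males_covered is None:
        min_males_covered = -(-len(m_rows) * 4 // 5)  # ceil(0.8 n)
    male = track.depth[m_rows]
    female_total = track.depth[f_rows].sum(axis=0)
    ok = (
        ((male >= 1).sum(axis=0) >= min_males_covered)
        & (male.sum(axis=0) > male_total_gt)
        & (female_total < female_total_lt)
    )
    regions = []
    padded = np.concatenate([[False], ok, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_len:
            regions.append(
                MaleOnlyRegion(
                    track.contig,
                    int(start),
                    int(end),
                    float(male[:, start:end].mean()),
                    float(track.depth[f_rows][:, start:end].mean()),
                )
            )
    return regions


def filter_y_contigs(
    profiles: dict[str, DepthTrack],
    sexes: dict[str, str],
    max_male_pos: int = 50,
    female_pos_cut: int = 5,
    female_mode: str = "pooled",
) -> list[str]:
    """Vet candidate Y contigs by back-mapped coverage.

    A contig is dropped when any single male exceeds ``max_male_pos`` depth
    at any position (likely an individual-specific repeat), or when female
    coverage reaches ``female_pos_cut`` at any position (pooled across
    females by default; ``female_mode="per_individual"`` tests each female
    separately).  Survivors are returned in input order.
    """
    if female_mode not in ("pooled", "per_individual"):
        raise ValueError("female_mode must be 'pooled' or 'per_individual'")
    kept = []
    for name, tr in profiles.items():
        m_rows = _sex_rows(tr, sexes, "M")
        f_rows = _sex_rows(tr, sexes, "F")
        if (tr.depth[m_rows] > max_male_pos).any():
            continue
        fem = (
            tr.depth[f_rows].sum(axis=0)
            if female_mode == "pooled"
            else tr.depth[f_rows].max(axis=0)
        )
        if (fem >= female_pos_cut).any():
            continue
        kept.append(name)
    return kept


def write_regions(regions: list[MaleOnlyRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tlength\tmean_male_depth\tmean_female_depth\n")
        for r in regions:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.length}\t"
                f"{r.mean_male_depth:.3f}\t{r.mean_female_depth:.3f}\n"
            )
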