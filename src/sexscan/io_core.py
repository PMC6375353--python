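"""Core data model and readers/writers for the formats the pipeline touches.

Genotypes are held as a dense site-by-sample matrix of alt-allele counts
(0, 1, 2; -1 for a missing call).  VCF positions are 1-based; every internal
window is a 0-based half-open interval, so a site at VCF position ``P``
belongs to window ``(P - 1) // width``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

MISSING = -1

SEX_CODES = frozenset({"M", "F", "J", "U"})


@dataclass
class SampleSheet:
    """Per-sample sex (M/F/J/U) and population label."""

    samples: list[str]
    sex: dict[str, str]
    population: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in sample sheet")
        for s in self.samples:
            if self.sex[s] not in SEX_CODES:
                raise ValueError(f"invalid sex code {self.sex[s]!r} for sample {s}")

    def of_sex(self, code: str, population: str | None = None) -> list[str]:
        return [
            s
            for s in self.samples
            if self.sex[s] == code
            and (population is None or self.population[s] == population)
        ]

    def males(self, population: str | None = None) -> list[str]:
        return self.of_sex("M", population)

    def females(self, population: str | None = None) -> list[str]:
        return self.of_sex("F", population)

    def populations(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.population[s]
            if p not in seen:
                seen.append(p)
        return seen


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV with header columns: sample, sex, population."""
    samples, sex, pop = [], {}, {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_s, i_x, i_p = (header.index(c) for c in ("sample", "sex", "population"))
        except ValueError as e:
            raise ValueError(f"sample sheet {path} missing required column: {e}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            s = parts[i_s]
            samples.append(s)
            sex[s] = parts[i_x]
            pop[s] = parts[i_p]
    return SampleSheet(samples, sex, pop)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tsex\tpopulation\n")
        for s in sheet.samples:
            fh.write(f"{s}\t{sheet.sex[s]}\t{sheet.population[s]}\n")


@dataclass
class GenotypeMatrix:
    """Biallelic variant sites x diploid samples, as alt-allele counts.

    ``contig``/``positions``/``ref``/``alt`` are per-site arrays; positions
    are 1-based as in the source VCF and strictly increasing within a contig.
    """

    samples: list[str]
    contig: np.ndarray  # per-site contig name (unicode)
    positions: np.ndarray  # int64, 1-based
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray  # int8 (n_sites, n_samples), -1 missing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.contig = np.asarray(self.contig)
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("invalid genotype code in matrix")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e} not in genotype matrix")

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples,
            self.contig[mask_or_index],
            self.positions[mask_or_index],
            self.ref[mask_or_index],
            self.alt[mask_or_index],
            self.genotypes[mask_or_index],
        )

    def for_contig(self, contig: str) -> "GenotypeMatrix":
        return self.take_sites(self.contig == contig)

    def contigs(self) -> list[str]:
        seen: list[str] = []
        for c in self.contig:
            if not seen or seen[-1] != c:
                if c not in seen:
                    seen.append(str(c))
        return seen

    def allele_counts(self, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele copies, called allele copies) per site for a
        sample subset; missing genotypes contribute to neither count."""
        g = self.genotypes[:, sample_idx]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)


def read_vcf(path: str | Path, sheet: SampleSheet | None = None) -> GenotypeMatrix:
    """Read biallelic records from a VCF 4.x into a GenotypeMatrix.

    Multiallelic records are dropped (with a logged count); indels are kept
    as single REF-vs-ALT sites.  If a sample sheet is given, columns are
    restricted to, and ordered as, the sheet's samples.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    if sheet is not None:
        for s in sheet.samples:
            if s not in vcf_samples:
                raise ValueError(f"sample {s!r} from sample sheet absent from VCF {path}")
        order = np.array([vcf_samples.index(s) for s in sheet.samples], dtype=np.intp)
        samples = list(sheet.samples)
    else:
        order = np.arange(len(vcf_samples), dtype=np.intp)
        samples = vcf_samples

    contigs, positions, refs, alts, rows = [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        contigs.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(g[order])
    if n_multi:
        log.info("read_vcf: dropped %d multiallelic record(s) from %s", n_multi, path)
    geno = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples,
        np.array(contigs, dtype=str),
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        geno,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexscan\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(matrix.contig.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in matrix.genotypes[i])
            fh.write(
                f"{matrix.contig[i]}\t{matrix.positions[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_missingness(
    matrix: GenotypeMatrix, max_missing_fraction: float = 0.5
) -> GenotypeMatrix:
    """Drop sites whose missing-call fraction strictly exceeds the threshold.

    A site with exactly the threshold fraction missing is kept.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    miss = (matrix.genotypes == MISSING).mean(axis=1)
    return matrix.take_sites(miss <= max_missing_fraction)


@dataclass(frozen=True)
class Window:
    """0-based half-open genomic interval on a contig."""

    contig: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


def make_windows(contig: str, contig_length: int, width: int = 10_000) -> list[Window]:
    """Tile a contig with non-overlapping windows; the last may be partial."""
    if width <= 0:
        raise ValueError("window width must be positive")
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    return [
        Window(contig, s, min(s + width, contig_length))
        for s in range(0, contig_length, width)
    ]


def window_index(positions: np.ndarray, width: int) -> np.ndarray:
    """Window ordinal for 1-based site positions under a fixed tiling."""
    return (np.asarray(positions, dtype=np.int64) - 1) // width


@dataclass
class DepthTrack:
    """Dense per-position read depth for one contig, all samples.

    Row ``i`` of ``depth`` is sample ``samples[i]`` over positions
    ``1..L`` (stored 0-based).  ``dialect`` records whether depths came
    from all alignments or only mismatch-free ("perfect") alignments.
    """

    contig: str
    samples: list[str]
    depth: np.ndarray  # (n_samples, L) int
    dialect: str  # "all" | "perfect"

    def __post_init__(self) -> None:
        if self.dialect not in ("all", "perfect"):
            raise ValueError(f"unknown depth dialect {self.dialect!r}")
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return self.depth.shape[1]


def write_depth_tsv(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    """samtools depth -aa layout: contig, pos, one column per sample.

    A single '#'-prefixed header row names the sample columns.
    """
    import pandas as pd

    tracks = list(tracks)
    with open(path, "w") as fh:
        fh.write("#contig\tpos\t" + "\t".join(tracks[0].samples) + "\n")
        for tr in tracks:
            df = pd.DataFrame(tr.depth.T)
            df.insert(0, "pos", np.arange(1, tr.length + 1))
            df.insert(0, "contig", tr.contig)
            df.to_csv(fh, sep="\t", header=False, index=False)


def read_depth_tsv(
    path: str | Path, dialect: str, samples: list[str] | None = None
) -> dict[str, DepthTrack]:
    """Read a samtools-depth-like TSV into per-contig DepthTracks.

    Sample names come from a leading '#' header row, or must be supplied.
    Positions are assumed dense (``-aa`` style: every position present,
    in order) per contig.
    """
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        header_names = first.lstrip("#").rstrip("\n").split("\t")[2:]
        df = pd.read_csv(path, sep="\t", skiprows=1, header=None)
    else:
        if samples is None:
            raise ValueError("depth TSV has no header row; pass sample names")
        header_names = list(samples)
        df = pd.read_csv(path, sep="\t", header=None)
    if samples is None:
        samples = header_names
    tracks: dict[str, DepthTrack] = {}
    for contig, sub in df.groupby(0, sort=False):
        pos = sub[1].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"depth track for {contig} is not dense from position 1")
        depth = sub.iloc[:, 2:].to_numpy().T
        # reorder columns if an explicit sample order was requested
        order = [header_names.index(s) for s in samples]
        tracks[str(contig)] = DepthTrack(str(contig), list(samples), depth[order], dialect)
    return tracks


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")
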