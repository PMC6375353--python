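"""Alignment-free sex-specific sequence discovery from raw reads.

Catalogs count every k-long word (default k = 37) that starts with a short
trigger prefix (default "AG"), pooled over all individuals of one sex; the
trigger cuts the catalog to ~1/16 of all words, which is what makes
desktop-scale k-mer comparison of whole read sets tractable.  Words are
taken from reads as written — no reverse-complement canonicalization — so a
word and its reverse complement are distinct entries (this halves per-strand
sensitivity; the placement step searches both strands explicitly).

Classification against the pooled counts: a Y-mer is effectively
male-private (male count > 9, female count < 5 — Y haplotypes exist only in
males); an X-mer sits at the 2:1 female:male dosage of X-linked sequence
(female/male ratio within [1.75, 2.25]).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class KmerCatalog:
    """Pooled word -> count mapping for one sex's read set."""

    k: int = 37
    trigger: str = "AG"
    min_count: int = 5
    counts: dict[str, int] = field(default_factory=dict)

    def compatible(self, other: "KmerCatalog") -> bool:
        return self.k == other.k and self.trigger == other.trigger


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a FASTQ file (gzip-transparent)."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header.rstrip("\n")[1:], seq, qual


def _count_into(counts: dict[str, int], seq: str, k: int, trigger: str) -> None:
    start = seq.find(trigger)
    last = len(seq) - k
    while 0 <= start <= last:
        word = seq[start : start + k]
        if _ACGT.issuperset(word):
            counts[word] = counts.get(word, 0) + 1
        start = seq.find(trigger, start + 1)


def count_kmers(
    fastq_paths: Iterable[str | Path],
    k: int = 37,
    trigger: str = "AG",
    min_count: int = 5,
) -> KmerCatalog:
    """Tally trigger-prefixed k-mers over read files, dropping words with
    fewer than ``min_count`` occurrences after pooling.

    Words containing non-ACGT characters are skipped.  Counting is additive
    over files: counting shards and summing equals counting the
    concatenation.
    """
    counts: dict[str, int] = {}
    n_reads = 0
    for path in fastq_paths:
        for _, seq, _ in iter_fastq(path):
            n_reads += 1
            _count_into(counts, seq, k, trigger)
    if n_reads == 0:
        log.warning("count_kmers: no reads in input; catalog is empty")
    if min_count > 1:
        counts = {w: c for w, c in counts.items() if c >= min_count}
    return KmerCatalog(k=k, trigger=trigger, min_count=min_count, counts=counts)


def merge_catalogs(catalogs: Iterable[KmerCatalog], min_count: int = 5) -> KmerCatalog:
    """Pool per-individual catalogs (built with min_count=1) into one sex
    catalog, applying ``min_count`` after merging."""
    catalogs = list(catalogs)
    base = catalogs[0]
    counts: dict[str, int] = {}
    for cat in catalogs:
        if not base.compatible(cat):
            raise ValueError("catalogs differ in k or trigger")
        for w, c in cat.counts.items():
            counts[w] = counts.get(w, 0) + c
    counts = {w: c for w, c in counts.items() if c >= min_count}
    return KmerCatalog(k=base.k, trigger=base.trigger, min_count=min_count, counts=counts)


def classify_kmers(
    male_catalog: KmerCatalog,
    female_catalog: KmerCatalog,
    y_male_min: int = 10,
    y_female_max: int = 4,
    x_ratio_lo: float = 1.75,
    x_ratio_hi: float = 2.25,
    female_scale: float = 1.0,
) -> pd.DataFrame:
    """Classify every word of either catalog as Y-mer, X-mer or other.

    Y-mer: male count >= y_male_min and female count <= y_female_max
    (absence counts as 0).  X-mer: male count >= 1 and scaled female/male
    ratio within [x_ratio_lo, x_ratio_hi].  The Y test is applied first, so
    the classes are mutually exclusive.  ``female_scale`` multiplies female
    counts before the ratio when sex sample sizes differ.
    """
    if not male_catalog.compatible(female_catalog):
        raise ValueError("catalogs differ in k or trigger")
    words = sorted(set(male_catalog.counts) | set(female_catalog.counts))
    m = np.array([male_catalog.counts.get(w, 0) for w in words], dtype=np.int64)
    f = np.array([female_catalog.counts.get(w, 0) for w in words], dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m > 0, female_scale * f / np.maximum(m, 1), np.inf)
    is_y = (m >= y_male_min) & (f <= y_female_max)
    is_x = ~is_y & (m >= 1) & (ratio >= x_ratio_lo) & (ratio <= x_ratio_hi)
    cls = np.where(is_y, "Y-mer", np.where(is_x, "X-mer", "other"))
    return pd.DataFrame(
        {"kmer": words, "male_count": m, "female_count": f, "class": cls}
    )


def _matches_any(seq: str, kmer_set: frozenset[str], k: int, trigger: str | None) -> bool:
    if trigger is not None:
        start = seq.find(trigger)
        last = len(seq) - k
        while 0 <= start <= last:
            if seq[start : start + k] in kmer_set:
                return True
            start = seq.find(trigger, start + 1)
        return False
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] in kmer_set:
            return True
    return False


def extract_reads_by_kmers(
    fastq1: str | Path,
    fastq2: str | Path,
    kmers: Iterable[str],
    out1: str | Path,
    out2: str | Path,
) -> int:
    """Keep read pairs where either mate contains a set k-mer as an exact
    substring; both mates of a kept pair are written, order preserved.
    Returns the number of pairs kept."""
    kmer_set = frozenset(kmers)
    if not kmer_set:
        raise ValueError("empty k-mer set")
    ks = {len(w) for w in kmer_set}
    if len(ks) != 1:
        raise ValueError("k-mer set has mixed lengths")
    k = ks.pop()
    # exploit a common prefix when all words share one (trigger catalogs do)
    prefixes = {w[:2] for w in kmer_set}
    trigger = prefixes.pop() if len(prefixes) == 1 else None
    kept = 0
    it1, it2 = iter_fastq(fastq1), iter_fastq(fastq2)
    with open(out1, "w") as o1, open(out2, "w") as o2:
        for r1, r2 in zip(it1, it2, strict=True):
            if _matches_any(r1[1], kmer_set, k, trigger) or _matches_any(
                r2[1], kmer_set, k, trigger
            ):
                o1.write(f"@{r1[0]}\n{r1[1]}\n+\n{r1[2]}\n")
                o2.write(f"@{r2[0]}\n{r2[1]}\n+\n{r2[2]}\n")
                kept += 1
    return kept


def place_kmers(
    kmers: Iterable[str],
    assembly: dict[str, str],
    window: int = 10_000,
) -> pd.DataFrame:
    """Exact placements of k-mers on an assembly, both strands.

    Returns one row per match: contig, start (0-based), strand; plus a
    per-window density table is derivable via ``placement_density``.
    """
    kmer_set = frozenset(kmers)
    if not kmer_set:
        return pd.DataFrame(columns=["contig", "start", "strand"])
    ks = {len(w) for w in kmer_set}
    if len(ks) != 1:
        raise ValueError("k-mer set has mixed lengths")
    k = ks.pop()
    rc_set = frozenset(revcomp(w) for w in kmer_set)
    rows = []
    for contig, seq in assembly.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if word in kmer_set:
                rows.append((contig, i, "+"))
            if word in rc_set:
                rows.append((contig, i, "-"))
    return pd.DataFrame(rows, columns=["contig", "start", "strand"])


def placement_density(
    placements: pd.DataFrame, contig_lengths: dict[str, int], width: int = 10_000
) -> pd.DataFrame:
    """Per-window match counts from a placement table."""
    rows = []
    for contig, length in contig_lengths.items():
        sub = placements[placements["contig"] == contig]
        widx = (sub["start"].to_numpy() // width) if len(sub) else np.array([], int)
        n_windows = -(-length // width)
        counts = np.bincount(widx, minlength=n_windows)
        for w in range(n_windows):
            rows.append(
                (contig, w * width, min((w + 1) * width, length), int(counts[w]))
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "count"])


def write_catalog(catalog: KmerCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={catalog.k}\ttrigger={catalog.trigger}\tmin_count={catalog.min_count}\n")
        for w in sorted(catalog.counts):
            fh.write(f"{w}\t{catalog.counts[w]}\n")


def read_catalog(path: str | Path) -> KmerCatalog:
    counts: dict[str, int] = {}
    k, trigger, min_count = 37, "AG", 5
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                fields = dict(
                    kv.split("=") for kv in line.lstrip("#").rstrip("\n").split("\t")
                )
                k = int(fields.get("k", k))
                trigger = fields.get("trigger", trigger)
                min_count = int(fields.get("min_count", min_count))
                continue
            w, c = line.rstrip("\n").split("\t")
            counts[w] = int(c)
    return KmerCatalog(k=k, trigger=trigger, min_count=min_count, counts=counts)
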