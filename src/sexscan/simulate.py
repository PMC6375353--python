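"""Coalescent-based simulator of populations carrying a young XX-XY region.

The generator produces everything the downstream stages consume — a VCF-shaped
genotype matrix, per-sample depth tracks in two alignment-filter dialects,
paired reads, reference FASTAs — together with a machine-readable truth record,
so that every stage of the scan has a parameter-recovery test.

Model
-----
Each contig is tiled into non-recombining blocks (default 10 kb, matching the
analysis window width); blocks are independent, which stands in for free
recombination between blocks.  Within a block, haplotypes follow a standard
neutral (Kingman) coalescent with infinite-sites mutation: with per-block
scaled mutation rate theta, E[pairwise diversity] = theta and E[segregating
sites] = theta * sum_{i<n} 1/i.

Males are X/Y heterogametic.  Inside the sex-determining (sd) region one
ancestral Y haplotype is drawn from the X pool; Poisson(y_tau * length)
Y-specific derived mutations are shared by every Y copy (making all males
heterozygous and all females homozygous-ancestral there), and Y copies carry
additional private variation from a coalescent with rate y_internal_theta.
Y-specific insertion sequences, absent from females, live in a separate
male-assembly coordinate space.

Sequencing depth is Poisson per position and sample.  Under the
"perfect"-alignment dialect, male depth halves wherever a read spanning the
position would contain an X/Y mismatch; under the "all" dialect cross-mapping
hides the hemizygosity and male depth is unreduced.

All randomness derives from one integer seed through numpy SeedSequence
spawn keys, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import (
    DepthTrack,
    GenotypeMatrix,
    SampleSheet,
    write_depth_tsv,
    write_sample_sheet,
    write_vcf,
)

# stream ids for seed splitting (one per independent source of randomness)
_S_GENO, _S_DEPTH, _S_READS, _S_REF, _S_INS = 1, 2, 3, 4, 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the target system: ~20 Mb genome in ten 2 Mb contigs,
    five males and five females per population, per-site diversity ~0.005
    (theta = 50 per 10 kb block), a 1.5 Mb sd region on "LG7" whose Y lineage
    carries y_tau = 1.75e-3 derived mutations per bp (a mutation rate of
    3.5e-9/bp/generation over ~500,000 generations, i.e. a Y younger than a
    million years), a dozen kb-scale Y-specific insertions, and ~20x Poisson
    sequencing depth.
    """

    seed: int = 1
    n_males: int = 5
    n_females: int = 5
    n_populations: int = 1
    contigs: dict[str, int] = field(
        default_factory=lambda: {f"LG{i}": 2_000_000 for i in range(1, 11)}
    )
    block_length: int = 10_000
    theta: float = 50.0  # per block
    sd_region: tuple[str, int, int] | None = ("LG7", 300_000, 1_800_000)
    y_tau: float = 1.75e-3  # expected Y-specific derived mutations per bp
    y_internal_theta: float = 1.0  # per block, diversity among Y copies
    y_mode: str = "lake_only"  # lake_only | independent | shared
    n_y_insertions: int = 12
    y_insertion_length: int = 1_500
    split_theta_scale: float = 0.8  # population-private divergence, per block
    bottleneck_founders: int = 4  # founder haplotypes for population 2
    depth_lambda: float = 20.0
    read_depth: float = 20.0  # target per-base coverage for simulated reads
    read_length: int = 150
    fragment_length: int = 350

    def __post_init__(self) -> None:
        if self.n_populations not in (1, 2):
            raise ValueError("n_populations must be 1 or 2")
        if self.y_tau < 0:
            raise ValueError("y_tau must be >= 0")
        if self.sd_region is not None:
            c, a, b = self.sd_region
            if c not in self.contigs or not (0 <= a < b <= self.contigs[c]):
                raise ValueError("sd_region outside its contig")
        if self.y_mode not in ("lake_only", "independent", "shared"):
            raise ValueError(f"unknown y_mode {self.y_mode!r}")

    @property
    def populations(self) -> list[str]:
        return ["lake", "creek"][: self.n_populations]


def simulate_autosomal_block(
    n_haplotypes: int,
    theta: float,
    rng: np.random.Generator | int,
    block_length: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral single-population coalescent for one non-recombining block.

    Returns (haplotypes, positions): a (n, S) 0/1 array of derived-allele
    indicators and sorted, distinct 1-based positions uniform in the block.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    branches, lengths = _kingman_branches(n_haplotypes, rng)
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    n_mut = min(n_mut, block_length)  # infinite-sites cap at integer positions
    if n_mut == 0:
        return (
            np.empty((n_haplotypes, 0), dtype=np.uint8),
            np.empty(0, dtype=np.int64),
        )
    which = rng.choice(len(lengths), size=n_mut, p=lengths / total)
    haps = branches[which].T.astype(np.uint8)  # (n, S)
    pos = np.sort(rng.choice(block_length, size=n_mut, replace=False)) + 1
    return haps, pos.astype(np.int64)


def _kingman_branches(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """All non-root branches of a Kingman genealogy.

    Returns (carriers, lengths): carriers[b] is the boolean leaf set below
    branch b; time is scaled so that E[pairwise coalescence] = 1.
    """
    active = list(range(n))
    birth = np.zeros(2 * n - 1)
    length = np.zeros(2 * n - 1)
    leafsets = np.zeros((2 * n - 1, n), dtype=bool)
    for i in range(n):
        leafsets[i, i] = True
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        length[a] = t - birth[a]
        length[b] = t - birth[b]
        leafsets[nxt] = leafsets[a] | leafsets[b]
        birth[nxt] = t
        for idx in sorted((i, j), reverse=True):
            del active[idx]
        active.append(nxt)
        nxt += 1
    root = active[0]
    keep = np.ones(nxt, dtype=bool)
    keep[root] = False
    return leafsets[:nxt][keep], length[:nxt][keep]


@dataclass
class SimResult:
    """Everything the simulator knows about one synthetic cohort."""

    config: SimConfig
    sheet: SampleSheet
    matrix: GenotypeMatrix
    truth: dict
    # phased haplotypes: contig -> (n_samples, 2, S_contig) uint8 over the
    # positions of `matrix` restricted to that contig
    haplotypes: dict[str, np.ndarray]


def _sample_names(config: SimConfig) -> tuple[list[str], dict[str, str], dict[str, str]]:
    names, sex, pop = [], {}, {}
    for p, plabel in zip(config.populations, "AB"):
        for i in range(config.n_males):
            s = f"{plabel}_M{i + 1}"
            names.append(s)
            sex[s] = "M"
            pop[s] = p
        for i in range(config.n_females):
            s = f"{plabel}_F{i + 1}"
            names.append(s)
            sex[s] = "F"
            pop[s] = p
    return names, sex, pop


def _distinct_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, taken: set[int]
) -> np.ndarray:
    """n distinct 1-based positions in (lo, hi] not already taken."""
    out: list[int] = []
    while len(out) < n:
        cand = rng.integers(lo, hi, size=n - len(out)) + 1
        for c in cand:
            c = int(c)
            if c not in taken:
                taken.add(c)
                out.append(c)
    return np.array(sorted(out), dtype=np.int64)


def simulate_genotypes(config: SimConfig) -> SimResult:
    """Simulate phased haplotypes, genotypes, sample sheet, and truth."""
    names, sex, pop = _sample_names(config)
    sheet = SampleSheet(names, sex, pop)
    n_samples = len(names)
    male_rows = np.array([i for i, s in enumerate(names) if sex[s] == "M"])
    pop_rows = {
        p: np.array([i for i, s in enumerate(names) if pop[s] == p])
        for p in config.populations
    }

    contig_arr, pos_arr, geno_rows = [], [], []
    haplotypes: dict[str, np.ndarray] = {}
    y_sites: list[int] = []
    y_internal_sites: list[int] = []

    for ci, (contig, length) in enumerate(config.contigs.items()):
        rng = _rng(config.seed, _S_GENO, ci)
        hap_cols: list[np.ndarray] = []  # each (n_samples, 2) per site
        pos_cols: list[int] = []
        n_blocks = -(-length // config.block_length)
        for b in range(n_blocks):
            b_start = b * config.block_length
            b_len = min(config.block_length, length - b_start)
            sd_overlap = _sd_overlap(config, contig, b_start, b_len)
            hap2, positions = _simulate_block(
                config, rng, sheet, pop_rows, b_len, sd_overlap,
                y_sites_out=y_sites, y_internal_out=y_internal_sites,
                offset=b_start,
            )
            hap_cols.append(hap2)
            pos_cols.extend((positions + b_start).tolist())
        if hap_cols:
            H = np.concatenate(hap_cols, axis=2)  # (n_samples, 2, S)
        else:
            H = np.empty((n_samples, 2, 0), dtype=np.uint8)
        pos = np.array(pos_cols, dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos, H = pos[order], H[:, :, order]
        # keep only sites polymorphic in the full sample
        g = H.sum(axis=1)  # (n_samples, S)
        poly = (g.sum(axis=0) > 0) & (g.sum(axis=0) < 2 * n_samples)
        pos, H, g = pos[poly], H[:, :, poly], g[:, poly]
        haplotypes[contig] = H
        contig_arr.extend([contig] * len(pos))
        pos_arr.extend(pos.tolist())
        geno_rows.append(g.T.astype(np.int8))  # (S, n_samples)

    geno = (
        np.concatenate(geno_rows, axis=0)
        if geno_rows
        else np.empty((0, n_samples), dtype=np.int8)
    )
    n_sites = geno.shape[0]
    ref_rng = _rng(config.seed, _S_REF, 0)
    bases = np.array(list("ACGT"))
    ref_idx = ref_rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + ref_rng.integers(1, 4, size=n_sites)) % 4
    matrix = GenotypeMatrix(
        names,
        np.array(contig_arr, dtype=str),
        np.array(pos_arr, dtype=np.int64),
        bases[ref_idx].astype(object),
        bases[alt_idx].astype(object),
        geno,
    )
    # positions emitted in the VCF (for flagging fixed-on-Y-only truth sites)
    emitted = set(map(int, matrix.positions[matrix.contig == (config.sd_region[0] if config.sd_region else "")]))
    truth = {
        "sd_region": list(config.sd_region) if config.sd_region else None,
        "y_sites": sorted(y_sites),
        "y_sites_fixed_on_y_only": sorted(p for p in y_sites if p not in emitted),
        "y_internal_sites": sorted(y_internal_sites),
        "karyotype": {
            s: ("XY" if sex[s] == "M" and _has_y(config, pop[s]) else "XX")
            for s in names
        },
        "y_insertions": [],
        "male_assembly": None,
        "y_insertion_read_pairs": {},
    }
    return SimResult(config, sheet, matrix, truth, haplotypes)


def _has_y(config: SimConfig, population: str) -> bool:
    if config.sd_region is None:
        return False
    return population == "lake" or config.y_mode in ("independent", "shared")


def _sd_overlap(
    config: SimConfig, contig: str, b_start: int, b_len: int
) -> tuple[int, int] | None:
    if config.sd_region is None or config.sd_region[0] != contig:
        return None
    _, a, b = config.sd_region
    lo, hi = max(a, b_start), min(b, b_start + b_len)
    if lo >= hi:
        return None
    return lo - b_start, hi - b_start  # block-local, 0-based half-open


def _simulate_block(
    config: SimConfig,
    rng: np.random.Generator,
    sheet: SampleSheet,
    pop_rows: dict[str, np.ndarray],
    b_len: int,
    sd_overlap: tuple[int, int] | None,
    y_sites_out: list[int],
    y_internal_out: list[int],
    offset: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One block for all samples; returns ((n_samples, 2, S), positions)."""
    n_samples = len(sheet.samples)
    two_pop = config.n_populations == 2
    theta = config.theta * (b_len / config.block_length)

    # haplotype pool from a single ancestral coalescent
    n_total_hap = 2 * n_samples
    pool_n = n_total_hap if not two_pop else max(n_total_hap, 8)
    # one spare per Y-carrying population (the ancestral Y is drawn from
    # the X pool but must not also be someone's X)
    n_spare = 0
    if sd_overlap is not None:
        n_spare = sum(
            1 for p in config.populations if _has_y(config, p)
        ) if config.y_mode != "shared" else 1
    pool, positions = simulate_autosomal_block(pool_n + n_spare, theta, rng, b_len)
    # per-sample haplotype assignment
    H = np.zeros((n_samples, 2, pool.shape[1]), dtype=np.uint8)
    taken = set(map(int, positions))
    extra_cols: list[tuple[np.ndarray, int]] = []  # (carrier rows (n,2) bool, pos)

    spare_used = 0
    shared_y_base: np.ndarray | None = None
    shared_y_extra: list[tuple[np.ndarray, int]] | None = None
    for pi, p in enumerate(config.populations):
        rows = pop_rows[p]
        if not two_pop or pi == 0:
            idx = np.arange(2 * len(rows)) if not two_pop else rng.choice(
                pool_n, size=2 * len(rows), replace=True
            )
        else:
            founders = rng.choice(pool_n, size=config.bottleneck_founders, replace=False)
            idx = rng.choice(founders, size=2 * len(rows), replace=True)
        for k, r in enumerate(rows):
            H[r, 0] = pool[idx[2 * k]]
            H[r, 1] = pool[idx[2 * k + 1]]
        if two_pop:
            # population-private divergence: fixed derived sites in this pop
            n_priv = rng.poisson(config.split_theta_scale * theta / 2.0)
            n_priv = min(n_priv, max(b_len - len(taken), 0))
            for pos in _distinct_positions(rng, 0, b_len, n_priv, taken):
                carry = np.zeros((n_samples, 2), dtype=bool)
                carry[rows, :] = True
                extra_cols.append((carry, int(pos)))

    # the Y overlay
    if sd_overlap is not None:
        lo, hi = sd_overlap
        for p in config.populations:
            if not _has_y(config, p):
                continue
            m_rows = np.array(
                [i for i in pop_rows[p] if sheet.sex[sheet.samples[i]] == "M"]
            )
            if len(m_rows) == 0:
                continue
            if config.y_mode == "shared" and shared_y_base is not None:
                y_base, y_extra = shared_y_base, shared_y_extra
            else:
                y_base = pool[pool_n + spare_used].copy()
                if config.y_mode != "shared":
                    spare_used += 1
                # Y-specific derived mutations shared by every Y copy
                n_y = rng.poisson(config.y_tau * (hi - lo))
                n_y = min(n_y, max(hi - lo - 10, 0))
                y_extra = []
                for pos in _distinct_positions(rng, lo, hi, n_y, taken):
                    y_extra.append((None, int(pos)))
                    y_sites_out.append(int(pos) + offset)
                if config.y_mode == "shared":
                    shared_y_base, shared_y_extra = y_base, y_extra
            # haplotype 1 of each male is the Y
            for r in m_rows:
                H[r, 1] = y_base
            for _, pos in y_extra:
                carry = np.zeros((n_samples, 2), dtype=bool)
                carry[m_rows, 1] = True
                extra_cols.append((carry, int(pos)))
            # private variation among this population's Y copies
            if config.y_internal_theta > 0 and len(m_rows) >= 2:
                yh, _ = simulate_autosomal_block(
                    len(m_rows), config.y_internal_theta * (b_len / config.block_length),
                    rng, b_len,
                )
                n_int = min(yh.shape[1], max(hi - lo - 10, 0))
                if n_int:
                    ipos = _distinct_positions(rng, lo, hi, n_int, taken)
                    for j, pos in enumerate(ipos):
                        carry = np.zeros((n_samples, 2), dtype=bool)
                        carry[m_rows, 1] = yh[:, j].astype(bool)
                        extra_cols.append((carry, int(pos)))
                        y_internal_out.append(int(pos) + offset)

    if extra_cols:
        add = np.zeros((n_samples, 2, len(extra_cols)), dtype=np.uint8)
        add_pos = np.zeros(len(extra_cols), dtype=np.int64)
        for j, (carry, pos) in enumerate(extra_cols):
            add[:, :, j] = carry
            add_pos[j] = pos
        H = np.concatenate([H, add], axis=2)
        positions = np.concatenate([positions, add_pos])  # already 1-based
    order = np.argsort(positions, kind="stable")
    return H[:, :, order], positions[order]


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


def x_specific_mask(
    config: SimConfig, truth: dict, contig: str, length: int
) -> np.ndarray:
    """Positions (0-based) where a male read would carry an X/Y mismatch.

    A position is X-specific when an X/Y-differentiating site lies within
    one read length of it, i.e. any perfectly-aligning male read covering it
    must come from the X copy only.
    """
    mask = np.zeros(length, dtype=bool)
    if config.sd_region is None or config.sd_region[0] != contig:
        return mask
    diff = np.array(
        sorted(set(truth["y_sites"]) | set(truth.get("y_internal_sites", []))),
        dtype=np.int64,
    )
    for p in diff:  # p is 1-based
        lo = max(0, p - config.read_length)
        hi = min(length, p - 1 + config.read_length)
        mask[lo:hi] = True
    return mask


def simulate_depth(
    config: SimConfig,
    truth: dict,
    dialect: str,
    seed_stream: int = 0,
    full_sd_mask: bool = False,
) -> dict[str, DepthTrack]:
    """Per-sample Poisson depth tracks over the female-reference contigs.

    Under ``dialect="perfect"`` male depth is Poisson(lambda/2) over
    X-specific positions of the sd region; under ``dialect="all"`` male
    depth is unreduced there (Y reads cross-map onto the X).  With
    ``full_sd_mask`` every sd-region position is treated as X-specific
    (a completely differentiated region).
    """
    if dialect not in ("all", "perfect"):
        raise ValueError(f"unknown dialect {dialect!r}")
    names = _sample_names(config)[0]
    karyo = truth.get("karyotype", {})
    tracks: dict[str, DepthTrack] = {}
    for ci, (contig, length) in enumerate(config.contigs.items()):
        rng = _rng(config.seed, _S_DEPTH, seed_stream, ci, 0 if dialect == "all" else 1)
        depth = rng.poisson(config.depth_lambda, size=(len(names), length)).astype(
            np.int32
        )
        if dialect == "perfect" and config.sd_region and config.sd_region[0] == contig:
            if full_sd_mask:
                mask = np.zeros(length, dtype=bool)
                mask[config.sd_region[1] : config.sd_region[2]] = True
            else:
                mask = x_specific_mask(config, truth, contig, length)
            n_masked = int(mask.sum())
            for i, s in enumerate(names):
                if karyo.get(s, "XX") == "XY":
                    depth[i, mask] = rng.poisson(
                        config.depth_lambda / 2.0, size=n_masked
                    )
        tracks[contig] = DepthTrack(contig, list(names), depth, dialect)
    return tracks


# ---------------------------------------------------------------------------
# Y insertions, references, reads
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def add_y_insertions(result: SimResult) -> None:
    """Draw Y-specific insertion sequences and their male-haplotype anchors.

    Anchors live inside the sd region (female-reference coordinates); the
    male-assembly coordinate space is the sd contig with the insertions
    spliced into the Y haplotype, recorded in ``truth["male_assembly"]``.
    """
    config = result.config
    if config.sd_region is None or config.n_y_insertions == 0:
        return
    contig, a, b = config.sd_region
    rng = _rng(config.seed, _S_INS, 0)
    anchors = np.sort(
        rng.choice(b - a - 1, size=config.n_y_insertions, replace=False) + a + 1
    )
    ins = []
    shift = 0
    male_intervals = []
    for anchor in anchors:
        seq = _random_seq(rng, config.y_insertion_length)
        ins.append({"anchor": int(anchor), "sequence": seq})
        start = int(anchor) + shift
        male_intervals.append([start, start + len(seq)])
        shift += len(seq)
    result.truth["y_insertions"] = ins
    result.truth["male_assembly"] = {
        "contig": f"{contig}_male",
        "length": int(config.contigs[contig] + shift),
        "insertion_intervals": male_intervals,
    }


def reference_sequences(result: SimResult) -> dict[str, str]:
    """Female-reference sequence per contig (random, seed-determined).

    Bases at variant positions are forced to the matrix's REF allele so that
    reads, VCF and FASTA describe one consistent genome.
    """
    config = result.config
    seqs = {}
    for ci, (contig, length) in enumerate(config.contigs.items()):
        rng = _rng(config.seed, _S_REF, 1, ci)
        arr = np.frombuffer(_random_seq(rng, length).encode(), dtype="S1").copy()
        on = result.matrix.contig == contig
        pos = result.matrix.positions[on]
        arr[pos - 1] = np.char.encode(result.matrix.ref[on].astype(str))
        seqs[contig] = arr.tobytes().decode()
    return seqs


def male_assembly_sequence(result: SimResult, refs: dict[str, str]) -> tuple[str, str]:
    """(name, sequence) of the male-assembly contig: sd contig + insertions."""
    ma = result.truth["male_assembly"]
    if ma is None:
        raise ValueError("no Y insertions simulated")
    contig = result.config.sd_region[0]
    base = refs[contig]
    parts, prev = [], 0
    for entry in result.truth["y_insertions"]:
        a = entry["anchor"]
        parts.append(base[prev:a])
        parts.append(entry["sequence"])
        prev = a
    parts.append(base[prev:])
    return ma["contig"], "".join(parts)


def simulate_male_assembly_depth(
    result: SimResult, seed_stream: int = 0
) -> DepthTrack:
    """Depth over the male-assembly space: females 0 on insertions, males
    hemizygous (Poisson(lambda/2)) there, Poisson(lambda) elsewhere."""
    config = result.config
    ma = result.truth["male_assembly"]
    if ma is None:
        raise ValueError("no Y insertions simulated")
    names, sexes, pops = _sample_names(config)
    rng = _rng(config.seed, _S_DEPTH, seed_stream, 999)
    L = ma["length"]
    lam = np.full((len(names), L), config.depth_lambda)
    ins_mask = np.zeros(L, dtype=bool)
    for a, b in ma["insertion_intervals"]:
        ins_mask[a:b] = True
    karyo = result.truth["karyotype"]
    for i, s in enumerate(names):
        if karyo.get(s, "XX") == "XY":
            lam[i, ins_mask] = config.depth_lambda / 2.0
        else:
            lam[i, ins_mask] = 0.0
    depth = rng.poisson(lam).astype(np.int32)
    return DepthTrack(ma["contig"], list(names), depth, "all")


def _haplotype_sequence(
    ref: str, positions: np.ndarray, alleles: np.ndarray, refb: np.ndarray,
    altb: np.ndarray,
) -> str:
    seq = np.frombuffer(ref.encode(), dtype="S1").copy()
    carry = alleles.astype(bool)
    seq[positions[carry] - 1] = np.char.encode(altb[carry].astype(str))
    return seq.tobytes().decode()


def simulate_reads(
    result: SimResult, outdir: str | Path, seed_stream: int = 0
) -> dict[str, tuple[Path, Path]]:
    """Paired FASTQ per sample from each individual's two haplotypes.

    Fragments are sampled uniformly per haplotype (including spliced Y
    insertions for XY males); mates are the fragment's ends, mate 2
    reverse-complemented, with constant base quality.  Read names carry the
    sample, haplotype and fragment origin; names of pairs overlapping
    Y-insertion sequence are mirrored into the truth record.
    """
    config = result.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.read_length > config.fragment_length:
        raise ValueError("read_length must be <= fragment_length")
    refs = reference_sequences(result)
    sd_contig = config.sd_region[0] if config.sd_region else None
    karyo = result.truth["karyotype"]
    files: dict[str, tuple[Path, Path]] = {}
    qual = "I" * config.read_length
    result.truth["y_insertion_read_pairs"] = {}

    for si, sample in enumerate(result.sheet.samples):
        rng = _rng(config.seed, _S_READS, seed_stream, si)
        p1 = outdir / f"{sample}_1.fastq"
        p2 = outdir / f"{sample}_2.fastq"
        yins_reads: list[str] = []
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for contig, length in config.contigs.items():
                cpos = result.matrix.positions[result.matrix.contig == contig]
                refb = result.matrix.ref[result.matrix.contig == contig]
                altb = result.matrix.alt[result.matrix.contig == contig]
                H = result.haplotypes[contig][si]  # (2, S)
                for hap in (0, 1):
                    seq = _haplotype_sequence(refs[contig], cpos, H[hap], refb, altb)
                    ins_ivals: list[tuple[int, int]] = []
                    if (
                        contig == sd_contig
                        and hap == 1
                        and karyo[sample] == "XY"
                        and result.truth["y_insertions"]
                    ):
                        # splice Y insertions into the Y haplotype
                        parts, prev, shift = [], 0, 0
                        for entry in result.truth["y_insertions"]:
                            a = entry["anchor"]
                            parts.append(seq[prev:a])
                            ins_ivals.append((a + shift, a + shift + len(entry["sequence"])))
                            parts.append(entry["sequence"])
                            shift += len(entry["sequence"])
                            prev = a
                        parts.append(seq[prev:])
                        seq = "".join(parts)
                    if len(seq) < config.fragment_length:
                        continue
                    # each fragment yields 2*read_length sequenced bases; two
                    # haplotypes together hit the per-base target read_depth
                    n_frag = int(
                        round(config.read_depth * len(seq) / (4.0 * config.read_length))
                    )
                    starts = rng.integers(
                        0, len(seq) - config.fragment_length + 1, size=n_frag
                    )
                    flips = rng.integers(0, 2, size=n_frag)
                    for fi, st in enumerate(starts):
                        st = int(st)
                        frag = seq[st : st + config.fragment_length]
                        if flips[fi]:  # libraries sample both duplex strands
                            frag = _revcomp(frag)
                        tag = ""
                        if any(
                            st < e and st + config.fragment_length > a
                            for a, e in ins_ivals
                        ):
                            tag = ":Yins"
                        name = f"{sample}:{contig}:h{hap}:{st}:{fi}{tag}"
                        if tag:
                            yins_reads.append(name)
                        r1 = frag[: config.read_length]
                        r2 = _revcomp(frag[-config.read_length :])
                        f1.write(f"@{name}/1\n{r1}\n+\n{qual}\n")
                        f2.write(f"@{name}/2\n{r2}\n+\n{qual}\n")
        result.truth["y_insertion_read_pairs"][sample] = yins_reads
        files[sample] = (p1, p2)
    return files


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def minimal_truth(config: SimConfig) -> dict:
    """Truth skeleton (sd region, karyotypes, no variant lists) for stages
    that need only the design of the cohort, e.g. depth simulation over a
    fully differentiated region."""
    names, sex, pop = _sample_names(config)
    return {
        "sd_region": list(config.sd_region) if config.sd_region else None,
        "y_sites": [],
        "y_internal_sites": [],
        "karyotype": {
            s: ("XY" if sex[s] == "M" and _has_y(config, pop[s]) else "XX")
            for s in names
        },
        "y_insertions": [],
        "male_assembly": None,
    }


def simulate_cohort(config: SimConfig, with_insertions: bool = True) -> SimResult:
    """Genotypes + truth (+ Y insertions); the common entry point."""
    result = simulate_genotypes(config)
    if with_insertions and config.sd_region is not None and config.n_y_insertions:
        add_y_insertions(result)
    return result


def simulate_to_dir(
    config: SimConfig,
    outdir: str | Path,
    write_reads: bool = False,
    write_fastas: bool = False,
) -> SimResult:
    """Run the generator and write the full file set a real study would have:
    VCF, sample sheet, two depth-dialect TSVs, male-assembly depth, truth
    JSON, and optionally FASTQs and reference FASTAs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_cohort(config)
    write_vcf(result.matrix, outdir / "cohort.vcf", config.contigs)
    write_sample_sheet(result.sheet, outdir / "samples.tsv")
    for dialect in ("all", "perfect"):
        tracks = simulate_depth(config, result.truth, dialect)
        write_depth_tsv(tracks.values(), outdir / f"cohort.{dialect}.depth.tsv")
    if result.truth["male_assembly"] is not None:
        write_depth_tsv(
            [simulate_male_assembly_depth(result)],
            outdir / "male_assembly.depth.tsv",
        )
    if write_reads:
        simulate_reads(result, outdir / "reads")
    if write_fastas:
        refs = reference_sequences(result)
        write_fasta(refs, outdir / "female_assembly.fasta")
        if result.truth["male_assembly"] is not None:
            name, seq = male_assembly_sequence(result, refs)
            write_fasta({name: seq}, outdir / "male_assembly.fasta")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(result.truth, fh, indent=1)
    return result
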