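"""Synthetic pooled target-capture sequencing data.

This module is the stand-in for the study's real inputs (HapMap samples,
capture arrays, an Illumina GAIIx).  It generates three layers:

1. a *truth set* of SNVs and short (1-18 bp) indels with per-pool alt
   chromosome counts drawn from a rare-skewed site frequency spectrum;
2. per-pool, per-site *read counts* (a pileup summary) under an
   over-dispersed capture-coverage model, pooling imbalance, and
   substitution/indel sequencing errors;
3. toy *gapped reads* around planted indels, a fraction of which are
   emitted with deliberately gapless, mismatch-bearing alignments — the
   substrate for the indel-sensitive realignment module.

Counts are held columnar (sites x pools numpy arrays) in
:class:`SiteCountsTable`; :class:`PoolSiteCounts` records are a per-row
view used for TSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._rng import substream
from .design import PoolDesign

__all__ = [
    "TruthVariant",
    "PoolSiteCounts",
    "SiteCountsTable",
    "SimulatedRead",
    "random_reference",
    "simulate_truth",
    "simulate_site_counts",
    "simulate_pool_counts",
    "simulate_reads_with_indels",
]

BASES = np.array(list("ACGT"))

#: defaults mirroring the study conditions
DEFAULT_MEAN_COVERAGE = 683.0      # mean per-pool depth over targets
DEFAULT_COVERAGE_DISPERSION = 2.0  # gamma shape; ~94% of bases in [mean/5, 5*mean]
DEFAULT_ERROR_RATE = 0.0075        # GAIIx per-base substitution error, 0.5-1%
DEFAULT_INDEL_ERROR_RATE = 1e-4    # per-read spurious indel rate
DEFAULT_INDEL_FRACTION = 100.0 / 2849.0
DEFAULT_READ_LENGTH = 55
MAX_INDEL_LEN = 18


class ConfigError(ValueError):
    """Raised for invalid simulator configuration (bad SFS, sizes, rates)."""


# ---------------------------------------------------------------------------
# truth variants


@dataclass(frozen=True)
class TruthVariant:
    """A true segregating site with per-pool alt chromosome counts."""

    contig: str
    position: int                # 1-based
    ref_allele: str
    alt_allele: str
    var_type: str                # "SNV" | "insertion" | "deletion"
    per_pool_alt_chromosomes: tuple[int, ...]
    population_frequency: float

    def __post_init__(self) -> None:
        if self.var_type == "SNV":
            if not (len(self.ref_allele) == 1 and len(self.alt_allele) == 1):
                raise ValueError("SNV alleles must be single bases")
        else:
            delta = abs(len(self.ref_allele) - len(self.alt_allele))
            if not 1 <= delta <= MAX_INDEL_LEN:
                raise ValueError(f"indel length must be 1-{MAX_INDEL_LEN} bp")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    def segregates_in(self, pool: int) -> bool:
        return self.per_pool_alt_chromosomes[pool] > 0

    def pool_frequency(self, pool: int, chromosomes_per_pool: int) -> float:
        return self.per_pool_alt_chromosomes[pool] / chromosomes_per_pool


def random_reference(length: int, seed: int, gc: float = 0.5) -> str:
    """A random reference sequence (independent bases, configurable GC)."""
    rng = substream(seed, "reference")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _resolve_sfs(sfs, total_chromosomes: int) -> np.ndarray:
    """Probability vector over population alt counts 1..total_chromosomes."""
    m = total_chromosomes
    if sfs is None or (isinstance(sfs, str) and sfs == "neutral"):
        w = 1.0 / np.arange(1, m + 1)
        return w / w.sum()
    if isinstance(sfs, dict):
        w = np.zeros(m)
        for count, mass in sfs.items():
            if not 1 <= int(count) <= m:
                raise ConfigError(f"SFS support must be within 1..{m}: got {count}")
            w[int(count) - 1] = mass
    else:
        w = np.asarray(sfs, dtype=float)
        if w.shape != (m,):
            raise ConfigError(f"SFS vector must have length {m}; got shape {w.shape}")
    if (w < 0).any():
        raise ConfigError("SFS must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ConfigError("SFS has no mass")
    return w / total


def _indel_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Indel lengths 1..18 bp, short-skewed (mass proportional to 1/length)."""
    w = 1.0 / np.arange(1, MAX_INDEL_LEN + 1)
    return rng.choice(np.arange(1, MAX_INDEL_LEN + 1), size=n, p=w / w.sum())


def simulate_truth(
    design: PoolDesign,
    n_sites: int,
    sfs=None,
    indel_fraction: float = DEFAULT_INDEL_FRACTION,
    seed: int = 0,
    contig: str = "target1",
    region_length: int | None = None,
    reference: str | None = None,
) -> list[TruthVariant]:
    """Draw a truth set of segregating sites.

    Each site's population alt chromosome count m is drawn from ``sfs``
    (a distribution over 1..2N*P; default neutral, mass ∝ 1/m, which puts
    roughly half the variants at ≤5% population frequency) and split
    across pools by multivariate hypergeometric sampling, i.e. carriers
    are assigned to pools at random.  A site is an indel with probability
    ``indel_fraction`` (default: the study's 100/2849 indel share).

    When ``reference`` is given, alleles are consistent with it (ref
    alleles read off the sequence, VCF-style anchor bases); otherwise
    alleles are random.  Deterministic given ``seed``.
    """
    if n_sites < 0:
        raise ConfigError("n_sites must be >= 0")
    if not 0 <= indel_fraction <= 1:
        raise ConfigError("indel_fraction must be in [0, 1]")
    if n_sites == 0:
        return []
    rng = substream(seed, "truth")
    if reference is not None:
        region_length = len(reference)
    elif region_length is None:
        region_length = 200 * n_sites + 200
    # leave room at both ends for indel anchors/deleted bases
    usable = region_length - MAX_INDEL_LEN - 2
    if usable < n_sites:
        raise ConfigError("region too short for the requested number of sites")
    positions = np.sort(rng.choice(np.arange(2, 2 + usable), size=n_sites, replace=False))

    probs = _resolve_sfs(sfs, design.total_chromosomes)
    pop_counts = rng.choice(np.arange(1, design.total_chromosomes + 1), size=n_sites, p=probs)
    colors = [design.chromosomes_per_pool] * design.n_pools
    per_pool = np.stack(
        [rng.multivariate_hypergeometric(colors, int(m)) for m in pop_counts]
    )

    is_indel = rng.random(n_sites) < indel_fraction
    ins_flag = rng.random(n_sites) < 0.5
    lengths = _indel_lengths(rng, n_sites)

    variants: list[TruthVariant] = []
    for i, pos in enumerate(positions):
        pos = int(pos)
        if reference is not None:
            ref_base = reference[pos - 1]
        else:
            ref_base = str(rng.choice(BASES))
        if not is_indel[i]:
            alt = str(rng.choice(BASES[BASES != ref_base]))
            ref, var_type = ref_base, "SNV"
        elif ins_flag[i]:
            inserted = "".join(rng.choice(BASES, size=int(lengths[i])))
            ref, alt, var_type = ref_base, ref_base + inserted, "insertion"
        else:
            d = int(lengths[i])
            if reference is not None:
                deleted = reference[pos : pos + d]
            else:
                deleted = "".join(rng.choice(BASES, size=d))
            ref, alt, var_type = ref_base + deleted, ref_base, "deletion"
        variants.append(
            TruthVariant(
                contig=contig,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                var_type=var_type,
                per_pool_alt_chromosomes=tuple(int(c) for c in per_pool[i]),
                population_frequency=float(pop_counts[i]) / design.total_chromosomes,
            )
        )
    return variants


# ---------------------------------------------------------------------------
# per-pool site counts


@dataclass(frozen=True)
class PoolSiteCounts:
    """Filtered read-count summary for one pool at one site."""

    contig: str
    position: int
    pool_id: int
    depth: int                   # reads retained after quality filters
    allele_counts: dict
    mean_error_prob: float
    raw_depth: int

    def __post_init__(self) -> None:
        if sum(self.allele_counts.values()) != self.depth:
            raise ValueError("allele_counts must sum to depth")
        if self.depth > self.raw_depth:
            raise ValueError("depth cannot exceed raw_depth")


@dataclass
class SiteCountsTable:
    """Columnar per-site, per-pool counts for S sites x P pools."""

    contig: str
    positions: np.ndarray          # (S,) 1-based
    ref_alleles: list[str]
    alt_alleles: list[str]
    var_types: list[str]
    depth: np.ndarray              # (S, P) post-filter depth
    alt: np.ndarray                # (S, P) alt-supporting reads
    other: np.ndarray              # (S, P) third/fourth-allele reads
    raw_depth: np.ndarray          # (S, P)
    mean_error_prob: np.ndarray    # (S, P)
    truth: list[TruthVariant] | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_pools(self) -> int:
        return self.depth.shape[1]

    @property
    def ref(self) -> np.ndarray:
        return self.depth - self.alt - self.other

    def to_records(self) -> list[PoolSiteCounts]:
        out = []
        ref_counts = self.ref
        for s in range(self.n_sites):
            for p in range(self.n_pools):
                counts = {self.ref_alleles[s]: int(ref_counts[s, p])}
                if self.alt[s, p] or True:
                    counts[self.alt_alleles[s]] = int(self.alt[s, p])
                if self.other[s, p]:
                    counts["<other>"] = int(self.other[s, p])
                out.append(
                    PoolSiteCounts(
                        contig=self.contig,
                        position=int(self.positions[s]),
                        pool_id=p,
                        depth=int(self.depth[s, p]),
                        allele_counts=counts,
                        mean_error_prob=float(self.mean_error_prob[s, p]),
                        raw_depth=int(self.raw_depth[s, p]),
                    )
                )
        return out


def _draw_depths(
    rng: np.random.Generator,
    shape: tuple[int, int],
    mean: float,
    dispersion: float | None,
) -> np.ndarray:
    """Over-dispersed site depths: Poisson-gamma (negative binomial).

    ``dispersion`` is the gamma shape; smaller means more spread.  The
    default (2.0) puts ~94% of bases within [mean/5, 5*mean], matching
    observed capture non-uniformity.  ``None`` (or inf) gives fixed
    depth, used for experiments conditioned on a coverage stratum.
    """
    if dispersion is None or not np.isfinite(dispersion):
        return np.full(shape, int(round(mean)), dtype=np.int64)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=shape)
    return rng.poisson(lam)


def _alt_read_probability(
    rng: np.random.Generator,
    alt_chroms: np.ndarray,      # (S, P)
    proportions: np.ndarray,     # (P, N) per-individual DNA fractions
) -> np.ndarray:
    """P(a read carries the alt allele) per site/pool, given carriers.

    The alt chromosomes at each site are assigned to distinct chromosomes
    uniformly at random; a read samples individual i with probability
    proportional to its DNA fraction and one of its two chromosomes
    uniformly.
    """
    S, P = alt_chroms.shape
    N = proportions.shape[1]
    if (alt_chroms == 0).all():
        return np.zeros((S, P))
    # weight of each chromosome within its pool
    chrom_w = np.repeat(proportions / 2.0, 2, axis=1)       # (P, 2N)
    u = rng.random((S, P, 2 * N))
    ranks = u.argsort(axis=2).argsort(axis=2)
    chosen = ranks < alt_chroms[:, :, None]
    return (chosen * chrom_w[None, :, :]).sum(axis=2)


def simulate_site_counts(
    truth: Sequence[TruthVariant],
    design: PoolDesign,
    mean_coverage_per_pool: float = DEFAULT_MEAN_COVERAGE,
    coverage_dispersion: float | None = DEFAULT_COVERAGE_DISPERSION,
    error_rate: float = DEFAULT_ERROR_RATE,
    imbalance: float | None = None,
    seed: int = 0,
    indel_error_rate: float = DEFAULT_INDEL_ERROR_RATE,
    error_rate_cv: float = 0.1,
    filter_keep_rate: float = 0.98,
) -> SiteCountsTable:
    """Simulate the filtered pileup counts for every truth site.

    Per site and pool: depth is over-dispersed around the pool mean;
    each read draws a source chromosome (Dirichlet-perturbed individual
    proportions when ``imbalance``, a symmetric Dirichlet concentration,
    is finite); reads report their true allele except for errors.  SNV
    errors flip to each alternative base at ``error_rate/3``; indel
    errors occur at ``indel_error_rate`` per read.  The per-site error
    rate wobbles around ``error_rate`` with coefficient of variation
    ``error_rate_cv``, and the reported ``mean_error_prob`` is that
    quality-derived rate (base qualities are assumed calibrated).
    """
    if mean_coverage_per_pool <= 0:
        raise ConfigError("mean_coverage_per_pool must be > 0")
    if not 0 <= error_rate < 0.5:
        raise ConfigError("error_rate must be in [0, 0.5)")
    rng = substream(seed, "counts")
    S, P = len(truth), design.n_pools
    positions = np.array([v.position for v in truth], dtype=np.int64)
    alt_chroms = np.array(
        [v.per_pool_alt_chromosomes for v in truth], dtype=np.int64
    ).reshape(S, P)
    is_indel = np.array([v.var_type != "SNV" for v in truth], dtype=bool)

    if imbalance is None or not np.isfinite(imbalance):
        proportions = design.dna_proportions
    else:
        proportions = np.stack(
            [
                rng.dirichlet(np.full(design.individuals_per_pool, imbalance) )
                for _ in range(P)
            ]
        )
        proportions = design.dna_proportions * design.individuals_per_pool * proportions
        proportions = proportions / proportions.sum(axis=1, keepdims=True)

    raw_depth = _draw_depths(rng, (S, P), mean_coverage_per_pool, coverage_dispersion)
    if filter_keep_rate < 1.0:
        depth = rng.binomial(raw_depth, filter_keep_rate)
    else:
        depth = raw_depth.copy()

    p_alt = _alt_read_probability(rng, alt_chroms, proportions)
    a_true = rng.binomial(depth, p_alt)
    r_true = depth - a_true

    # per-site/pool error rate (what calibrated base qualities report)
    if error_rate > 0 and error_rate_cv > 0:
        shape = 1.0 / error_rate_cv**2
        e_site = rng.gamma(shape=shape, scale=error_rate / shape, size=(S, P))
        e_site = np.clip(e_site, 1e-8, 0.49)
    else:
        e_site = np.full((S, P), error_rate)

    alt_obs = np.empty((S, P), dtype=np.int64)
    ref_obs = np.empty((S, P), dtype=np.int64)
    other_obs = np.zeros((S, P), dtype=np.int64)

    snv = ~is_indel
    if snv.any():
        e = e_site[snv]
        rt, at = r_true[snv], a_true[snv]
        x_alt = rng.binomial(rt, e / 3.0)                       # ref reads miscalled as alt
        rem = rt - x_alt
        x_other = rng.binomial(rem, (2 * e / 3.0) / (1 - e / 3.0))
        y_ref = rng.binomial(at, e / 3.0)                       # alt reads miscalled as ref
        rem_a = at - y_ref
        y_other = rng.binomial(rem_a, (2 * e / 3.0) / (1 - e / 3.0))
        alt_obs[snv] = at - y_ref - y_other + x_alt
        ref_obs[snv] = rt - x_alt - x_other + y_ref
        other_obs[snv] = x_other + y_other
    if is_indel.any():
        ei = indel_error_rate
        rt, at = r_true[is_indel], a_true[is_indel]
        x_alt = rng.binomial(rt, ei)
        y_ref = rng.binomial(at, ei)
        alt_obs[is_indel] = at - y_ref + x_alt
        ref_obs[is_indel] = rt - x_alt + y_ref

    mean_err = np.maximum(e_site, 1e-10)
    return SiteCountsTable(
        contig=truth[0].contig if S else "target1",
        positions=positions,
        ref_alleles=[v.ref_allele for v in truth],
        alt_alleles=[v.alt_allele for v in truth],
        var_types=[v.var_type for v in truth],
        depth=depth.astype(np.int64),
        alt=alt_obs,
        other=other_obs,
        raw_depth=raw_depth.astype(np.int64),
        mean_error_prob=mean_err,
        truth=list(truth),
    )


def simulate_pool_counts(
    truth: Sequence[TruthVariant],
    design: PoolDesign,
    mean_coverage_per_pool: float = DEFAULT_MEAN_COVERAGE,
    coverage_dispersion: float | None = DEFAULT_COVERAGE_DISPERSION,
    error_rate: float = DEFAULT_ERROR_RATE,
    imbalance: float | None = None,
    seed: int = 0,
    **kwargs,
) -> list[PoolSiteCounts]:
    """Record-level wrapper around :func:`simulate_site_counts`."""
    table = simulate_site_counts(
        truth,
        design,
        mean_coverage_per_pool=mean_coverage_per_pool,
        coverage_dispersion=coverage_dispersion,
        error_rate=error_rate,
        imbalance=imbalance,
        seed=seed,
        **kwargs,
    )
    return table.to_records()


def null_truth(
    design: PoolDesign,
    n_sites: int,
    contig: str = "target1",
    seed: int = 0,
) -> list[TruthVariant]:
    """Monomorphic 'candidate' sites (no alt chromosomes anywhere).

    Used for caller calibration: every alt read at these sites is a
    sequencing error.
    """
    rng = substream(seed, "null-truth")
    zeros = tuple(0 for _ in range(design.n_pools))
    variants = []
    for i in range(n_sites):
        ref = str(rng.choice(BASES))
        alt = str(rng.choice(BASES[BASES != ref]))
        variants.append(
            TruthVariant(
                contig=contig,
                position=10 * (i + 1),
                ref_allele=ref,
                alt_allele=alt,
                var_type="SNV",
                per_pool_alt_chromosomes=zeros,
                population_frequency=0.0,
            )
        )
    return variants


# ---------------------------------------------------------------------------
# gapped reads around indels


@dataclass(frozen=True)
class SimulatedRead:
    """A SAM-like read record with a CIGAR-described alignment."""

    read_id: str
    contig: str
    start: int                    # 1-based leftmost reference position
    sequence: str
    base_qualities: tuple[int, ...]
    mapping_quality: int
    cigar: str
    is_original_alignment: bool = True

    def __post_init__(self) -> None:
        from .cigar import query_length

        if query_length(self.cigar) != len(self.sequence):
            raise ValueError(
                f"CIGAR {self.cigar} query length != sequence length {len(self.sequence)}"
            )
        if len(self.base_qualities) != len(self.sequence):
            raise ValueError("base_qualities length must match sequence length")


def _apply_indels(reference: str, indels: Sequence[TruthVariant]):
    """Alternate haplotype with all (non-overlapping) indels applied.

    Returns (alt_sequence, blocks) where blocks is a list of
    (ref_start, alt_start, length) 1-based matching segments, enough to
    map alt-haplotype coordinates back to the reference.
    """
    indels = sorted(indels, key=lambda v: v.position)
    last_end = 0
    for v in indels:
        span_end = v.position + len(v.ref_allele) - 1
        if v.position <= last_end:
            raise ConfigError("overlapping indels are not supported")
        last_end = span_end
    pieces: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    ref_cursor = 1
    alt_cursor = 1
    for v in indels:
        # matching block up to and including the anchor base
        seg_len = v.position - ref_cursor + 1
        pieces.append(reference[ref_cursor - 1 : v.position])
        blocks.append((ref_cursor, alt_cursor, seg_len))
        ref_cursor = v.position + len(v.ref_allele)
        alt_cursor += seg_len
        inserted = v.alt_allele[1:]
        pieces.append(inserted)
        alt_cursor += len(inserted)
    pieces.append(reference[ref_cursor - 1 :])
    blocks.append((ref_cursor, alt_cursor, len(reference) - ref_cursor + 1))
    return "".join(pieces), blocks


def _alt_to_ref(blocks: list[tuple[int, int, int]], alt_pos: int) -> int | None:
    """Map a 1-based alt-haplotype position to the reference (None if inserted)."""
    for ref_start, alt_start, length in blocks:
        if alt_start <= alt_pos < alt_start + length:
            return ref_start + (alt_pos - alt_start)
    return None


def _gapped_cigar_and_start(
    blocks: list[tuple[int, int, int]],
    alt_start: int,
    read_len: int,
) -> tuple[int, str]:
    """Correct gapped alignment for an alt-haplotype read at ``alt_start``."""
    ops: list[tuple[str, int]] = []
    ref_start = None
    prev_ref = None
    for off in range(read_len):
        rpos = _alt_to_ref(blocks, alt_start + off)
        if rpos is None:
            op = "I"
        else:
            if ref_start is None:
                ref_start = rpos
            if prev_ref is not None and rpos > prev_ref + 1:
                ops.append(("D", rpos - prev_ref - 1))
            prev_ref = rpos
            op = "M"
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if ref_start is None:
        raise ConfigError("read lies entirely within an insertion")
    # leading insertions cannot be represented without a mapped base before them
    while ops and ops[0][0] == "I":
        raise ConfigError("read starts inside an insertion; choose another start")
    cigar = "".join(f"{n}{op}" for op, n in ops)
    return ref_start, cigar


def simulate_reads_with_indels(
    reference: str,
    truth: Sequence[TruthVariant],
    read_length: int = DEFAULT_READ_LENGTH,
    coverage: float = 100.0,
    misalignment_rate_near_indels: float = 0.0,
    seed: int = 0,
    error_rate: float = 0.0,
    alt_haplotype_fraction: float = 0.5,
    contig: str = "ref",
    base_quality: int = 35,
    mapping_quality: int = 60,
) -> list[SimulatedRead]:
    """Simulate reads from a reference and its indel haplotype.

    Reads come from the indel-carrying haplotype with probability
    ``alt_haplotype_fraction``.  A read overlapping an indel is emitted
    with its correct gapped alignment, except with probability
    ``misalignment_rate_near_indels`` it is emitted *gapless*, anchored
    at its leftmost exactly-mapping block — mimicking an independent
    per-read aligner forced to place an indel-spanning read without a
    gap, which strews mismatches near the read end.
    """
    if read_length > len(reference):
        raise ConfigError("reference shorter than read_length")
    indels = [v for v in truth if v.var_type != "SNV"]
    rng = substream(seed, "reads")
    alt_seq, blocks = _apply_indels(reference, indels)
    n_reads = int(round(coverage * len(reference) / read_length))
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        on_alt = bool(indels) and (rng.random() < alt_haplotype_fraction)
        hap = alt_seq if on_alt else reference
        if len(hap) < read_length:
            raise ConfigError("haplotype shorter than read_length")
        start_h = int(rng.integers(1, len(hap) - read_length + 2))
        seq = np.array(list(hap[start_h - 1 : start_h - 1 + read_length]))
        if error_rate > 0:
            flip = rng.random(read_length) < error_rate
            if flip.any():
                repl = rng.choice(BASES, size=int(flip.sum()))
                cur = seq[flip]
                # force a change where the draw equals the current base
                same = repl == cur
                while same.any():
                    repl[same] = rng.choice(BASES, size=int(same.sum()))
                    same = repl == cur
                seq[flip] = repl
        sequence = "".join(seq)
        quals = tuple([base_quality] * read_length)

        if not on_alt:
            start, cigar = start_h, f"{read_length}M"
        else:
            try:
                gstart, gcigar = _gapped_cigar_and_start(blocks, start_h, read_length)
            except ConfigError:
                continue
            if "I" in gcigar or "D" in gcigar:
                if rng.random() < misalignment_rate_near_indels:
                    # gapless, left-anchored placement: first base's ref position
                    start = _alt_to_ref(blocks, start_h)
                    assert start is not None
                    if start + read_length - 1 > len(reference):
                        start = len(reference) - read_length + 1
                    cigar = f"{read_length}M"
                else:
                    start, cigar = gstart, gcigar
            else:
                start, cigar = gstart, gcigar
        reads.append(
            SimulatedRead(
                read_id=f"read{i:06d}",
                contig=contig,
                start=start,
                sequence=sequence,
                base_qualities=quals,
                mapping_quality=mapping_quality,
                cigar=cigar,
            )
        )
    return reads


def iter_truth_pool_frequencies(
    truth: Sequence[TruthVariant], design: PoolDesign
) -> Iterator[tuple[tuple, np.ndarray]]:
    """Yield (site key, per-pool true frequency vector) for each truth site."""
    for v in truth:
        yield v.key, np.asarray(v.per_pool_alt_chromosomes) / design.chromosomes_per_pool
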