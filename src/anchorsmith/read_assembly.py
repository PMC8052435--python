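"""Demultiplexing, pair merging, read recruitment, extension assembly, and
ambiguity-aware consensus calling.

The assembly model is quasi-de novo: reads are recruited to divergent
per-locus references under the same spaced-seed + confirmation contract used
for genome scanning, laid out gaplessly (offsets only, no indel
realignment), and the growing consensus then serves as the reference while
the assembly is extended into less conserved flanking sequence.  Consensus
sequences are emitted only for clusters above an average-depth gate, with
IUPAC ambiguity codes at sites whose base frequencies cannot be explained
by the sequencing-error model.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .io_core import (
    ConfigError,
    IUPAC_FROM_SET,
    PipelineConfig,
    SequenceRecord,
    get_logger,
    reverse_complement,
)
from . import kmerlib

log = get_logger("anchorsmith.assembly")

UNDETERMINED = "undetermined"


# ---------------------------------------------------------------------------
# Demultiplexing


def default_index_of(read: SequenceRecord) -> str:
    """Index parsed from the read header: the last ':'-separated field of the
    id, ignoring a trailing /1 or /2 mate suffix (Illumina-style)."""
    name = read.id
    if name.endswith(("/1", "/2")):
        name = name[:-2]
    return name.rsplit(":", 1)[-1]


def load_index_map(path) -> dict:
    """TSV of sample<TAB>index -> {index: sample}; duplicate indexes refuse."""
    index_map: dict = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, index = line.split("\t")[:2]
            if index in index_map and index_map[index] != sample:
                raise ConfigError(f"index {index} assigned to both {index_map[index]} and {sample}")
            index_map[index] = sample
    return index_map


def demultiplex(reads: Iterable[SequenceRecord], index_map: dict, index_of=default_index_of) -> dict:
    """Group reads by sample; no index mismatches are tolerated.

    A read is assigned iff its index equals a map key exactly; every other
    read lands in the 'undetermined' bin.
    """
    bins: dict = {sample: [] for sample in index_map.values()}
    bins[UNDETERMINED] = []
    for read in reads:
        sample = index_map.get(index_of(read))
        if sample is None:
            bins[UNDETERMINED].append(read)
        else:
            read.sample = sample
            bins[sample].append(read)
    return bins


# ---------------------------------------------------------------------------
# Overlap merging


def merge_pairs(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 12,
    max_mismatch_rate: float = 0.1,
) -> Optional[SequenceRecord]:
    """Merge an overlapping pair; returns None when the pair does not merge.

    r2 is given in sequencing orientation (reverse strand) and is
    reverse-complemented before the gapless overlap search.  Within the
    overlap the higher-quality base wins; merged quality is max(q1, q2) on
    agreement and |q1 - q2| on conflict.  When the fragment is shorter than
    the read length, adapter bases read through beyond the fragment ends are
    removed: the merged read spans exactly the fragment.
    """
    if len(r1) == 0 or len(r2) == 0:
        return None
    a = kmerlib.encode(r1.residues)
    rc2 = r2.reverse_complement()
    b = kmerlib.encode(rc2.residues)
    qa = np.asarray(r1.qualities if r1.qualities is not None else [30] * len(a))
    qb = np.asarray(rc2.qualities if rc2.qualities is not None else [30] * len(b))
    la, lb = len(a), len(b)

    best = None  # (matches, overlap, shift)
    for s in range(-(lb - min_overlap), la - min_overlap + 1):
        a0, a1 = max(0, s), min(la, s + lb)
        o = a1 - a0
        if o < min_overlap:
            continue
        b0 = a0 - s
        mism = int(np.count_nonzero(a[a0:a1] != b[b0 : b0 + o]))
        if mism / o > max_mismatch_rate:
            continue
        cand = (o - mism, o, -abs(s))
        if best is None or cand > best[:3]:
            best = (o - mism, o, -abs(s), s)
    if best is None:
        return None
    s = best[3]
    # fragment spans [max(0, s')..]: with r1 starting the fragment, the merged
    # read covers positions 0 .. s+lb on r1's axis (bases past either end are
    # adapter read-through and are dropped).
    frag_len = s + lb
    if frag_len <= 0:
        return None
    out = np.empty(frag_len, dtype=np.uint8)
    qual = np.empty(frag_len, dtype=int)
    for i in range(frag_len):
        in_a = 0 <= i < la
        j = i - s
        in_b = 0 <= j < lb
        if in_a and in_b:
            if a[i] == b[j]:
                out[i], qual[i] = a[i], max(qa[i], qb[j])
            elif qa[i] >= qb[j]:
                out[i], qual[i] = a[i], abs(int(qa[i]) - int(qb[j]))
            else:
                out[i], qual[i] = b[j], abs(int(qa[i]) - int(qb[j]))
        elif in_a:
            out[i], qual[i] = a[i], qa[i]
        elif in_b:
            out[i], qual[i] = b[j], qb[j]
        else:  # gap between non-overlapping reads cannot occur post-merge test
            out[i], qual[i] = ord("N"), 0
    base_id = r1.id[:-2] if r1.id.endswith("/1") else r1.id
    return SequenceRecord(
        id=base_id + ":merged",
        residues=out.tobytes().decode("ascii"),
        qualities=[int(q) for q in qual],
        sample=r1.sample,
    )


def merge_read_pool(pairs: Sequence[tuple], min_overlap: int = 12, max_mismatch_rate: float = 0.1) -> list[SequenceRecord]:
    """Merge each (r1, r2); unmerged pairs contribute both mates as singles."""
    out = []
    for r1, r2 in pairs:
        merged = merge_pairs(r1, r2, min_overlap, max_mismatch_rate)
        if merged is not None:
            out.append(merged)
        else:
            out.append(r1)
            out.append(r2)
    return out


# ---------------------------------------------------------------------------
# Recruitment


@dataclass
class AlignedRead:
    """A read placed gaplessly on a locus axis (reference coordinates)."""

    read: SequenceRecord  # oriented to the reference strand
    offset: int
    strand: str
    identities: int
    locus_id: str


@dataclass
class RecruitmentResult:
    by_locus: dict  # locus_id -> list[AlignedRead]
    multi_locus: set  # read ids passing for >1 locus (kept in best locus)
    unassigned: list  # reads passing for no locus


def _read_kmer_hits(seq: str, k: int) -> list:
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            out.append((kmer, i))
    return out


def _best_placements(seq_fwd: str, seq_rev: str, index: dict, refs, config: PipelineConfig):
    """All valid placements of one read against indexed references.

    Returns a list of (identities, ref_idx, strand, offset) tuples.
    """
    placements = []
    for strand, seq in (("+", seq_fwd), ("-", seq_rev)):
        by_ref = kmerlib.candidate_offsets(seq, index, config.anchor_k)
        for ridx, diagonals in by_ref.items():
            hit = kmerlib.align_gapless(
                seq,
                refs[ridx].residues,
                diagonals,
                seed_window=config.seed_window,
                seed_min=config.seed_min_matches,
                confirm_window=config.confirm_window,
                confirm_min=config.confirm_min_matches,
                mode=config.confirm_mode,
            )
            if hit is not None and hit.valid:
                placements.append((hit.identities, ridx, strand, hit.offset))
    return placements


def recruit_reads(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    config: Optional[PipelineConfig] = None,
) -> RecruitmentResult:
    """Assign reads to loci under the seed + confirmation contract.

    A read goes to the locus of its best-scoring reference on either strand;
    reads passing for more than one locus go to the best and are flagged.
    References carry their locus in ``.locus`` (falling back to ``.id``).
    """
    config = config or PipelineConfig()
    index = kmerlib.build_anchor_index(references, config.anchor_k)
    locus_of = [ref.locus or ref.id for ref in references]
    by_locus: dict = {}
    multi: set = set()
    unassigned: list = []
    for read in reads:
        fwd = read.residues
        rev = reverse_complement(fwd)
        placements = _best_placements(fwd, rev, index, references, config)
        if not placements:
            unassigned.append(read)
            continue
        placements.sort(key=lambda p: (-p[0], locus_of[p[1]], p[2]))
        ident, ridx, strand, offset = placements[0]
        locus = locus_of[ridx]
        if any(locus_of[p[1]] != locus for p in placements[1:]):
            multi.add(read.id)
        oriented = read if strand == "+" else read.reverse_complement()
        by_locus.setdefault(locus, []).append(AlignedRead(oriented, offset, strand, ident, locus))
    return RecruitmentResult(by_locus=by_locus, multi_locus=multi, unassigned=unassigned)


# ---------------------------------------------------------------------------
# Assembly clusters


_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class AssemblyCluster:
    """Per-locus, per-sample gapless read layout with per-site base counts.

    Offsets live on the locus reference axis (reference start = 0); the
    consensus spans [start, end) on that axis.  Only A/C/G/T read bases are
    tallied -- an N in a read covers a site without voting.
    """

    locus_id: str
    sample: str
    reads: list = field(default_factory=list)
    offsets: dict = field(default_factory=dict)

    @classmethod
    def from_recruitment(cls, locus_id: str, sample: str, aligned: Sequence[AlignedRead]) -> "AssemblyCluster":
        cluster = cls(locus_id=locus_id, sample=sample)
        for ar in aligned:
            cluster.add(ar.read, ar.offset)
        return cluster

    def add(self, read: SequenceRecord, offset: int) -> None:
        if read.id in self.offsets:
            raise ValueError(f"read {read.id} already in cluster {self.locus_id}")
        self.reads.append(read)
        self.offsets[read.id] = offset

    @property
    def start(self) -> int:
        return min(self.offsets.values()) if self.offsets else 0

    @property
    def end(self) -> int:
        return max(self.offsets[r.id] + len(r) for r in self.reads) if self.reads else 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def site_counts(self) -> np.ndarray:
        """(4, L) base tallies over the consensus span, rows A/C/G/T."""
        counts = np.zeros((4, max(self.length, 0)), dtype=np.int32)
        origin = self.start
        for read in self.reads:
            off = self.offsets[read.id] - origin
            codes = _BASE_INDEX[kmerlib.encode(read.residues)]
            valid = codes >= 0
            pos = np.arange(len(codes))[valid] + off
            np.add.at(counts, (codes[valid], pos), 1)
        return counts

    def avg_depth(self) -> float:
        if self.length == 0:
            return 0.0
        return float(self.site_counts().sum()) / self.length

    def consensus_string(self, counts: Optional[np.ndarray] = None) -> str:
        """Plain majority consensus used as the extension reference; ties go
        to the alphabetically first base, uncovered sites to N."""
        if counts is None:
            counts = self.site_counts()
        if counts.shape[1] == 0:
            return ""
        best = np.argmax(counts, axis=0)
        depth = counts.sum(axis=0)
        out = np.frombuffer(b"ACGT", dtype=np.uint8)[best].copy()
        out[depth == 0] = ord("N")
        return out.tobytes().decode("ascii")


def make_clusters(result: RecruitmentResult, sample: str) -> dict:
    return {
        locus: AssemblyCluster.from_recruitment(locus, sample, aligned)
        for locus, aligned in result.by_locus.items()
    }


# ---------------------------------------------------------------------------
# Extension assembly


class _ReadScanCache:
    """Pre-tokenised anchor k-mers per read and orientation, shared across
    loci and iterations so the unassigned pool is cheap to rescan."""

    def __init__(self, reads: Sequence[SequenceRecord], k: int):
        self.k = k
        self.reads = {r.id: r for r in reads}
        self.tokens = {}
        for r in reads:
            fwd = r.residues
            rev = reverse_complement(fwd)
            self.tokens[r.id] = (
                (fwd, _read_kmer_hits(fwd, k)),
                (rev, _read_kmer_hits(rev, k)),
            )


def _scan_cached(tokens, index: dict, consensus: str, config: PipelineConfig):
    """Valid placements of a cached read against one consensus index."""
    placements = []
    for strand, (seq, kmer_hits) in zip("+-", tokens):
        votes: Counter = Counter()
        for kmer, i in kmer_hits:
            for _ridx, pos in index.get(kmer, ()):
                votes[i - pos] += 1
        if not votes:
            continue
        diagonals = [d for d, _ in votes.most_common(6)]
        hit = kmerlib.align_gapless(
            seq,
            consensus,
            diagonals,
            seed_window=config.seed_window,
            seed_min=config.seed_min_matches,
            confirm_window=config.confirm_window,
            confirm_min=config.confirm_min_matches,
            mode=config.confirm_mode,
        )
        if hit is not None and hit.valid:
            placements.append((hit.identities, strand, hit.offset))
    return placements


def extend_all(
    clusters: dict,
    unassigned_reads: Sequence[SequenceRecord],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Iteratively extend every cluster from a shared unassigned pool.

    Each round rebuilds every consensus, rescans the remaining pool under
    the same seed + confirmation criteria, and claims passing reads for the
    best-matching cluster; rounds repeat until none adds a read.  A read
    whose two best placements tie with incompatible offsets is rejected and
    logged.  The recruited set grows monotonically and the pool shrinks, so
    at most ``len(unassigned_reads)`` productive rounds can occur.
    """
    config = config or PipelineConfig()
    pool = sorted(unassigned_reads, key=lambda r: r.id)
    cache = _ReadScanCache(pool, config.anchor_k)
    max_rounds = len(pool) + 1
    for _round in range(max_rounds):
        if not pool:
            break
        consensi = {}
        indexes = {}
        starts = {}
        for locus, cluster in sorted(clusters.items()):
            if not cluster.reads:
                continue
            cons = cluster.consensus_string()
            consensi[locus] = cons
            indexes[locus] = kmerlib.build_anchor_index([cons], config.anchor_k)
            starts[locus] = cluster.start
        claimed = []
        rejected = []
        for read in pool:
            candidates = []  # (identities, locus, strand, offset)
            for locus, cons in consensi.items():
                for ident, strand, offset in _scan_cached(
                    cache.tokens[read.id], indexes[locus], cons, config
                ):
                    candidates.append((ident, locus, strand, offset))
            if not candidates:
                continue
            candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
            best = candidates[0]
            ties = [c for c in candidates if c[0] == best[0] and (c[2], c[3]) != (best[2], best[3])]
            if ties:
                log.info("read %s has conflicting placements; rejected", read.id)
                rejected.append(read)
                continue
            ident, locus, strand, offset = best
            cluster = clusters[locus]
            oriented = read if strand == "+" else read.reverse_complement()
            # offset is in round-start consensus coordinates; shift to the axis
            cluster.add(oriented, starts[locus] + offset)
            claimed.append(read)
        drop = {r.id for r in claimed} | {r.id for r in rejected}
        pool = [r for r in pool if r.id not in drop]
        if not claimed:
            break
    return clusters


def extend_assembly(
    cluster: AssemblyCluster,
    unassigned_reads: Sequence[SequenceRecord],
    config: Optional[PipelineConfig] = None,
) -> AssemblyCluster:
    """Extend one cluster (see :func:`extend_all`); no reads -> fixed point."""
    extend_all({cluster.locus_id: cluster}, unassigned_reads, config)
    return cluster


# ---------------------------------------------------------------------------
# Consensus calling


@dataclass
class ConsensusSequence:
    """IUPAC consensus with the per-site evidence that produced it."""

    locus_id: str
    sample: str
    residues: str
    depth: np.ndarray
    retained: list  # per-site frozenset of retained bases

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(
            id=f"{self.sample}::{self.locus_id}",
            residues=self.residues,
            sample=self.sample,
            locus=self.locus_id,
        )


def _min_significant_count(n: int, p: float, alpha: float, cache: dict) -> int:
    """Smallest count c with P(X >= c | n, p) < alpha (one-sided exact tail)."""
    if n not in cache:
        c = 1
        while c <= n and binom.sf(c - 1, n, p) >= alpha:
            c += 1
        cache[n] = c
    return cache[n]


def call_consensus(
    cluster: AssemblyCluster, config: Optional[PipelineConfig] = None
) -> Optional[ConsensusSequence]:
    """IUPAC consensus of a cluster, or None when the depth gate fails.

    The cluster is emitted only if average depth (aligned bases / consensus
    length) is strictly greater than ``min_avg_depth``.  At each site the
    majority base is always retained (a tie retains both, logged); a
    minority base with count c at depth n is retained iff the one-sided
    exact binomial tail P(X >= c | n, p) is below ``alpha``, where p is the
    per-base error rate toward a specific base (``error_rate``, or
    ``error_rate``/3 with the three-way partition flag).  Uncovered sites
    are N.
    """
    config = config or PipelineConfig()
    counts = cluster.site_counts()
    L = counts.shape[1]
    if L == 0:
        return None
    total = int(counts.sum())
    avg_depth = total / L
    log.info(
        "cluster %s/%s: %d reads, avg depth %.1f",
        cluster.sample, cluster.locus_id, len(cluster.reads), avg_depth,
    )
    if not avg_depth > config.min_avg_depth:
        log.info("cluster %s/%s rejected by depth gate", cluster.sample, cluster.locus_id)
        return None
    p = config.error_rate / 3 if config.error_partition_three else config.error_rate
    cache: dict = {}
    residues = []
    retained_sets = []
    depth = counts.sum(axis=0)
    bases = "ACGT"
    for j in range(L):
        n = int(depth[j])
        if n == 0:
            residues.append("N")
            retained_sets.append(frozenset())
            continue
        col = counts[:, j]
        top = int(col.max())
        retained = {bases[i] for i in range(4) if col[i] == top}
        if len(retained) > 1:
            log.info("majority tie at site %d of %s/%s", j, cluster.sample, cluster.locus_id)
        cmin = _min_significant_count(n, p, config.alpha, cache)
        for i in range(4):
            c = int(col[i])
            if 0 < c < top and c >= cmin:
                retained.add(bases[i])
        retained_sets.append(frozenset(retained))
        residues.append(IUPAC_FROM_SET[frozenset(retained)])
    return ConsensusSequence(
        locus_id=cluster.locus_id,
        sample=cluster.sample,
        residues="".join(residues),
        depth=depth,
        retained=retained_sets,
    )


def cluster_site_table(cluster: AssemblyCluster) -> list:
    """Rows (site, A, C, G, T, depth) for the TSV cluster dump."""
    counts = cluster.site_counts()
    depth = counts.sum(axis=0)
    return [
        (j, int(counts[0, j]), int(counts[1, j]), int(counts[2, j]), int(counts[3, j]), int(depth[j]))
        for j in range(counts.shape[1])
    ]
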