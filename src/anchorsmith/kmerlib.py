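"""k-mer enumeration, spaced-seed matching, profiles, and gapless search.

Shared by target discovery (genome scanning), read recruitment, orthology
(20-mer Jaccard distances), locus dedup, and repeat masking.  The matching
contract is a 17-of-20 spaced-seed window followed by a 55-of-100
confirmation window; :func:`seed_match` and :func:`confirm_match` state that
contract literally, while :func:`align_gapless` applies it efficiently along
candidate gapless offsets proposed by exact shared anchor k-mers.

k-mers containing N (or any non-ACGT symbol) are skipped everywhere.
Strand handling follows the pipeline convention: scanning is strand-explicit
(both strands scanned separately); profiles used for orthology, dedup, and
coverage use the canonical (lexicographically smaller of k-mer and reverse
complement) form, because the identity of a locus is strand-free.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .io_core import SequenceRecord, get_logger, reverse_complement, write_tsv

log = get_logger("anchorsmith.kmerlib")

_ACGT = frozenset("ACGT")


def _residues(seq: Union[str, SequenceRecord]) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq


def _source_id(seq: Union[str, SequenceRecord]) -> str:
    return seq.id if isinstance(seq, SequenceRecord) else ""


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class SpacedSeedPattern:
    """Boolean care-mask over a seed window; True positions are compared.

    The published pattern is not reproduced in the protocol text, so the
    default is all-care (a contiguous window with a mismatch budget).
    """

    care_mask: tuple
    weight: int = field(init=False)

    def __post_init__(self) -> None:
        self.care_mask = tuple(bool(x) for x in self.care_mask)
        self.weight = sum(self.care_mask)

    def __len__(self) -> int:
        return len(self.care_mask)

    @classmethod
    def all_care(cls, length: int = 20) -> "SpacedSeedPattern":
        return cls((True,) * length)

    @classmethod
    def from_string(cls, template: str) -> "SpacedSeedPattern":
        """Parse e.g. '1110111' where 1 = care position."""
        return cls(tuple(c == "1" for c in template))


@dataclass
class KmerProfile:
    """Multiset of k-mers from one source sequence (or read set)."""

    k: Union[int, str]
    counts: dict
    source_id: str = ""
    canonical: bool = False

    @property
    def distinct(self) -> frozenset:
        return frozenset(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def merge(self, other: "KmerProfile") -> "KmerProfile":
        if self.k != other.k or self.canonical != other.canonical:
            raise ValueError("cannot merge profiles with differing k/canonicalization")
        merged = Counter(self.counts)
        merged.update(other.counts)
        return KmerProfile(self.k, dict(merged), self.source_id, self.canonical)

    def to_tsv(self, path) -> None:
        write_tsv(path, ["kmer", "count"], sorted(self.counts.items()))


def _count_kmers(residues: str, k: int, canonical: bool, counts: Counter) -> None:
    for i in range(len(residues) - k + 1):
        kmer = residues[i : i + k]
        if not _ACGT.issuperset(kmer):
            continue
        counts[canonical_kmer(kmer) if canonical else kmer] += 1


def enumerate_kmers(
    seq: Union[str, SequenceRecord], k: Union[int, str], canonical: bool = False
) -> KmerProfile:
    """All length-k windows of a sequence; k='all' takes every length 1..L.

    k longer than the sequence yields an empty profile with a warning.
    """
    residues = _residues(seq).upper()
    counts: Counter = Counter()
    if k == "all":
        for kk in range(1, len(residues) + 1):
            _count_kmers(residues, kk, canonical, counts)
    else:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k > len(residues):
            log.warning("k=%d exceeds sequence length %d; empty profile", k, len(residues))
        else:
            _count_kmers(residues, k, canonical, counts)
    return KmerProfile(k=k, counts=dict(counts), source_id=_source_id(seq), canonical=canonical)


def profile_from_reads(
    reads: Iterable[Union[str, SequenceRecord]], k: int, canonical: bool = True, source_id: str = ""
) -> KmerProfile:
    """Pooled k-mer multiset over a read set (canonical by default)."""
    counts: Counter = Counter()
    for read in reads:
        _count_kmers(_residues(read).upper(), k, canonical, counts)
    return KmerProfile(k=k, counts=dict(counts), source_id=source_id, canonical=canonical)


def seed_match(
    window: str,
    ref: str,
    pattern: Optional[SpacedSeedPattern] = None,
    min_matches: int = 17,
) -> bool:
    """True iff >= min_matches care positions agree; N never matches."""
    if pattern is None:
        pattern = SpacedSeedPattern.all_care(len(window))
    if len(window) != len(ref) or len(window) != len(pattern):
        raise ValueError(
            f"seed_match length mismatch: window {len(window)}, ref {len(ref)}, "
            f"pattern {len(pattern)}"
        )
    matches = 0
    for care, a, b in zip(pattern.care_mask, window.upper(), ref.upper()):
        if care and a == b and a in _ACGT:
            matches += 1
    return matches >= min_matches


def confirm_match(
    query: str,
    ref: str,
    anchor: int,
    confirm_window: int = 100,
    confirm_min: int = 55,
    mode: str = "aligned",
) -> bool:
    """Confirmation test around a seed anchor on a gapless alignment.

    ``query`` and ``ref`` are compared position-by-position (the caller has
    already placed them at a common offset).  The test passes iff the best
    window of ``confirm_window`` bases containing ``anchor`` holds at least
    ``confirm_min`` identities ('aligned' mode), or an exact-match run of at
    least that many bases ('consecutive' mode).  Windows clipped at sequence
    ends scale the threshold proportionally.
    """
    length = min(len(query), len(ref))
    if not 0 <= anchor < len(query):
        raise ValueError(f"anchor {anchor} outside query of length {len(query)}")
    if length == 0:
        return False
    q = query.upper()
    r = ref.upper()
    matches = [q[i] == r[i] and q[i] in _ACGT for i in range(length)]
    # full-length windows whenever one fits; the threshold scales down only
    # when the whole comparable region is shorter than the window
    w = min(confirm_window, length)
    lo = max(0, anchor - w + 1)
    hi = min(anchor, length - w)
    for start in range(lo, hi + 1):
        stop = start + w
        wlen = stop - start
        need = math.ceil(confirm_min * wlen / confirm_window)
        if mode == "aligned":
            if sum(matches[start:stop]) >= need:
                return True
        elif mode == "consecutive":
            run = best = 0
            for m in matches[start:stop]:
                run = run + 1 if m else 0
                best = max(best, run)
            if best >= need:
                return True
        else:
            raise ValueError(f"unknown confirm mode {mode!r}")
    return False


def profile_distance(a: KmerProfile, b: KmerProfile, weighted: bool = False) -> float:
    """Jaccard distance between k-mer sets: 1 - |A n B| / |A u B|.

    With ``weighted=True``, multiplicities are compared instead
    (1 - sum(min)/sum(max) over the key union).
    """
    if a.k != b.k:
        raise ValueError(f"profile k mismatch: {a.k} vs {b.k}")
    if not a.counts and not b.counts:
        log.warning("profile_distance on two empty profiles; returning 1")
        return 1.0
    if weighted:
        union = set(a.counts) | set(b.counts)
        num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in union)
        den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in union)
        return 1.0 - num / den
    sa, sb = a.distinct, b.distinct
    inter = len(sa & sb)
    union_n = len(sa | sb)
    return 1.0 - inter / union_n


def coverage_track(
    target: Union[str, SequenceRecord], read_profile: KmerProfile
) -> np.ndarray:
    """Per-position mean multiplicity (in the read profile) of covering k-mers.

    Positions with no full covering k-mer take the nearest defined value; a
    target shorter than k gets a single uniform whole-sequence lookup.
    """
    residues = _residues(target).upper()
    k = read_profile.k
    if not isinstance(k, int):
        raise ValueError("coverage_track requires a fixed-k profile")
    L = len(residues)
    if L < k:
        key = canonical_kmer(residues) if read_profile.canonical else residues
        return np.full(L, float(read_profile.counts.get(key, 0)))
    n_kmers = L - k + 1
    counts = np.zeros(n_kmers, dtype=float)
    for j in range(n_kmers):
        kmer = residues[j : j + k]
        if not _ACGT.issuperset(kmer):
            continue
        key = canonical_kmer(kmer) if read_profile.canonical else kmer
        counts[j] = read_profile.counts.get(key, 0)
    csum = np.concatenate(([0.0], np.cumsum(counts)))
    track = np.empty(L, dtype=float)
    for i in range(L):
        j0 = max(0, i - k + 1)
        j1 = min(i, n_kmers - 1)
        track[i] = (csum[j1 + 1] - csum[j0]) / (j1 - j0 + 1)
    return track


def coverage_track_to_bed(track: np.ndarray, contig: str, path) -> None:
    rows = [(contig, i, i + 1, f"{contig}:{i}", f"{v:.3f}", "+") for i, v in enumerate(track)]
    write_tsv(path, ["#contig", "start", "end", "name", "score", "strand"], rows)


# ---------------------------------------------------------------------------
# Gapless anchored search engine


def encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8)


_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, _ACGT_CODES)


def build_anchor_index(
    refs: Sequence[Union[str, SequenceRecord]], k: int, max_positions: int = 64
) -> dict:
    """Exact k-mer -> list of (ref index, position); hyper-repetitive k-mers
    (more than max_positions placements) are dropped as uninformative."""
    index: dict = {}
    for ridx, ref in enumerate(refs):
        residues = _residues(ref).upper()
        for pos in range(len(residues) - k + 1):
            kmer = residues[pos : pos + k]
            if not _ACGT.issuperset(kmer):
                continue
            index.setdefault(kmer, []).append((ridx, pos))
    return {kmer: posns for kmer, posns in index.items() if len(posns) <= max_positions}


def candidate_offsets(
    query: str, index: dict, k: int, max_offsets_per_ref: int = 6
) -> dict:
    """Vote gapless diagonals between a query and indexed references.

    Returns {ref index: [d, ...]} with diagonals ordered by vote count,
    where d = query position - reference position of a shared exact k-mer;
    the query start then sits at reference coordinate -d.  Feed these
    directly to :func:`align_gapless`.
    """
    votes: Counter = Counter()
    q = query.upper()
    for i in range(len(q) - k + 1):
        kmer = q[i : i + k]
        hits = index.get(kmer)
        if not hits:
            continue
        for ridx, pos in hits:
            votes[(ridx, i - pos)] += 1
    by_ref: dict = {}
    for (ridx, d), _count in votes.most_common():
        offs = by_ref.setdefault(ridx, [])
        if len(offs) < max_offsets_per_ref:
            offs.append(d)
    return by_ref


@dataclass
class GaplessHit:
    """A validated gapless placement of a query against a reference.

    ``offset`` is the query start position expressed in reference
    coordinates (query position i aligns to reference position i + offset...
    see :func:`align_gapless`).  Spans are 0-based half-open on each axis.
    """

    offset: int
    identities: int
    overlap: int
    seed_ok: bool
    confirm_ok: bool
    query_span: tuple
    ref_span: tuple

    @property
    def valid(self) -> bool:
        return self.seed_ok and self.confirm_ok


def evaluate_offset(
    qa: np.ndarray,
    ra: np.ndarray,
    ref_offset: int,
    seed_window: int = 20,
    seed_min: int = 17,
    confirm_window: int = 100,
    confirm_min: int = 55,
    mode: str = "aligned",
    care: Optional[np.ndarray] = None,
) -> Optional[GaplessHit]:
    """Apply the seed + confirmation contract at one gapless offset.

    ``ref_offset`` places query position 0 at reference coordinate
    ``ref_offset`` (may be negative).  Query position i aligns to reference
    position i + ref_offset over the overlap of the two sequences.
    """
    qs = max(0, -ref_offset)
    qe = min(len(qa), len(ra) - ref_offset)
    if qe - qs < seed_window:
        return None
    q = qa[qs:qe]
    r = ra[qs + ref_offset : qe + ref_offset]
    m = (q == r) & _valid_mask(q) & _valid_mask(r)
    L = len(m)
    cm = np.concatenate(([0], np.cumsum(m)))
    if care is None:
        seed_sums = cm[seed_window:] - cm[:-seed_window]
    else:
        seed_sums = np.correlate(m.astype(np.int32), care.astype(np.int32), mode="valid")
    seed_pos = np.flatnonzero(seed_sums >= seed_min)
    identities = int(cm[-1])
    if seed_pos.size == 0:
        return GaplessHit(ref_offset, identities, L, False, False, (qs, qe), (qs + ref_offset, qe + ref_offset))
    w = min(confirm_window, L)
    need = math.ceil(confirm_min * w / confirm_window)
    if mode == "aligned":
        conf_sums = cm[w:] - cm[:-w]
        conf_pass = conf_sums >= need
    elif mode == "consecutive":
        # run_end[i] = length of exact-match run ending at i
        run_end = np.zeros(L, dtype=np.int64)
        run = 0
        mm = m.tolist()
        for i, hit in enumerate(mm):
            run = run + 1 if hit else 0
            run_end[i] = run
        conf_pass = np.zeros(L - w + 1, dtype=bool)
        for p in np.flatnonzero(run_end >= need):
            lo = max(0, p - w + 1)
            hi = min(p - need + 1, L - w)
            if hi >= lo:
                conf_pass[lo : hi + 1] = True
    else:
        raise ValueError(f"unknown confirm mode {mode!r}")
    # a confirmation window must contain a seed-hit anchor (the seed window start)
    cp = np.concatenate(([0], np.cumsum(conf_pass)))
    confirm_ok = False
    for s in seed_pos:
        lo = max(0, int(s) - w + 1)
        hi = min(int(s), L - w)
        if hi >= lo and cp[hi + 1] - cp[lo] > 0:
            confirm_ok = True
            break
    return GaplessHit(
        ref_offset,
        identities,
        L,
        True,
        bool(confirm_ok),
        (qs, qe),
        (qs + ref_offset, qe + ref_offset),
    )


def align_gapless(
    query: str,
    ref: str,
    offsets: Iterable[int],
    seed_window: int = 20,
    seed_min: int = 17,
    confirm_window: int = 100,
    confirm_min: int = 55,
    mode: str = "aligned",
    care: Optional[np.ndarray] = None,
) -> Optional[GaplessHit]:
    """Best valid gapless hit among candidate offsets (max identities)."""
    qa = encode(query)
    ra = encode(ref)
    best: Optional[GaplessHit] = None
    for d in offsets:
        hit = evaluate_offset(
            qa, ra, -d, seed_window, seed_min, confirm_window, confirm_min, mode, care
        )
        if hit is None or not hit.valid:
            continue
        if best is None or hit.identities > best.identities:
            best = hit
    return best
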