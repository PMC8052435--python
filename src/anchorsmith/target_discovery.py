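"""Conserved anchor-target discovery.

Reciprocal best-match pairing of two transcript sets locates loci present in
both, and genome scanning under the spaced-seed + confirmation contract
places each locus on an assembly, keeping a candidate window (default
10 kb) around every validated hit cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_core import PipelineConfig, SequenceRecord, get_logger, reverse_complement
from . import kmerlib

log = get_logger("anchorsmith.discovery")


@dataclass
class ReciprocalPair:
    """A transcript pair in which each member is the other's best match."""

    id_a: str
    id_b: str
    score_ab: int
    score_ba: int


@dataclass
class LocusTarget:
    """A candidate anchor window on a genome contig (0-based half-open)."""

    locus_id: str
    contig: str
    start: int
    end: int
    strand: str
    seed_reference: str
    hit_positions: list = field(default_factory=list)


def reciprocal_best_pairs(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    config: Optional[PipelineConfig] = None,
) -> list[ReciprocalPair]:
    """Pair transcripts that are mutual best matches.

    The match score is the number of shared canonical k-mers (k =
    ``config.kmer_k``), an internal stand-in for an aligner bit-score; an
    adapter can substitute external scores by calling
    :func:`reciprocal_from_scores` directly.  Ties are broken toward the
    lexicographically smaller id and logged.  Transcripts with no shared
    k-mers remain unpaired.
    """
    config = config or PipelineConfig()
    if not set_a or not set_b:
        raise ValueError("reciprocal_best_pairs requires two non-empty sets")
    k = config.kmer_k
    profiles_a = {rec.id: kmerlib.enumerate_kmers(rec, k, canonical=True).distinct for rec in set_a}
    profiles_b = {rec.id: kmerlib.enumerate_kmers(rec, k, canonical=True).distinct for rec in set_b}
    scores = {
        (ida, idb): len(sa & sb)
        for ida, sa in profiles_a.items()
        for idb, sb in profiles_b.items()
    }
    return reciprocal_from_scores(list(profiles_a), list(profiles_b), scores)


def _argmax(candidates: list, score_of) -> Optional[str]:
    best_id, best_score = None, 0
    for cid in sorted(candidates):
        s = score_of(cid)
        if s > best_score:
            best_id, best_score = cid, s
        elif s == best_score and s > 0 and best_id is not None:
            log.info("best-match tie between %s and %s; keeping %s", best_id, cid, best_id)
    return best_id


def reciprocal_from_scores(ids_a: list, ids_b: list, scores: dict) -> list[ReciprocalPair]:
    """Reciprocal-best contract over an arbitrary {(a, b): score} table."""
    best_for_a = {a: _argmax(ids_b, lambda b: scores.get((a, b), 0)) for a in ids_a}
    best_for_b = {b: _argmax(ids_a, lambda a: scores.get((a, b), 0)) for b in ids_b}
    pairs = []
    for a in sorted(ids_a):
        b = best_for_a[a]
        if b is not None and best_for_b[b] == a:
            pairs.append(ReciprocalPair(a, b, scores[(a, b)], scores[(a, b)]))
    unpaired = [a for a in ids_a if best_for_a[a] is None]
    if unpaired:
        log.info("%d transcripts had no match and remain unpaired", len(unpaired))
    return pairs


def _scan_oriented(
    contig_seq: str,
    refs: Sequence[SequenceRecord],
    index: dict,
    config: PipelineConfig,
) -> list[tuple]:
    """Validated hits of any reference against one contig orientation.

    Returns (start, end, ref_id, identities) tuples in scanned coordinates,
    where [start, end) is the confirmed overlap span on the contig.
    """
    by_ref = kmerlib.candidate_offsets(contig_seq, index, config.anchor_k)
    hits = []
    for ridx, diagonals in by_ref.items():
        ref = refs[ridx]
        spans_seen = set()
        for d in diagonals:  # every diagonal separately: a reference can hit twice
            hit = kmerlib.align_gapless(
                ref.residues,
                contig_seq,
                [-d],  # contig diagonal -> ref-vs-contig offset
                seed_window=config.seed_window,
                seed_min=config.seed_min_matches,
                confirm_window=config.confirm_window,
                confirm_min=config.confirm_min_matches,
                mode=config.confirm_mode,
            )
            if hit is not None and hit.valid and hit.ref_span not in spans_seen:
                spans_seen.add(hit.ref_span)
                hits.append((hit.ref_span[0], hit.ref_span[1], ref.id, hit.identities))
    return hits


def scan_genome(
    genome: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    config: Optional[PipelineConfig] = None,
) -> list[LocusTarget]:
    """Scan both strands of a genome for windows matching any reference.

    Every candidate placement (proposed by exact shared anchor k-mers) is
    validated with the seed + confirmation contract; validated hits within
    ``target_window`` of each other on the same contig and strand are merged
    leftmost-first into one :class:`LocusTarget` whose window is centered on
    the hit span and clipped to the contig.  The target is labelled with the
    reference contributing the most confirmed identities.
    """
    config = config or PipelineConfig()
    index = kmerlib.build_anchor_index(references, config.anchor_k)
    raw: list = []  # (contig, strand, start, end, ref_id, identities) forward coords
    for contig in genome:
        L = len(contig)
        if L < config.seed_window:
            log.warning("contig %s shorter than seed window; skipped", contig.id)
            continue
        for strand in "+-":
            seq = contig.residues if strand == "+" else reverse_complement(contig.residues)
            for start, end, ref_id, ident in _scan_oriented(seq, references, index, config):
                if strand == "-":
                    start, end = L - end, L - start
                raw.append((contig.id, strand, start, end, ref_id, ident))

    # leftmost-first greedy merge of hits within target_window on one contig/strand
    contig_len = {c.id: len(c) for c in genome}
    grouped: dict = {}
    for contig_id, strand, start, end, ref_id, ident in raw:
        grouped.setdefault((contig_id, strand), []).append((start, end, ref_id, ident))
    targets = []
    for (contig_id, strand), hits in sorted(grouped.items()):
        hits.sort()
        cluster: list = []
        clusters = []
        for hit in hits:
            if cluster and hit[0] - cluster[-1][1] > config.target_window:
                clusters.append(cluster)
                cluster = []
            cluster.append(hit)
        if cluster:
            clusters.append(cluster)
        for cluster in clusters:
            span_start = min(h[0] for h in cluster)
            span_end = max(h[1] for h in cluster)
            center = (span_start + span_end) // 2
            half = config.target_window // 2
            L = contig_len[contig_id]
            start = center - half
            end = start + config.target_window
            if start < 0:
                start, end = 0, min(L, config.target_window)
            if end > L:
                end, start = L, max(0, L - config.target_window)
            best_ref = max(cluster, key=lambda h: (h[3], h[2]))[2]
            targets.append(
                LocusTarget(
                    locus_id="",
                    contig=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    seed_reference=best_ref,
                    hit_positions=[h[0] for h in cluster],
                )
            )
    targets.sort(key=lambda t: (t.contig, t.start, t.strand))
    for i, t in enumerate(targets):
        t.locus_id = f"L{i:03d}"
    log.info("scan_genome: %d validated hit clusters", len(targets))
    return targets


def extract_windows(
    genome: Sequence[SequenceRecord], targets: Sequence[LocusTarget]
) -> list[SequenceRecord]:
    """Slice target windows out of the genome; minus-strand windows are
    reverse-complemented so every window reads in reference orientation."""
    contigs = {c.id: c.residues for c in genome}
    out = []
    for t in targets:
        seq = contigs[t.contig]
        if not (0 <= t.start < t.end <= len(seq)):
            raise ValueError(f"target {t.locus_id} outside contig {t.contig}")
        window = seq[t.start : t.end]
        if t.strand == "-":
            window = reverse_complement(window)
        out.append(SequenceRecord(id=t.locus_id, residues=window, locus=t.locus_id))
    return out
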