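"""Alignment trimming, masking, filtering, dedup, and supermatrix export.

QC never edits a character: it only masks cells (the boolean mask layer) or
removes whole sites/loci.  Thresholds follow the published protocol: a site
is reliable when its modal non-gap character reaches 50% (inclusive); a run
of 14+ consecutive reliable-site disagreements is masked in that sequence;
sites present in fewer than 25 sequences are removed; loci represented by
less than half the panel are removed; loci sharing any 20-mer are
de-duplicated; regions with substantially elevated k-mer coverage in the
WGS reads (default 5x the per-sequence median) are masked as repetitive.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_core import PipelineConfig, SequenceRecord, get_logger, write_tsv
from . import kmerlib

log = get_logger("anchorsmith.alignment_qc")

_GAP = ord("-")


@dataclass
class AlignmentMatrix:
    """Taxa x sites character matrix with an explicit exclusion mask.

    ``chars`` is a (taxa, sites) uint8 matrix over {A,C,G,T,IUPAC,-};
    ``mask`` is boolean with the same shape, True = excluded.  Masked cells
    never contribute to site statistics.  ``site_map`` records original
    column indices after sites have been dropped.
    """

    taxa: list
    chars: np.ndarray
    mask: np.ndarray = None
    locus_id: str = ""
    site_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chars = np.asarray(self.chars, dtype=np.uint8)
        if self.chars.ndim != 2 or self.chars.shape[0] != len(self.taxa):
            raise ValueError("alignment matrix is not rectangular over its taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"duplicate taxon in locus {self.locus_id!r}")
        if self.mask is None:
            self.mask = np.zeros(self.chars.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.chars.shape:
            raise ValueError("mask shape does not match matrix shape")

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord], locus_id: str = "") -> "AlignmentMatrix":
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in alignment {locus_id!r}: {sorted(lengths)}")
        chars = np.vstack([kmerlib.encode(r.residues) for r in records]) if records else np.zeros((0, 0), np.uint8)
        return cls(taxa=[r.id for r in records], chars=chars, locus_id=locus_id)

    @property
    def n_taxa(self) -> int:
        return self.chars.shape[0]

    @property
    def n_sites(self) -> int:
        return self.chars.shape[1]

    def sequence(self, i: int) -> str:
        return self.chars[i].tobytes().decode("ascii")

    def to_records(self) -> list:
        return [SequenceRecord(id=t, residues=self.sequence(i)) for i, t in enumerate(self.taxa)]

    def copy(self) -> "AlignmentMatrix":
        return AlignmentMatrix(
            list(self.taxa), self.chars.copy(), self.mask.copy(), self.locus_id,
            None if self.site_map is None else self.site_map.copy(),
        )


def _present(aln: AlignmentMatrix) -> np.ndarray:
    """Unmasked non-gap cells."""
    return (~aln.mask) & (aln.chars != _GAP)


def _modal(aln: AlignmentMatrix):
    """Per-site modal non-gap character (ties -> smallest byte) and its count,
    plus the count of unmasked non-gap characters."""
    present = _present(aln)
    total = present.sum(axis=0)
    modal_char = np.full(aln.n_sites, _GAP, dtype=np.uint8)
    modal_count = np.zeros(aln.n_sites, dtype=int)
    for value in sorted(np.unique(aln.chars)):
        if value == _GAP:
            continue
        count = ((aln.chars == value) & present).sum(axis=0)
        better = count > modal_count
        modal_count = np.where(better, count, modal_count)
        modal_char = np.where(better, value, modal_char)
    return modal_char, modal_count, total


def identify_reliable_sites(aln: AlignmentMatrix, threshold: float = 0.5) -> np.ndarray:
    """A site is reliable iff its modal non-gap character reaches ``threshold``
    (inclusive) among unmasked non-gap characters; gap-only sites are not."""
    _char, modal_count, total = _modal(aln)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, modal_count / np.maximum(total, 1), 0.0)
    return (total > 0) & (frac >= threshold)


def _true_runs(mask_1d: np.ndarray):
    """(start, stop) of maximal True runs."""
    padded = np.concatenate(([False], mask_1d, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return zip(starts, stops)


def mask_misaligned_regions(
    aln: AlignmentMatrix, run_threshold: int = 14, threshold: float = 0.5
) -> AlignmentMatrix:
    """Mask runs of >= run_threshold consecutive reliable-site disagreements.

    For each sequence, a run consists of consecutive reliable sites at which
    the sequence has a non-gap character different from the site's modal
    character; agreement, a gap, or an unreliable site breaks the run.  Only
    the offending sequence is masked.
    """
    out = aln.copy()
    reliable = identify_reliable_sites(out, threshold)
    modal_char, _count, _total = _modal(out)
    for i in range(out.n_taxa):
        row = out.chars[i]
        disagree = reliable & (row != _GAP) & (row != modal_char) & (~out.mask[i])
        for start, stop in _true_runs(disagree):
            if stop - start >= run_threshold:
                out.mask[i, start:stop] = True
    return out


def drop_sparse_sites(aln: AlignmentMatrix, min_sequences: int = 25) -> AlignmentMatrix:
    """Remove sites with fewer than ``min_sequences`` unmasked non-gap
    characters; surviving original coordinates are kept in ``site_map``."""
    present_count = _present(aln).sum(axis=0)
    keep = present_count >= min_sequences
    prior = aln.site_map if aln.site_map is not None else np.arange(aln.n_sites)
    return AlignmentMatrix(
        list(aln.taxa), aln.chars[:, keep], aln.mask[:, keep], aln.locus_id, prior[keep]
    )


def trim_and_mask(aln: AlignmentMatrix, config: Optional[PipelineConfig] = None) -> AlignmentMatrix:
    """The full automated pass: identify reliable sites, mask misaligned
    runs, drop sparse sites."""
    config = config or PipelineConfig()
    masked = mask_misaligned_regions(
        aln, config.mask_run_length, config.reliable_site_threshold
    )
    return drop_sparse_sites(masked, config.min_sequences_per_site)


def _nonempty_rows(aln: AlignmentMatrix) -> int:
    return int(_present(aln).any(axis=1).sum())


def filter_sparse_loci(
    loci: dict, min_fraction: float = 0.5, panel_size: Optional[int] = None
) -> dict:
    """Keep a locus iff its non-empty sequences reach ``min_fraction`` of the
    panel (a locus at exactly the fraction survives: only those *below* it
    are removed)."""
    kept = {}
    for locus_id, aln in loci.items():
        size = panel_size if panel_size is not None else aln.n_taxa
        if size <= 0:
            raise ValueError("panel_size must be positive")
        if _nonempty_rows(aln) / size >= min_fraction:
            kept[locus_id] = aln
        else:
            log.info("locus %s removed: %d/%d sequences", locus_id, _nonempty_rows(aln), size)
    return kept


def _locus_kmers(aln: AlignmentMatrix, k: int) -> frozenset:
    kmers: set = set()
    for i in range(aln.n_taxa):
        seq = aln.sequence(i).replace("-", "")
        kmers |= kmerlib.enumerate_kmers(seq, k, canonical=True).distinct
    return frozenset(kmers)


def _locus_total_length(aln: AlignmentMatrix) -> int:
    return int((aln.chars != _GAP).sum())


def dedup_overlapping_loci(loci: dict, k: int = 20) -> dict:
    """Remove loci until no two share a single (canonical, gap-stripped)
    k-mer.  Of an overlapping pair, the locus with the smaller total
    ungapped length goes; on a tie the lexicographically later id goes."""
    kept = dict(loci)
    kmer_sets = {lid: _locus_kmers(aln, k) for lid, aln in kept.items()}
    while True:
        ids = sorted(kept)
        overlap = None
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if kmer_sets[a] & kmer_sets[b]:
                    overlap = (a, b)
                    break
            if overlap:
                break
        if overlap is None:
            return kept
        a, b = overlap
        la, lb = _locus_total_length(kept[a]), _locus_total_length(kept[b])
        loser = b if (lb < la or (lb == la and b > a)) else a
        log.info("loci %s and %s share %d-mers; removing %s", a, b, k, loser)
        del kept[loser]
        del kmer_sets[loser]


def mask_repetitive_regions(
    aln: AlignmentMatrix,
    read_profile: kmerlib.KmerProfile,
    elevation_factor: float = 5.0,
) -> AlignmentMatrix:
    """Mask cells whose covering-k-mer coverage in the WGS read profile
    exceeds ``elevation_factor`` times that sequence's median track value
    (falling back to the mean when the median is zero; an all-zero track
    masks nothing)."""
    out = aln.copy()
    k = read_profile.k
    for i in range(out.n_taxa):
        row = out.chars[i]
        nongap_cols = np.flatnonzero(row != _GAP)
        seq = row[nongap_cols].tobytes().decode("ascii")
        if len(seq) == 0:
            continue
        track = kmerlib.coverage_track(seq, read_profile)
        baseline = float(np.median(track))
        if baseline == 0.0:
            baseline = float(np.mean(track))
        if baseline == 0.0:
            continue
        elevated = track > elevation_factor * baseline
        out.mask[i, nongap_cols[elevated]] = True
    return out


def concatenate(loci: dict, taxa_order: Sequence[str]):
    """Supermatrix over ``taxa_order`` plus a 1-based inclusive partition
    table (RAxML dialect); taxa missing from a locus are gap-padded."""
    rows = {t: [] for t in taxa_order}
    partitions = []
    cursor = 1
    for locus_id in loci:
        aln = loci[locus_id]
        L = aln.n_sites
        row_of = {t: i for i, t in enumerate(aln.taxa)}
        for t in taxa_order:
            if t in row_of:
                rows[t].append(aln.sequence(row_of[t]))
            else:
                rows[t].append("-" * L)
        partitions.append((locus_id, cursor, cursor + L - 1))
        cursor += L
    records = [SequenceRecord(id=t, residues="".join(rows[t])) for t in taxa_order]
    supermatrix = AlignmentMatrix.from_records(records, locus_id="supermatrix")
    return supermatrix, partitions


def write_partitions(partitions: Sequence[tuple], path) -> None:
    with open(path, "w") as handle:
        for locus_id, start, end in partitions:
            handle.write(f"DNA, {locus_id} = {start}-{end}\n")


def locus_alignment_stats(loci: dict) -> dict:
    """Locus count and alignment-length summary (mean/median/min/max/total)."""
    lengths = np.array([aln.n_sites for aln in loci.values()], dtype=float)
    if lengths.size == 0:
        return {"n_loci": 0, "mean_length": 0.0, "median_length": 0.0,
                "min_length": 0, "max_length": 0, "total_length": 0}
    return {
        "n_loci": int(lengths.size),
        "mean_length": float(lengths.mean()),
        "median_length": float(np.median(lengths)),
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
        "total_length": int(lengths.sum()),
    }


def qc_report(loci: dict, path) -> None:
    """Per-locus masked fraction and size table, for human review in place of
    the manual alignment-viewer inspection step."""
    rows = []
    for locus_id, aln in sorted(loci.items()):
        cells = aln.chars.size or 1
        rows.append(
            (locus_id, aln.n_taxa, aln.n_sites, f"{aln.mask.sum() / cells:.4f}", _nonempty_rows(aln))
        )
    write_tsv(path, ["locus_id", "n_taxa", "n_sites", "masked_fraction", "nonempty_sequences"], rows)


# ---------------------------------------------------------------------------
# Alignment construction


def align_star(records: Sequence[SequenceRecord], config: Optional[PipelineConfig] = None,
               locus_id: str = "") -> AlignmentMatrix:
    """Gapless star alignment: place every sequence against the longest by
    its best anchored offset and pad with terminal gaps.

    Exact for substitution-only divergence (no indels), which is the regime
    of the synthetic panels; real data should go through the external
    aligner adapter instead.
    """
    config = config or PipelineConfig()
    if not records:
        return AlignmentMatrix(taxa=[], chars=np.zeros((0, 0), np.uint8), locus_id=locus_id)
    center = max(records, key=lambda r: (len(r), r.id))
    index = kmerlib.build_anchor_index([center], config.anchor_k)
    placements = []  # (record, offset on center axis)
    for rec in records:
        if rec.id == center.id:
            placements.append((rec, 0))
            continue
        by_ref = kmerlib.candidate_offsets(rec.residues, index, config.anchor_k)
        hit = None
        if 0 in by_ref:
            hit = kmerlib.align_gapless(
                rec.residues, center.residues, by_ref[0],
                seed_window=config.seed_window, seed_min=config.seed_min_matches,
                confirm_window=config.confirm_window, confirm_min=config.confirm_min_matches,
                mode=config.confirm_mode,
            )
        if hit is None or not hit.valid:
            log.warning("sequence %s does not place against %s; left-anchored", rec.id, center.id)
            placements.append((rec, 0))
        else:
            placements.append((rec, hit.offset))
    lo = min(off for _r, off in placements)
    hi = max(off + len(r) for r, off in placements)
    rows = []
    for rec, off in placements:
        left = off - lo
        right = hi - (off + len(rec))
        rows.append(SequenceRecord(id=rec.id, residues="-" * left + rec.residues + "-" * right))
    return AlignmentMatrix.from_records(rows, locus_id=locus_id)


def align_external(
    records: Sequence[SequenceRecord],
    command_template: str = "mafft --auto {infile}",
    locus_id: str = "",
) -> AlignmentMatrix:
    """Run an external multiple aligner (stdout = aligned FASTA).

    ``command_template`` receives ``{infile}``; the default drives mafft.
    """
    from .io_core import read_sequences, write_sequences

    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        write_sequences(records, infile, "fasta")
        cmd = shlex.split(command_template.format(infile=infile))
        with open(outfile, "w") as out:
            subprocess.run(cmd, stdout=out, stderr=subprocess.DEVNULL, check=True)
        aligned = read_sequences(outfile, "fasta")
    return AlignmentMatrix.from_records(aligned, locus_id=locus_id)
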