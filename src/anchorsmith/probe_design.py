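"""Uniform in-silico probe tiling at a requested coverage depth.

Probes of fixed length (default 120 bp) are laid at a regular step of
round(probe_length / density) along each gap-stripped source sequence, with
the final probe right-anchored so coverage has no terminal gap.  Tiling a
locus applies this to every (up to 10) sequence in the final alignment and
drops probes touching masked or N positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_core import PipelineConfig, SequenceRecord, get_logger, write_tsv
from .alignment_qc import AlignmentMatrix, _GAP

log = get_logger("anchorsmith.probes")


@dataclass
class Probe:
    source_id: str
    start: int  # 0-based half-open on the gap-stripped source
    end: int
    sequence: str


@dataclass
class ProbeSet:
    probes: list
    requested_density: float
    achieved_density: dict = field(default_factory=dict)  # source_id -> float

    def __len__(self) -> int:
        return len(self.probes)

    def extend(self, other: "ProbeSet") -> None:
        self.probes.extend(other.probes)
        self.achieved_density.update(other.achieved_density)

    def to_records(self) -> list:
        return [
            SequenceRecord(id=f"{p.source_id}|{p.start}-{p.end}", residues=p.sequence)
            for p in self.probes
        ]

    def to_tsv(self, path) -> None:
        rows = [(p.source_id, p.start, p.end) for p in self.probes]
        write_tsv(path, ["source_id", "start", "end"], rows)


def probe_starts(length: int, probe_length: int = 120, density: float = 3.5) -> list:
    """Start coordinates of the uniform tiling: 0, step, 2*step, ... plus a
    right-anchored terminal probe at length - probe_length."""
    step = round(probe_length / density)
    if step < 1:
        step = 1
    starts = list(range(0, length - probe_length + 1, step))
    last = length - probe_length
    if starts and starts[-1] != last:
        starts.append(last)
    return starts


def tile_probes(
    source: SequenceRecord, probe_length: int = 120, density: float = 3.5
) -> ProbeSet:
    """Tile one sequence; gaps are stripped before tiling.

    A source shorter than the probe length yields a single probe spanning
    the whole source (warned).
    """
    residues = source.residues.replace("-", "")
    L = len(residues)
    if L == 0:
        return ProbeSet([], density, {source.id: 0.0})
    if L < probe_length:
        log.warning("source %s (%d bp) shorter than probe length %d", source.id, L, probe_length)
        probes = [Probe(source.id, 0, L, residues)]
    else:
        probes = [
            Probe(source.id, s, s + probe_length, residues[s : s + probe_length])
            for s in probe_starts(L, probe_length, density)
        ]
    achieved = sum(p.end - p.start for p in probes) / L
    return ProbeSet(probes, density, {source.id: achieved})


def tile_locus(aln: AlignmentMatrix, config: Optional[PipelineConfig] = None) -> ProbeSet:
    """Tile every sequence of a locus alignment; probes containing any
    masked or N position are dropped and logged."""
    config = config or PipelineConfig()
    out = ProbeSet([], config.tiling_density)
    for i, taxon in enumerate(aln.taxa):
        row = aln.chars[i]
        nongap = row != _GAP
        seq = row[nongap].tobytes().decode("ascii")
        bad = (aln.mask[i] | (row == ord("N")))[nongap]  # per gap-stripped position
        rec = SequenceRecord(id=f"{aln.locus_id}|{taxon}" if aln.locus_id else taxon, residues=seq)
        if len(seq) == 0:
            continue
        tiled = tile_probes(rec, config.probe_length, config.tiling_density)
        kept = [p for p in tiled.probes if not bad[p.start : p.end].any()]
        dropped = len(tiled.probes) - len(kept)
        if dropped:
            log.info("%s: dropped %d probes over masked/N positions", rec.id, dropped)
        usable = int((~bad).sum())
        achieved = sum(p.end - p.start for p in kept) / usable if usable else 0.0
        out.probes.extend(kept)
        out.achieved_density[rec.id] = achieved
    return out


def probe_coverage(probes: Sequence[Probe], source_length: int) -> np.ndarray:
    """Per-position covering-probe count on one source."""
    cov = np.zeros(source_length, dtype=int)
    for p in probes:
        cov[p.start : p.end] += 1
    return cov
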