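"""Sequence records, file formats, and run configuration.

Everything downstream of this module exchanges :class:`SequenceRecord`
objects and a :class:`PipelineConfig`.  All genomic intervals are 0-based
half-open internally; only human-readable log lines use 1-based coordinates.
Residue case is normalised to uppercase on ingestion -- masking is carried in
an explicit mask layer, never in letter case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord


class FormatError(ValueError):
    """A file did not parse under the named standard."""


class ConfigError(ValueError):
    """A configuration file or value is invalid."""


def get_logger(name: str = "anchorsmith") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.WARNING)
    return logger


log = get_logger()

# IUPAC degenerate codes and complements cover every symbol we emit.
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

IUPAC_FROM_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
    frozenset(): "N",
}
SET_FROM_IUPAC = {code: bases for bases, code in IUPAC_FROM_SET.items() if bases}
SET_FROM_IUPAC["N"] = frozenset("ACGT")

DNA_BASES = "ACGT"


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One named nucleotide sequence, optionally with Phred qualities."""

    id: str
    residues: str
    qualities: Optional[list[int]] = None
    sample: Optional[str] = None
    locus: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.residues = self.residues.upper()
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise FormatError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, id_suffix: str = "") -> "SequenceRecord":
        quals = None if self.qualities is None else list(reversed(self.qualities))
        return SequenceRecord(
            id=self.id + id_suffix,
            residues=reverse_complement(self.residues),
            qualities=quals,
            sample=self.sample,
            locus=self.locus,
        )


_FASTA_SUFFIXES = {".fa", ".fasta", ".fas", ".fna", ".ffn"}
_FASTQ_SUFFIXES = {".fq", ".fastq"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gz":
        suffix = Path(path.stem).suffix.lower()
    if suffix in _FASTA_SUFFIXES:
        return "fasta"
    if suffix in _FASTQ_SUFFIXES:
        return "fastq"
    raise FormatError(f"cannot infer sequence format from {path.name!r}")


def read_sequences(path, fmt: Optional[str] = None) -> list[SequenceRecord]:
    """Read FASTA or FASTQ into records; residues uppercased, order preserved."""
    path = Path(path)
    if fmt is None:
        fmt = _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise FormatError(f"unsupported format {fmt!r}")
    records = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            quals = None
            if fmt == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), qualities=quals))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path, fmt: Optional[str] = None) -> None:
    """Write FASTA (wrapped at 60 columns) or FASTQ (Phred+33)."""
    path = Path(path)
    if fmt is None:
        fmt = _infer_format(path)
    bio = []
    for rec in records:
        brec = _BioRecord(Seq(rec.residues), id=rec.id, description="")
        if fmt == "fastq":
            if rec.qualities is None:
                raise FormatError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            brec.letter_annotations["phred_quality"] = rec.qualities
        bio.append(brec)
    with open(path, "w") as handle:
        SeqIO.write(bio, handle, fmt)


def write_targets_bed(targets: Sequence, path) -> None:
    """Write locus targets as BED6 (0-based half-open), name = locus id."""
    with open(path, "w") as handle:
        for t in targets:
            if t.end <= t.start:
                raise ValueError(f"target {t.locus_id}: end {t.end} <= start {t.start}")
            score = len(getattr(t, "hit_positions", []) or [])
            handle.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.locus_id}\t{score}\t{t.strand}\n")


@dataclass
class BedInterval:
    contig: str
    start: int
    end: int
    name: str
    score: int
    strand: str


def read_targets_bed(path) -> list[BedInterval]:
    out = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: expected BED6, got {len(parts)} columns")
            out.append(
                BedInterval(parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]), parts[5])
            )
    return out


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults reproduce the published protocol: a 17-of-20 initial spaced
    k-mer match confirmed by 55-of-100 identities, 10 kb candidate windows,
    consensus clusters gated at average depth > 250 under a 1% error model,
    a 50% reliable-site threshold, a 14-base misalignment mask run, 25
    sequences required per site, 50% minimum locus occupancy, and 120 bp
    probes tiled at 3.5x depth with a 98% barcode-identity assignment rule.
    """

    seed_window: int = 20
    seed_min_matches: int = 17
    confirm_window: int = 100
    confirm_min_matches: int = 55
    target_window: int = 10000
    kmer_k: int = 20
    min_avg_depth: float = 250.0
    error_rate: float = 0.01
    reliable_site_threshold: float = 0.5
    mask_run_length: int = 14
    min_sequences_per_site: int = 25
    min_locus_fraction: float = 0.5
    tiling_density: float = 3.5
    probe_length: int = 120
    identity_assign_threshold: float = 0.98
    rng_seed: int = 0
    # secondary knobs (not printed in the protocol; see docs/methods.md)
    alpha: float = 0.05
    error_partition_three: bool = False
    anchor_k: int = 14
    confirm_mode: str = "aligned"
    cluster_linkage: str = "average"
    cluster_cutoff: float = 0.999
    repeat_elevation_factor: float = 5.0
    merge_min_overlap: int = 12
    merge_max_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "seed_window seed_min_matches confirm_window confirm_min_matches "
            "target_window kmer_k min_avg_depth error_rate reliable_site_threshold "
            "mask_run_length min_sequences_per_site min_locus_fraction tiling_density "
            "probe_length identity_assign_threshold alpha anchor_k cluster_cutoff "
            "repeat_elevation_factor merge_min_overlap merge_max_mismatch_rate"
        ).split()
        for name in positive:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{name} must be numeric, got {value!r}")
            if not value > 0:
                raise ConfigError(f"{name} must be positive, got {value!r}")
        if self.seed_min_matches > self.seed_window:
            raise ConfigError("seed_min_matches must be <= seed_window")
        if self.confirm_min_matches > self.confirm_window:
            raise ConfigError("confirm_min_matches must be <= confirm_window")
        if self.confirm_mode not in ("aligned", "consecutive"):
            raise ConfigError(f"confirm_mode must be aligned|consecutive, got {self.confirm_mode!r}")
        if self.cluster_linkage not in ("single", "average"):
            raise ConfigError(f"cluster_linkage must be single|average, got {self.cluster_linkage!r}")

    def resolved(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **overrides) -> "PipelineConfig":
        values = self.resolved()
        values.update(overrides)
        return PipelineConfig(**values)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a flat key:value config file; unspecified keys take the defaults."""
    values: dict = {}
    if path is not None:
        with open(path) as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a flat key:value mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        config = PipelineConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    log.info("resolved config: %s", config.resolved())
    return config


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")
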