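"""Seedable simulator of genomes, transcripts, anchor loci, repeats, and
sequencing reads, with full truth tables.

The generator emulates the data regime of an anchored-enrichment design
study across divergent congeners: each locus is a conserved core (mutated
at half the panel divergence) with variable flanks (full divergence),
embedded in random genomic background; two designated taxa contribute
transcripts (the core regions); repeat families of known copy number are
planted in the background; paired 150 bp reads are drawn at a requested
coverage with a uniform per-base error rate, 8 bp sample indexes, adapter
read-through for short fragments, and optional 50/50 heterozygous sites.

The mutation model is substitution-only by default so that truth
alignments are positional and every downstream oracle is exact; an indel
mode is available for robustness checks but void the positional truth.
Every stochastic choice flows from one numpy Generator seeded per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_core import SequenceRecord, get_logger, reverse_complement

log = get_logger("anchorsmith.synthetic")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(rng: np.random.Generator, residues: str, rate: float) -> str:
    """Substitute each base independently at ``rate`` (always to a different
    base)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        current = arr[i]
        choices = BASES[BASES != current]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


@dataclass
class PlantedLocus:
    locus_id: str
    taxon: str
    contig: str
    start: int  # full insert (flank+core+flank), 0-based half-open, forward coords
    end: int
    strand: str
    core_start: int  # core span within the contig, forward coords
    core_end: int
    divergence_core: float
    divergence_flank: float
    truth_sequence: str  # planted insert in reference orientation


@dataclass
class RepeatTruth:
    family: str
    taxon: str
    contig: str
    positions: list  # start coordinates of planted copies
    unit_length: int


@dataclass
class ReadTruth:
    fragment_id: str
    sample: str
    contig: str
    start: int
    end: int
    locus_id: Optional[str]  # planted locus the fragment overlaps, else None


@dataclass
class SimulationTruth:
    loci: list = field(default_factory=list)  # PlantedLocus
    ortholog_map: dict = field(default_factory=dict)  # locus_id -> {taxon: insert id}
    repeats: list = field(default_factory=list)  # RepeatTruth
    reads: dict = field(default_factory=dict)  # fragment_id -> ReadTruth
    het_sites: list = field(default_factory=list)  # (contig, pos, ref, alt)

    def loci_for_taxon(self, taxon: str) -> list:
        return [p for p in self.loci if p.taxon == taxon]


@dataclass
class Panel:
    genomes: dict  # taxon -> list[SequenceRecord]
    transcripts: dict  # taxon -> list[SequenceRecord] (the two designated taxa)
    truth: SimulationTruth
    taxa: list


def simulate_panel(
    n_taxa: int = 10,
    n_loci: int = 20,
    locus_length: int = 400,
    flank_length: int = 250,
    within_divergence: float = 0.10,
    background_length: int = 10000,
    n_repeat_families: int = 2,
    repeat_copies: int = 10,
    repeat_unit_length: int = 300,
    margin: int = 300,
    seed: int = 0,
) -> Panel:
    """Simulate a taxon panel sharing conserved anchor loci.

    Each locus has a root sequence (flank + core + flank); per-taxon copies
    are mutated at ``within_divergence`` in the flanks and half that rate in
    the conserved core, then embedded (random strand) in random background
    margins, one contig per locus.  Each taxon also carries one background
    contig holding the planted repeat families.  Transcripts are the core
    regions of the first two taxa.  Fully determined by ``seed``.
    """
    if not 0 <= within_divergence <= 0.3:
        raise ValueError("within_divergence must be in [0, 0.3]")
    for name, value in [("n_taxa", n_taxa), ("n_loci", n_loci), ("locus_length", locus_length),
                        ("flank_length", flank_length), ("background_length", background_length)]:
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    truth = SimulationTruth()

    roots = {}
    for j in range(n_loci):
        locus_id = f"locus{j:03d}"
        flank_l = random_dna(rng, flank_length)
        core = random_dna(rng, locus_length)
        flank_r = random_dna(rng, flank_length)
        roots[locus_id] = (flank_l, core, flank_r)
        truth.ortholog_map[locus_id] = {}

    repeat_units = [random_dna(rng, repeat_unit_length) for _ in range(n_repeat_families)]

    genomes = {}
    transcripts = {}
    for t_idx, taxon in enumerate(taxa):
        contigs = []
        taxon_transcripts = []
        for j, (locus_id, (flank_l, core, flank_r)) in enumerate(sorted(roots.items())):
            mut_flank_l = mutate(rng, flank_l, within_divergence)
            mut_core = mutate(rng, core, within_divergence / 2)
            mut_flank_r = mutate(rng, flank_r, within_divergence)
            insert = mut_flank_l + mut_core + mut_flank_r
            strand = "+" if rng.random() < 0.5 else "-"
            left = random_dna(rng, margin)
            right = random_dna(rng, margin)
            embedded = insert if strand == "+" else reverse_complement(insert)
            contig_id = f"{taxon}_c{j:03d}"
            contigs.append(SequenceRecord(id=contig_id, residues=left + embedded + right, sample=taxon))
            start, end = margin, margin + len(insert)
            if strand == "+":
                core_start = start + len(mut_flank_l)
                core_end = core_start + len(mut_core)
            else:
                core_start = start + len(mut_flank_r)
                core_end = core_start + len(mut_core)
            truth.loci.append(
                PlantedLocus(
                    locus_id=locus_id, taxon=taxon, contig=contig_id,
                    start=start, end=end, strand=strand,
                    core_start=core_start, core_end=core_end,
                    divergence_core=within_divergence / 2,
                    divergence_flank=within_divergence,
                    truth_sequence=insert,
                )
            )
            truth.ortholog_map[locus_id][taxon] = f"{taxon}::{locus_id}"
            if t_idx < 2:
                taxon_transcripts.append(
                    SequenceRecord(id=f"tx_{taxon}_{locus_id}", residues=mut_core,
                                   sample=taxon, locus=locus_id)
                )
        # background contig with planted repeats
        bg = list(random_dna(rng, background_length))
        bg_id = f"{taxon}_bg"
        n_slots = background_length // repeat_unit_length
        copies = min(repeat_copies, n_slots // max(1, n_repeat_families))
        if n_repeat_families and copies < repeat_copies:
            log.warning("background too short for %d copies/family; planting %d", repeat_copies, copies)
        all_slots = rng.choice(n_slots, size=copies * n_repeat_families, replace=False) if n_repeat_families else []
        for f_idx, unit in enumerate(repeat_units):
            positions = []
            for slot in sorted(all_slots[f_idx * copies : (f_idx + 1) * copies]):
                pos = int(slot) * repeat_unit_length
                copy = mutate(rng, unit, 0.01)  # near-identical repeat copies
                bg[pos : pos + repeat_unit_length] = list(copy)
                positions.append(pos)
            truth.repeats.append(RepeatTruth(f"rep{f_idx}", taxon, bg_id, positions, repeat_unit_length))
        contigs.append(SequenceRecord(id=bg_id, residues="".join(bg), sample=taxon))
        genomes[taxon] = contigs
        if t_idx < 2:
            transcripts[taxon] = taxon_transcripts
    return Panel(genomes=genomes, transcripts=transcripts, truth=truth, taxa=taxa)


def _apply_errors(rng: np.random.Generator, residues: str, error_rate: float) -> str:
    if error_rate <= 0:
        return residues
    return mutate(rng, residues, error_rate)


def simulate_reads(
    genome: Sequence[SequenceRecord],
    coverage: float = 30.0,
    read_length: int = 150,
    fragment_mean: float = 350.0,
    fragment_sd: float = 50.0,
    error_rate: float = 0.01,
    adapter: str = DEFAULT_ADAPTER,
    het_sites: Optional[Sequence[tuple]] = None,
    sample: str = "S0",
    index: str = "ACGTACGT",
    seed: int = 0,
    truth_loci: Optional[Sequence[PlantedLocus]] = None,
) -> tuple:
    """Draw paired-end reads over a genome; returns (pairs, truth).

    ``pairs`` is a list of (r1, r2) records in sequencing orientation with
    Phred qualities; ``truth`` is {fragment_id: ReadTruth}.  Fragments
    shorter than the read length produce adapter read-through.  Het sites
    are (contig, position, alt_base) tuples; each overlapping fragment
    carries the reference or alternate allele with probability 1/2.
    Coverage counts sequenced genome bases (adapter excluded) per genome
    base.  Fully determined by ``seed``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    contigs = [(c.id, c.residues) for c in genome]
    lengths = np.array([len(s) for _i, s in contigs], dtype=float)
    total = lengths.sum()
    weights = lengths / total
    target_bases = total * coverage
    het_by_contig: dict = {}
    for site in het_sites or []:
        contig_id, pos, alt = site
        het_by_contig.setdefault(contig_id, []).append((pos, alt))
    locus_spans = [(p.contig, p.start, p.end, p.locus_id) for p in (truth_loci or [])]

    pairs = []
    truth: dict = {}
    covered = 0.0
    serial = 0
    while covered < target_bases:
        cidx = rng.choice(len(contigs), p=weights)
        contig_id, seq = contigs[cidx]
        frag_len = int(np.clip(rng.normal(fragment_mean, fragment_sd), 40, None))
        frag_len = min(frag_len, len(seq))
        start = int(rng.integers(0, len(seq) - frag_len + 1))
        frag = seq[start : start + frag_len]
        for pos, alt in het_by_contig.get(contig_id, []):
            if start <= pos < start + frag_len and rng.random() < 0.5:
                frag = frag[: pos - start] + alt + frag[pos - start + 1 :]
        fragment_id = f"{sample}:{serial}"
        serial += 1
        r1_src = frag + adapter
        r2_src = reverse_complement(frag) + adapter
        r1_seq = _apply_errors(rng, r1_src[:read_length], error_rate)
        r2_seq = _apply_errors(rng, r2_src[:read_length], error_rate)
        quals1 = [int(q) for q in rng.integers(33, 41, size=len(r1_seq))]
        quals2 = [int(q) for q in rng.integers(33, 41, size=len(r2_seq))]
        r1 = SequenceRecord(id=f"{fragment_id}:{index}/1", residues=r1_seq, qualities=quals1, sample=sample)
        r2 = SequenceRecord(id=f"{fragment_id}:{index}/2", residues=r2_seq, qualities=quals2, sample=sample)
        pairs.append((r1, r2))
        locus_id = None
        for l_contig, l_start, l_end, lid in locus_spans:
            if l_contig == contig_id and start < l_end and start + frag_len > l_start:
                locus_id = lid
                break
        truth[fragment_id] = ReadTruth(fragment_id, sample, contig_id, start, start + frag_len, locus_id)
        covered += min(frag_len, 2 * read_length) if frag_len > read_length else frag_len
    return pairs, truth


def simulate_barcode_panel(
    n_species: int = 5,
    n_queries_per_species: int = 2,
    length: int = 600,
    between_divergence: float = 0.12,
    within_divergence: float = 0.01,
    seed: int = 0,
) -> tuple:
    """References and queries exhibiting a barcode gap.

    Species roots each diverge ``between_divergence`` from a common
    ancestor (pairwise identity well under the gap ceiling); queries and
    references within a species differ by ``within_divergence``.  Returns
    (references, queries, truth_label) with species labels in ``.sample``.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_dna(rng, length)
    references = []
    queries = []
    truth_label = {}
    for s in range(n_species):
        label = f"species{s:02d}"
        root = mutate(rng, ancestor, between_divergence)
        references.append(SequenceRecord(id=f"ref_{label}", residues=root, sample=label))
        for q in range(n_queries_per_species):
            qid = f"query_{label}_{q}"
            queries.append(SequenceRecord(id=qid, residues=mutate(rng, root, within_divergence)))
            truth_label[qid] = label
    return references, queries, truth_label
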