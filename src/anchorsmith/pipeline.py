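"""End-to-end orchestration of the locus-design and read-processing stages.

Composes the module-level operations into the study workflow: transcript
pairing -> genome scan -> window extraction (design phase), then per-sample
merge -> recruit -> extension assembly -> consensus (capture phase), then
orthology clustering, alignment QC, dedup, and probe tiling.  Each stage is
also exposed individually on the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_core import PipelineConfig, SequenceRecord, get_logger
from . import alignment_qc, orthology, probe_design, read_assembly, target_discovery

log = get_logger("anchorsmith.pipeline")


@dataclass
class DiscoveryResult:
    pairs: list  # ReciprocalPair
    references: list  # anchor reference sequences used for the scan
    targets: list  # LocusTarget
    windows: list  # extracted window sequences


def discover_targets(
    genome: Sequence[SequenceRecord],
    transcripts_a: Sequence[SequenceRecord],
    transcripts_b: Sequence[SequenceRecord],
    config: Optional[PipelineConfig] = None,
) -> DiscoveryResult:
    """Design phase: reciprocal transcript pairing seeds a genome scan.

    The references handed to the scanner are the set-A members of each
    reciprocal pair (the transcriptome matched against its own genome).
    """
    config = config or PipelineConfig()
    pairs = target_discovery.reciprocal_best_pairs(transcripts_a, transcripts_b, config)
    by_id = {rec.id: rec for rec in transcripts_a}
    references = [by_id[p.id_a] for p in pairs]
    targets = target_discovery.scan_genome(genome, references, config)
    windows = target_discovery.extract_windows(genome, targets)
    return DiscoveryResult(pairs=pairs, references=references, targets=targets, windows=windows)


def capture_references(
    targets: Sequence, reference_pool: Sequence[SequenceRecord]
) -> list:
    """Per-locus recruitment references: the transcript that seeded each
    validated target, relabelled with the discovered locus id."""
    by_id = {rec.id: rec for rec in reference_pool}
    refs = []
    for t in targets:
        src = by_id[t.seed_reference]
        refs.append(
            SequenceRecord(id=f"{t.locus_id}|{src.id}", residues=src.residues, locus=t.locus_id)
        )
    return refs


@dataclass
class SampleCapture:
    sample: str
    clusters: dict  # locus -> AssemblyCluster
    consensi: dict  # locus -> ConsensusSequence
    multi_locus: set
    n_merged: int
    n_reads: int


def capture_sample(
    pairs: Sequence[tuple],
    references: Sequence[SequenceRecord],
    sample: str,
    config: Optional[PipelineConfig] = None,
) -> SampleCapture:
    """Capture phase for one sample: merge pairs, recruit, extend, call."""
    config = config or PipelineConfig()
    reads = read_assembly.merge_read_pool(
        pairs, config.merge_min_overlap, config.merge_max_mismatch_rate
    )
    n_merged = sum(1 for r in reads if r.id.endswith(":merged"))
    recruited = read_assembly.recruit_reads(reads, references, config)
    clusters = read_assembly.make_clusters(recruited, sample)
    read_assembly.extend_all(clusters, recruited.unassigned, config)
    consensi = {}
    for locus, cluster in sorted(clusters.items()):
        cons = read_assembly.call_consensus(cluster, config)
        if cons is not None:
            consensi[locus] = cons
    return SampleCapture(
        sample=sample,
        clusters=clusters,
        consensi=consensi,
        multi_locus=recruited.multi_locus,
        n_merged=n_merged,
        n_reads=len(reads),
    )


@dataclass
class OrthologyResult:
    groups: list
    matrix: orthology.DistanceMatrix
    member_identity: dict  # anonymised member id -> (sample, capture locus)


def cluster_consensi(
    captures: Sequence[SampleCapture],
    references: Sequence[SequenceRecord],
    config: Optional[PipelineConfig] = None,
) -> OrthologyResult:
    """Orthology phase over all consensi plus the anchor references.

    Consensus ids are anonymised (sample + serial) before clustering so
    group recovery depends only on 20-mer overlap, never on capture labels.
    """
    config = config or PipelineConfig()
    records = []
    identity = {}
    for cap in captures:
        for n, (locus, cons) in enumerate(sorted(cap.consensi.items())):
            anon = f"{cap.sample}::c{n:03d}"
            identity[anon] = (cap.sample, locus)
            records.append(SequenceRecord(id=anon, residues=cons.residues, sample=cap.sample))
    ref_ids = set()
    locus_of_ref = {}
    for ref in references:
        records.append(ref)
        ref_ids.add(ref.id)
        locus_of_ref[ref.id] = ref.locus or ref.id
    matrix = orthology.build_distance_matrix(records, k=config.kmer_k)
    groups = orthology.cluster_orthologs(
        matrix,
        linkage=config.cluster_linkage,
        cutoff=config.cluster_cutoff,
        reference_ids=ref_ids,
        locus_of_reference=locus_of_ref,
    )
    return OrthologyResult(groups=groups, matrix=matrix, member_identity=identity)


def build_locus_alignments(
    result: OrthologyResult,
    captures: Sequence[SampleCapture],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Align each ortholog group's member consensi (gapless star alignment)."""
    config = config or PipelineConfig()
    by_anon = {}
    for cap in captures:
        for n, (locus, cons) in enumerate(sorted(cap.consensi.items())):
            by_anon[f"{cap.sample}::c{n:03d}"] = cons
    alignments = {}
    for group in result.groups:
        members = []
        for sample in sorted(group.members):
            cons = by_anon[group.members[sample]]
            members.append(SequenceRecord(id=sample, residues=cons.residues, sample=sample))
        if len(members) < 2:
            continue
        alignments[group.locus_id] = alignment_qc.align_star(members, config, locus_id=group.locus_id)
    return alignments


def qc_locus_alignments(
    alignments: dict,
    config: Optional[PipelineConfig] = None,
    panel_size: Optional[int] = None,
    read_profile=None,
) -> dict:
    """Trim/mask, optional repeat masking, occupancy filter, and dedup."""
    config = config or PipelineConfig()
    out = {}
    for locus_id, aln in alignments.items():
        if read_profile is not None:
            aln = alignment_qc.mask_repetitive_regions(aln, read_profile, config.repeat_elevation_factor)
        out[locus_id] = alignment_qc.trim_and_mask(aln, config)
    out = alignment_qc.filter_sparse_loci(out, config.min_locus_fraction, panel_size)
    out = alignment_qc.dedup_overlapping_loci(out, k=config.kmer_k)
    return out


def tile_panel(alignments: dict, config: Optional[PipelineConfig] = None) -> probe_design.ProbeSet:
    config = config or PipelineConfig()
    out = probe_design.ProbeSet([], config.tiling_density)
    for locus_id in sorted(alignments):
        out.extend(probe_design.tile_locus(alignments[locus_id], config))
    return out


# ---------------------------------------------------------------------------
# Whole-study run on a simulated panel, with truth-aware evaluation


def pair_f1(predicted: Sequence[set], truth: Sequence[set]) -> float:
    """Pairwise F1 between two partitions of (a superset of) one item set."""
    def pairs(groups):
        out = set()
        for g in groups:
            members = sorted(g)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    out.add((a, b))
        return out

    p, t = pairs(predicted), pairs(truth)
    if not p and not t:
        return 1.0
    if not p or not t:
        return 0.0
    tp = len(p & t)
    precision = tp / len(p)
    recall = tp / len(t)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class StudyResult:
    discovery: DiscoveryResult
    captures: list
    ortho: OrthologyResult
    alignments: dict  # post-QC locus alignments
    probes: probe_design.ProbeSet
    supermatrix: object
    partitions: list
    metrics: dict


def run_panel_study(
    panel,
    config: Optional[PipelineConfig] = None,
    coverage: float = 30.0,
    n_decoys: int = 100,
    decoy_length: int = 2000,
    seed: int = 0,
) -> StudyResult:
    """Run the whole pipeline on a simulated panel and score it against truth.

    Discovery scans the first taxon's genome (plus random decoy contigs)
    with references from reciprocal pairing of the two transcript sets;
    every taxon's reads are then simulated, pooled, demultiplexed, and
    captured; consensi are clustered into ortholog groups, aligned, QC'd,
    and tiled.  Metrics cover planted-locus recovery, consensus identity,
    decoy false positives, ortholog-recovery F1, and tiling density.
    """
    import numpy as np

    from .barcode import percent_identity
    from .synthetic_data import random_dna, simulate_reads

    config = config or PipelineConfig()
    rng = np.random.default_rng(seed + 7919)
    taxon_a, taxon_b = panel.taxa[0], panel.taxa[1]
    decoys = [
        SequenceRecord(id=f"decoy{i:03d}", residues=random_dna(rng, decoy_length))
        for i in range(n_decoys)
    ]
    disc = discover_targets(
        panel.genomes[taxon_a] + decoys,
        panel.transcripts[taxon_a],
        panel.transcripts[taxon_b],
        config,
    )
    decoy_ids = {d.id for d in decoys}
    false_targets = [t for t in disc.targets if t.contig in decoy_ids]
    truth_a = {p.contig: p for p in panel.truth.loci_for_taxon(taxon_a)}
    recovered_windows = sum(
        1
        for t in disc.targets
        if t.contig in truth_a
        and t.start <= truth_a[t.contig].core_start
        and t.end >= truth_a[t.contig].core_end
    )
    refs = capture_references(disc.targets, panel.transcripts[taxon_a] + panel.transcripts[taxon_b])
    # capture locus id -> planted locus id, via the seeding transcript
    tx_locus = {rec.id: rec.locus for t in (taxon_a, taxon_b) for rec in panel.transcripts[t]}
    planted_of = {t.locus_id: tx_locus[t.seed_reference] for t in disc.targets}

    # pooled sequencing run: per-sample indexes, then demultiplexing
    index_map = {}
    pooled = []
    for i, taxon in enumerate(panel.taxa):
        index = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, size=8))
        while index in index_map:
            index = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, size=8))
        index_map[index] = taxon
        pairs, _read_truth = simulate_reads(
            panel.genomes[taxon],
            coverage=coverage,
            sample=taxon,
            index=index,
            seed=seed + 1 + i,
            truth_loci=panel.truth.loci_for_taxon(taxon),
        )
        pooled.extend(pairs)
    flat = [r for pair in pooled for r in pair]
    bins = read_assembly.demultiplex(flat, index_map)
    captures = []
    for taxon in panel.taxa:
        by_fragment: dict = {}
        for r in bins[taxon]:
            by_fragment.setdefault(r.id.rsplit("/", 1)[0], []).append(r)
        pairs = [tuple(v) for v in by_fragment.values() if len(v) == 2]
        captures.append(capture_sample(pairs, refs, taxon, config))

    # consensus evaluation against planted truth
    truth_seq = {(p.taxon, p.locus_id): p.truth_sequence for p in panel.truth.loci}
    per_unit = []
    for cap in captures:
        for locus, cons in cap.consensi.items():
            planted = planted_of[locus]
            ident = percent_identity(
                SequenceRecord(id="c", residues=cons.residues),
                SequenceRecord(id="t", residues=truth_seq[(cap.sample, planted)]),
                degenerate=True,
            )
            per_unit.append(ident)
    n_planted_units = len(set(planted_of.values())) * len(panel.taxa)
    recovered_units = sum(1 for ident in per_unit if ident >= 99.0)

    ortho = cluster_consensi(captures, refs, config)
    predicted = [set(g.members.values()) for g in ortho.groups]
    truth_groups: dict = {}
    for anon, (sample, locus) in ortho.member_identity.items():
        truth_groups.setdefault(planted_of[locus], set()).add(anon)
    f1 = pair_f1(predicted, list(truth_groups.values()))

    alignments = build_locus_alignments(ortho, captures, config)
    qcd = qc_locus_alignments(alignments, config, panel_size=len(panel.taxa))
    probes = tile_panel(qcd, config)
    supermatrix, partitions = alignment_qc.concatenate(qcd, list(panel.taxa))
    stats = alignment_qc.locus_alignment_stats(qcd)

    densities = list(probes.achieved_density.values())
    metrics = {
        "n_reciprocal_pairs": len(disc.pairs),
        "n_targets": len(disc.targets),
        "window_recovery_pct": 100.0 * recovered_windows / max(len(truth_a), 1),
        "decoy_false_loci": len(false_targets),
        "n_consensi": len(per_unit),
        "consensus_identity_mean_pct": float(np.mean(per_unit)) if per_unit else 0.0,
        "unit_recovery_pct": 100.0 * recovered_units / max(n_planted_units, 1),
        "ortholog_f1": f1,
        "locus_stats": stats,
        "probe_count": len(probes),
        "probe_density_mean": float(np.mean(densities)) if densities else 0.0,
        "supermatrix_sites": supermatrix.n_sites,
    }
    return StudyResult(
        discovery=disc,
        captures=captures,
        ortho=ortho,
        alignments=qcd,
        probes=probes,
        supermatrix=supermatrix,
        partitions=partitions,
        metrics=metrics,
    )
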