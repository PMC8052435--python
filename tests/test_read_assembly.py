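"""Demultiplexing, pair merging, recruitment, extension, consensus calling."""

import math

import numpy as np
import pytest

from anchorsmith.io_core import ConfigError, PipelineConfig, SequenceRecord, reverse_complement
from anchorsmith import read_assembly as RA
from anchorsmith.synthetic_data import mutate, random_dna, simulate_reads


def _read(id, residues, quals=None):
    return SequenceRecord(id=id, residues=residues, qualities=quals)


# ---------------------------------------------------------------------------
# demultiplex


def test_demultiplex_exact_only():
    index_map = {"AAAAAAAA": "s1", "CCCCCCCC": "s2"}
    reads = [
        _read("r1:AAAAAAAA/1", "ACGT"),
        _read("r2:AAAAAAAC/1", "ACGT"),  # one mismatch -> undetermined
        _read("r3:CCCCCCCC/2", "ACGT"),
        _read("r4:GGGGGGGG/1", "ACGT"),
    ]
    bins = RA.demultiplex(reads, index_map)
    assert [r.id for r in bins["s1"]] == ["r1:AAAAAAAA/1"]
    assert [r.id for r in bins["s2"]] == ["r3:CCCCCCCC/2"]
    assert {r.id for r in bins[RA.UNDETERMINED]} == {"r2:AAAAAAAC/1", "r4:GGGGGGGG/1"}


def test_demultiplex_recovers_simulated_counts(rng):
    genome = [SequenceRecord(id="g", residues=random_dna(rng, 5000))]
    index_map = {}
    expected = {}
    reads = []
    for i, sample in enumerate(["sA", "sB", "sC"]):
        index = "ACGT"[i] * 8
        index_map[index] = sample
        pairs, _ = simulate_reads(genome, coverage=2, sample=sample, index=index, seed=50 + i)
        expected[sample] = 2 * len(pairs)
        reads.extend(r for p in pairs for r in p)
    rng.shuffle(reads)
    bins = RA.demultiplex(reads, index_map)
    assert {s: len(bins[s]) for s in expected} == expected
    assert bins[RA.UNDETERMINED] == []


def test_duplicate_index_refused(tmp_path):
    path = tmp_path / "indexes.tsv"
    path.write_text("s1\tAAAAAAAA\ns2\tAAAAAAAA\n")
    with pytest.raises(ConfigError):
        RA.load_index_map(path)


# ---------------------------------------------------------------------------
# merge_pairs


def _pair_from_fragment(fragment, read_len, adapter="AGATCGGAAGAGC" * 12):
    r1 = (fragment + adapter)[:read_len]
    r2 = (reverse_complement(fragment) + adapter)[:read_len]
    q = [35] * read_len
    return _read("f/1", r1, list(q)), _read("f/2", r2, list(q))


def test_merge_overlapping_pair_geometry(rng):
    fragment = random_dna(rng, 100)
    r1, r2 = _pair_from_fragment(fragment, 70)
    merged = RA.merge_pairs(r1, r2)
    assert merged is not None
    assert merged.residues == fragment
    assert len(merged.qualities) == 100


def test_merge_removes_adapter_readthrough(rng):
    """Fragment shorter than the read length: merged read = fragment, no
    adapter bases survive."""
    adapter = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA" * 4
    fragment = random_dna(rng, 80)
    r1, r2 = _pair_from_fragment(fragment, 100, adapter)
    merged = RA.merge_pairs(r1, r2)
    assert merged is not None
    assert merged.residues == fragment
    assert adapter[:10] not in merged.residues


def test_non_overlapping_pair_unmerged(rng):
    fragment = random_dna(rng, 400)
    r1 = _read("f/1", fragment[:100], [35] * 100)
    r2 = _read("f/2", reverse_complement(fragment[-100:]), [35] * 100)
    assert RA.merge_pairs(r1, r2) is None


def test_merge_conflict_takes_higher_quality_base(rng):
    fragment = random_dna(rng, 100)
    r1_seq = (fragment + "X")[:70]
    r2_seq = reverse_complement(fragment)[:70]
    # plant a disagreement inside the overlap (positions 30..69 of fragment)
    pos = 50
    wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[fragment[pos]]
    r1_seq = r1_seq[:pos] + wrong + r1_seq[pos + 1 :]
    q1 = [20] * 70
    q2 = [38] * 70
    merged = RA.merge_pairs(_read("f/1", r1_seq, q1), _read("f/2", r2_seq, q2))
    assert merged.residues[pos] == fragment[pos]  # r2 wins on quality
    assert merged.qualities[pos] == 18  # |q1 - q2|


def test_merge_never_invents_bases(rng):
    """Every merged base comes from one of the two reads at that position."""
    for _ in range(50):
        fragment = random_dna(rng, int(rng.integers(60, 180)))
        r1, r2 = _pair_from_fragment(fragment, 100)
        r1.residues = mutate(rng, r1.residues, 0.02)
        r2.residues = mutate(rng, r2.residues, 0.02)
        merged = RA.merge_pairs(r1, r2)
        if merged is None:
            continue
        b = reverse_complement(r2.residues)
        s = len(merged.residues) - len(b)
        for i, base in enumerate(merged.residues):
            from_r1 = i < len(r1.residues) and r1.residues[i] == base
            j = i - s
            from_r2 = 0 <= j < len(b) and b[j] == base
            assert from_r1 or from_r2


def test_zero_length_read_unmerged():
    r1 = SequenceRecord(id="a", residues="")
    r2 = SequenceRecord(id="b", residues="ACGT")
    assert RA.merge_pairs(r1, r2) is None


# ---------------------------------------------------------------------------
# recruitment


def _refs(rng, n=3, length=400):
    return [
        SequenceRecord(id=f"ref{i}", residues=random_dna(rng, length), locus=f"L{i:03d}")
        for i in range(n)
    ]


def test_verbatim_read_recruits_to_its_locus(rng):
    refs = _refs(rng)
    read = _read("r0", refs[1].residues[100:250])
    result = RA.recruit_reads([read], refs)
    assert list(result.by_locus) == ["L001"]
    assert result.by_locus["L001"][0].offset == 100


def test_reverse_strand_read_recruits_oriented(rng):
    refs = _refs(rng)
    read = _read("r0", reverse_complement(refs[2].residues[50:200]))
    result = RA.recruit_reads([read], refs)
    [ar] = result.by_locus["L002"]
    assert ar.strand == "-"
    assert ar.read.residues == refs[2].residues[50:200]
    assert ar.offset == 50


def test_divergent_ortholog_reads_recruit_correctly(rng):
    """Reads from a 12%-divergent ortholog reach the right locus >=99% of
    the time; random reads are never recruited."""
    refs = _refs(rng, n=4)
    orthologs = [mutate(rng, r.residues, 0.12) for r in refs]
    n, correct = 0, 0
    for trial in range(2000):
        locus = trial % 4
        start = int(rng.integers(0, 250))
        read = _read(f"r{trial}", orthologs[locus][start : start + 150])
        result = RA.recruit_reads([read], refs)
        n += 1
        if list(result.by_locus) == [f"L{locus:03d}"]:
            correct += 1
    assert correct / n >= 0.99

    decoys = [_read(f"d{i}", random_dna(rng, 150)) for i in range(2000)]
    result = RA.recruit_reads(decoys, refs)
    assert result.by_locus == {}
    assert len(result.unassigned) == 2000


def test_multi_locus_read_flagged(rng):
    shared = random_dna(rng, 400)
    refs = [
        SequenceRecord(id="refA", residues=shared, locus="LA"),
        SequenceRecord(id="refB", residues=mutate(rng, shared, 0.02), locus="LB"),
    ]
    read = _read("r0", shared[100:260])
    result = RA.recruit_reads([read], refs)
    assert "r0" in result.multi_locus
    assert list(result.by_locus) == ["LA"]  # best (exact) wins


# ---------------------------------------------------------------------------
# extension assembly


def _tiled_cluster(rng, genome, anchor_start, anchor_len, read_len=150, step=5):
    """Cluster seeded with reads covering the anchor; pool holds the rest."""
    reads = [
        _read(f"t{start:05d}", genome[start : start + read_len])
        for start in range(0, len(genome) - read_len + 1, step)
    ]
    anchor_end = anchor_start + anchor_len
    seeded = [r for r in reads if int(r.id[1:]) >= anchor_start and int(r.id[1:]) + read_len <= anchor_end]
    pool = [r for r in reads if r not in seeded]
    cluster = RA.AssemblyCluster(locus_id="L000", sample="s")
    for r in seeded:
        cluster.add(r, int(r.id[1:]) - anchor_start)
    return cluster, pool


def test_extend_without_reads_is_fixed_point(rng, sim_config):
    genome = random_dna(rng, 2000)
    cluster, _pool = _tiled_cluster(rng, genome, 750, 500)
    before = cluster.consensus_string()
    RA.extend_assembly(cluster, [], sim_config)
    assert cluster.consensus_string() == before


def test_extension_recovers_flanks(rng, sim_config):
    """From a 500-base anchor, extension claims tiling reads out to >=90%
    of 750-base flanks either side."""
    genome = random_dna(rng, 2000)
    cluster, pool = _tiled_cluster(rng, genome, 750, 500)
    RA.extend_assembly(cluster, pool, sim_config)
    cons = cluster.consensus_string()
    assert len(cons) >= 0.9 * 2000
    assert cons in genome or genome in cons  # error-free reads -> exact


def test_extension_is_read_order_invariant(rng, sim_config):
    genome = random_dna(rng, 1500)
    cluster1, pool = _tiled_cluster(rng, genome, 500, 400)
    cluster2 = RA.AssemblyCluster(locus_id="L000", sample="s")
    for r in cluster1.reads:
        cluster2.add(r, cluster1.offsets[r.id])
    shuffled = list(pool)
    rng.shuffle(shuffled)
    RA.extend_assembly(cluster1, pool, sim_config)
    RA.extend_assembly(cluster2, shuffled, sim_config)
    assert cluster1.consensus_string() == cluster2.consensus_string()
    assert cluster1.offsets == cluster2.offsets


# ---------------------------------------------------------------------------
# consensus calling


def _uniform_cluster(n_reads, residues="ACGT" * 25):
    cluster = RA.AssemblyCluster(locus_id="L000", sample="s")
    for i in range(n_reads):
        cluster.add(_read(f"r{i}", residues), 0)
    return cluster


def test_depth_gate_is_strict():
    """Average depth exactly 250 is rejected; anything above is emitted."""
    cfg = PipelineConfig()  # protocol default gate: 250
    assert RA.call_consensus(_uniform_cluster(250), cfg) is None
    assert RA.call_consensus(_uniform_cluster(251), cfg) is not None


def _site_cluster(counts):
    """Cluster of length-1 reads realising one site with given base counts."""
    cluster = RA.AssemblyCluster(locus_id="L000", sample="s")
    i = 0
    for base, count in counts.items():
        for _ in range(count):
            cluster.add(_read(f"r{i}", base), 0)
            i += 1
    return cluster


def test_consensus_site_examples():
    cfg = PipelineConfig(min_avg_depth=250)
    assert RA.call_consensus(_site_cluster({"A": 300}), cfg).residues == "A"
    assert RA.call_consensus(_site_cluster({"A": 290, "G": 10}), cfg).residues == "R"
    assert RA.call_consensus(_site_cluster({"A": 297, "G": 3}), cfg).residues == "A"


def test_consensus_majority_tie_gets_both():
    cfg = PipelineConfig(min_avg_depth=100)
    cons = RA.call_consensus(_site_cluster({"A": 150, "G": 150}), cfg)
    assert cons.residues == "R"


def test_consensus_agrees_with_exact_binomial_oracle():
    """Minority-base retention matches an independent tail-sum oracle over
    depth {50,100,300,1000} x minor count 0..20 at p=0.01, alpha=0.05."""

    def oracle_tail(c, n, p):  # P(X >= c), exact
        return sum(math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(c, n + 1))

    cfg = PipelineConfig(min_avg_depth=1)
    p, alpha = 0.01, 0.05
    for depth in (50, 100, 300, 1000):
        # read i carries G at site j iff i < j: site j has minor count j
        n_sites = 21
        reads = []
        for i in range(depth):
            if i < n_sites:
                reads.append("A" * (i + 1) + "G" * (n_sites - i - 1))
            else:
                reads.append("A" * n_sites)
        cluster = RA.AssemblyCluster(locus_id="L", sample="s")
        for i, r in enumerate(reads):
            cluster.add(_read(f"r{i}", r), 0)
        cons = RA.call_consensus(cluster, cfg)
        for j in range(n_sites):
            minor = j
            expect_retained = minor > 0 and oracle_tail(minor, depth, p) < alpha
            expected = "R" if expect_retained else "A"
            assert cons.residues[j] == expected, (depth, minor)


def test_error_free_single_haplotype_has_no_ambiguity(rng, sim_config):
    genome = [SequenceRecord(id="g", residues=random_dna(rng, 800))]
    pairs, _ = simulate_reads(genome, coverage=40, error_rate=0.0, seed=77)
    reads = RA.merge_read_pool(pairs)
    refs = [SequenceRecord(id="ref", residues=genome[0].residues[200:600], locus="L000")]
    result = RA.recruit_reads(reads, refs, sim_config)
    clusters = RA.make_clusters(result, "s")
    RA.extend_all(clusters, result.unassigned, sim_config)
    cons = RA.call_consensus(clusters["L000"], sim_config)
    assert set(cons.residues) <= set("ACGT")


def test_heterozygous_sites_receive_two_base_codes(rng):
    """Planted 50/50 het sites at ~300x depth get the correct two-base
    IUPAC code at >=95% of sites."""
    genome_seq = random_dna(rng, 600)
    het_positions = list(range(50, 550, 50))
    het_sites = []
    for pos in het_positions:
        ref_base = genome_seq[pos]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        het_sites.append(("g", pos, alt))
    genome = [SequenceRecord(id="g", residues=genome_seq)]
    pairs, truth = simulate_reads(
        genome, coverage=300, error_rate=0.01, het_sites=het_sites, seed=99
    )
    cluster = RA.AssemblyCluster(locus_id="L000", sample="s")
    for (r1, r2) in pairs:
        frag = truth[r1.id.rsplit(":", 1)[0]]
        cluster.add(r1, frag.start)
        r2f = r2.reverse_complement()
        cluster.add(r2f, frag.end - len(r2f))
    cons = RA.call_consensus(cluster, PipelineConfig(min_avg_depth=250))
    from anchorsmith.io_core import SET_FROM_IUPAC

    good = 0
    for (contig, pos, alt) in het_sites:
        expected = frozenset({genome_seq[pos], alt})
        if SET_FROM_IUPAC.get(cons.residues[pos]) == expected:
            good += 1
    assert good / len(het_sites) >= 0.95


def test_uncovered_site_is_n():
    cluster = RA.AssemblyCluster(locus_id="L", sample="s")
    cluster.add(_read("r1", "AAA"), 0)
    cluster.add(_read("r2", "TTT"), 5)  # gap at positions 3..4
    cons = RA.call_consensus(cluster, PipelineConfig(min_avg_depth=0.1))
    assert cons.residues == "AAANNTTT"
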