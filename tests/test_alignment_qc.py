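"""Trimming thresholds, masking, filtering, dedup, repeat masking, concat."""

import numpy as np
import pytest

from anchorsmith.io_core import PipelineConfig, SequenceRecord
from anchorsmith import alignment_qc as Q
from anchorsmith import kmerlib as K
from anchorsmith.synthetic_data import mutate, random_dna


def aln_from(seqs, ids=None, locus_id="L"):
    ids = ids or [f"t{i}" for i in range(len(seqs))]
    return Q.AlignmentMatrix.from_records(
        [SequenceRecord(id=i, residues=s) for i, s in zip(ids, seqs)], locus_id=locus_id
    )


# ---------------------------------------------------------------------------
# reliable sites


def test_invariant_column_is_reliable():
    aln = aln_from(["A"] * 10)
    assert Q.identify_reliable_sites(aln).tolist() == [True]


def test_fifty_percent_boundary_is_inclusive():
    aln = aln_from(["A"] * 5 + ["C"] * 5)
    assert Q.identify_reliable_sites(aln, threshold=0.5).tolist() == [True]


def test_modal_frequency_below_threshold_unreliable():
    aln = aln_from(["A"] * 4 + ["C"] * 3 + ["G"] * 3)  # modal 0.4
    assert Q.identify_reliable_sites(aln).tolist() == [False]


def test_gap_only_site_unreliable():
    aln = aln_from(["-A", "-C", "-A", "-A"])
    assert Q.identify_reliable_sites(aln).tolist() == [False, True]


def test_gaps_leave_the_denominator():
    # 3 A of 3 non-gap chars at site 0, plus 5 gap rows: fully reliable
    aln = aln_from(["A"] * 3 + ["-"] * 5)
    assert Q.identify_reliable_sites(aln).tolist() == [True]


# ---------------------------------------------------------------------------
# misaligned-run masking


def _disagreement_fixture(run_length, n_taxa=20, length=60, start=10):
    """One deviant row disagreeing with an otherwise invariant alignment
    over [start, start+run_length)."""
    base = "A" * length
    deviant = list(base)
    for i in range(start, start + run_length):
        deviant[i] = "C"
    return aln_from([base] * (n_taxa - 1) + ["".join(deviant)])


def test_fourteen_base_run_is_masked():
    aln = Q.mask_misaligned_regions(_disagreement_fixture(14), run_threshold=14)
    assert aln.mask[-1, 10:24].all()
    assert not aln.mask[:-1].any()
    assert not aln.mask[-1, :10].any() and not aln.mask[-1, 24:].any()


def test_thirteen_base_run_is_not_masked():
    aln = Q.mask_misaligned_regions(_disagreement_fixture(13), run_threshold=14)
    assert not aln.mask.any()


def test_run_broken_by_gap_or_agreement():
    base = "A" * 40
    deviant = "C" * 10 + "-" + "C" * 10 + "A" + "C" * 10 + "A" * 8
    aln = aln_from([base] * 9 + [deviant])
    masked = Q.mask_misaligned_regions(aln, run_threshold=14)
    assert not masked.mask.any()  # all disagreement runs are <= 10


def test_masking_never_alters_characters():
    aln = _disagreement_fixture(20)
    masked = Q.mask_misaligned_regions(aln)
    assert (masked.chars == aln.chars).all()


def test_random_mutations_never_reach_run_threshold(rng):
    """At 5% scattered disagreement, runs of 14 are vanishingly unlikely."""
    root = random_dna(rng, 500)
    rows = [root] * 30 + [mutate(rng, root, 0.05) for _ in range(2000)]
    masked = Q.mask_misaligned_regions(aln_from(rows), run_threshold=14)
    assert not masked.mask.any()


# ---------------------------------------------------------------------------
# sparse sites / sparse loci


def test_site_occupancy_boundary():
    """A site present in 24 sequences is removed; 25 is kept."""
    n = 30
    col_24 = ["A"] * 24 + ["-"] * 6
    col_25 = ["A"] * 25 + ["-"] * 5
    rows = ["".join(pair) for pair in zip(col_24, col_25)]
    aln = aln_from(rows)
    out = Q.drop_sparse_sites(aln, min_sequences=25)
    assert out.n_sites == 1
    assert out.site_map.tolist() == [1]


def test_full_alignment_loses_nothing():
    aln = aln_from(["ACGT"] * 55)
    out = Q.drop_sparse_sites(aln, min_sequences=25)
    assert out.n_sites == 4


def test_removal_count_matches_census_oracle(rng):
    rows = []
    for _ in range(40):
        row = "".join(
            "-" if rng.random() < 0.5 else "ACGT"[int(rng.integers(4))] for _ in range(80)
        )
        rows.append(row)
    aln = aln_from(rows)
    out = Q.drop_sparse_sites(aln, min_sequences=25)
    expected_kept = sum(
        1 for j in range(80) if sum(rows[i][j] != "-" for i in range(40)) >= 25
    )
    assert out.n_sites == expected_kept


def test_masked_cells_do_not_count_as_present():
    aln = aln_from(["A"] * 25 + ["-"] * 5)
    aln.mask[0, 0] = True
    out = Q.drop_sparse_sites(aln, min_sequences=25)
    assert out.n_sites == 0


@pytest.mark.parametrize("present,kept", [(4, False), (5, True), (10, True)])
def test_locus_occupancy_boundary(present, kept):
    rows = ["ACGTACGT" * 10] * present + ["-" * 80] * (10 - present)
    loci = {"L0": aln_from(rows)}
    out = Q.filter_sparse_loci(loci, min_fraction=0.5, panel_size=10)
    assert ("L0" in out) is kept


# ---------------------------------------------------------------------------
# trim/mask idempotence


def test_trim_mask_pipeline_is_idempotent(rng):
    cfg = PipelineConfig(min_sequences_per_site=8)
    root = random_dna(rng, 300)
    rows = []
    for i in range(12):
        row = mutate(rng, root, 0.04)
        if i == 0:  # a genuinely misaligned stretch
            row = row[:100] + random_dna(rng, 40) + row[140:]
        if i < 3:  # ragged ends
            row = "-" * 30 + row[30:]
        rows.append(row)
    aln = aln_from(rows)
    once = Q.trim_and_mask(aln, cfg)
    twice = Q.trim_and_mask(once, cfg)
    assert once.n_sites == twice.n_sites
    assert (once.chars == twice.chars).all()
    assert (once.mask == twice.mask).all()


# ---------------------------------------------------------------------------
# dedup


def test_disjoint_loci_both_kept(rng):
    loci = {"A": aln_from([random_dna(rng, 200)]), "B": aln_from([random_dna(rng, 200)])}
    assert set(Q.dedup_overlapping_loci(loci)) == {"A", "B"}


def test_contained_locus_removed(rng):
    big = random_dna(rng, 400)
    loci = {"A": aln_from([big]), "B": aln_from([big[100:200]])}
    assert set(Q.dedup_overlapping_loci(loci)) == {"A"}


def test_dedup_tie_removes_later_id(rng):
    seq = random_dna(rng, 150)
    loci = {"A": aln_from([seq]), "B": aln_from([seq])}
    assert set(Q.dedup_overlapping_loci(loci)) == {"A"}


def test_dedup_postcondition_on_chained_overlaps(rng):
    """A~B and B~C overlapping chains resolve to pairwise-disjoint output."""
    x, y, z = random_dna(rng, 200), random_dna(rng, 200), random_dna(rng, 200)
    loci = {
        "A": aln_from([x + y[:40]]),
        "B": aln_from([y]),
        "C": aln_from([y[-40:] + z]),
        "D": aln_from([random_dna(rng, 100)]),
    }
    kept = Q.dedup_overlapping_loci(loci)
    assert "D" in kept
    sets = {lid: Q._locus_kmers(aln, 20) for lid, aln in kept.items()}
    ids = sorted(sets)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            assert not (sets[a] & sets[b])


def test_dedup_postcondition_on_random_fixtures(rng):
    shared = random_dna(rng, 60)
    loci = {}
    for i in range(8):
        seq = random_dna(rng, int(rng.integers(80, 250)))
        if i % 2 == 0:
            seq = seq[:40] + shared + seq[40:]
        loci[f"L{i}"] = aln_from([seq])
    kept = Q.dedup_overlapping_loci(loci)
    sets = {lid: Q._locus_kmers(aln, 20) for lid, aln in kept.items()}
    ids = sorted(sets)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            assert not (sets[a] & sets[b])
    # every odd (unshared) locus survives
    assert all(f"L{i}" in kept for i in (1, 3, 5, 7))


# ---------------------------------------------------------------------------
# repeat masking


def test_unique_locus_is_not_masked(rng):
    genome = random_dna(rng, 3000)
    reads = [genome[s : s + 150] for s in range(0, 2850, 5)]
    profile = K.profile_from_reads(reads, 20)
    aln = aln_from([genome[500:1000]])
    masked = Q.mask_repetitive_regions(aln, profile, elevation_factor=5)
    assert not masked.mask.any()


def test_planted_repeat_span_is_masked(rng):
    unit = random_dna(rng, 300)
    genome = random_dna(rng, 3000) + "".join(
        unit + random_dna(rng, 100) for _ in range(10)
    )
    reads = [genome[s : s + 150] for s in range(0, len(genome) - 150, 5)]
    profile = K.profile_from_reads(reads, 20)
    locus_seq = genome[2500:3000] + unit
    aln = aln_from([locus_seq])
    masked = Q.mask_repetitive_regions(aln, profile, elevation_factor=5)
    span = masked.mask[0, 500:800]
    # the repeat span is masked except k-1 edge attenuation
    assert span[19:-19].all()
    assert not masked.mask[0, :480].any()


def test_elevation_factor_is_monotone(rng):
    unit = random_dna(rng, 200)
    genome = random_dna(rng, 2000) + unit * 8
    reads = [genome[s : s + 150] for s in range(0, len(genome) - 150, 4)]
    profile = K.profile_from_reads(reads, 20)
    aln = aln_from([genome[1800:2200]])
    m5 = Q.mask_repetitive_regions(aln, profile, elevation_factor=5)
    m10 = Q.mask_repetitive_regions(aln, profile, elevation_factor=10)
    assert int(m10.mask.sum()) <= int(m5.mask.sum())


def test_all_zero_track_masks_nothing(rng):
    profile = K.KmerProfile(20, {}, canonical=True)
    aln = aln_from([random_dna(rng, 100)])
    assert not Q.mask_repetitive_regions(aln, profile).mask.any()


# ---------------------------------------------------------------------------
# concatenation


def test_concatenate_partition_arithmetic(rng):
    taxa = [f"t{i}" for i in range(3)]
    loci = {
        "l1": aln_from([random_dna(rng, 100)] * 3, ids=taxa),
        "l2": aln_from([random_dna(rng, 200)] * 3, ids=taxa),
        "l3": aln_from([random_dna(rng, 300)] * 3, ids=taxa),
    }
    supermatrix, partitions = Q.concatenate(loci, taxa)
    assert supermatrix.n_sites == 600
    assert partitions == [("l1", 1, 100), ("l2", 101, 300), ("l3", 301, 600)]
    # per-locus slices reproduce the inputs
    for (locus_id, start, end) in partitions:
        for i in range(3):
            assert (
                supermatrix.sequence(i)[start - 1 : end]
                == loci[locus_id].sequence(i)
            )


def test_missing_taxon_padded_with_gaps(rng):
    loci = {
        "l1": aln_from([random_dna(rng, 50)] * 2, ids=["t0", "t1"]),
        "l2": aln_from([random_dna(rng, 70)], ids=["t0"]),
    }
    supermatrix, _ = Q.concatenate(loci, ["t0", "t1"])
    assert supermatrix.sequence(1)[50:] == "-" * 70


def test_duplicate_taxon_in_locus_is_error(rng):
    with pytest.raises(ValueError):
        aln_from([random_dna(rng, 30)] * 2, ids=["t0", "t0"])


def test_partition_file_format(tmp_path, rng):
    loci = {"locus1": aln_from([random_dna(rng, 40)])}
    _sm, partitions = Q.concatenate(loci, ["t0"])
    path = tmp_path / "partitions.txt"
    Q.write_partitions(partitions, path)
    assert path.read_text() == "DNA, locus1 = 1-40\n"


def test_locus_alignment_stats(rng):
    loci = {
        "a": aln_from([random_dna(rng, 100)]),
        "b": aln_from([random_dna(rng, 300)]),
    }
    stats = Q.locus_alignment_stats(loci)
    assert stats == {
        "n_loci": 2, "mean_length": 200.0, "median_length": 200.0,
        "min_length": 100, "max_length": 300, "total_length": 400,
    }


# ---------------------------------------------------------------------------
# star alignment (internal fallback) and the external adapter


def test_star_alignment_exact_for_offset_substitution_copies(rng):
    center = random_dna(rng, 800)
    records = [
        SequenceRecord(id="t0", residues=center),
        SequenceRecord(id="t1", residues=mutate(rng, center[100:700], 0.05)),
        SequenceRecord(id="t2", residues=mutate(rng, center[250:], 0.08)),
    ]
    aln = Q.align_star(records)
    assert aln.n_sites == 800
    assert aln.sequence(1)[:100] == "-" * 100
    assert aln.sequence(1)[700:] == "-" * 100
    assert aln.sequence(2)[:250] == "-" * 250


def test_external_aligner_adapter_runs_mafft(rng):
    root = random_dna(rng, 240)
    records = [
        SequenceRecord(id=f"t{i}", residues=mutate(rng, root, 0.03)) for i in range(3)
    ]
    aln = Q.align_external(records)
    assert aln.n_taxa == 3
    assert aln.n_sites >= 240
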