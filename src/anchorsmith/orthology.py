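"""Alignment-free orthology: 20-mer Jaccard distances + agglomerative clustering.

Consensus sequences from all samples (plus the reference anchor sequences)
are compared by the overlap of their canonical 20-mer sets; agglomerative
clustering of the resulting distance matrix, cut at a configurable height,
recovers one group per locus.  Within the separation regime of divergent
congeners sharing conserved anchors, within-locus distances sit well below
the ~1.0 distance of unrelated loci, so the cut is not delicate; linkage
and cutoff are configurable because the upstream protocol does not print
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_core import PipelineConfig, SequenceRecord, get_logger, write_tsv
from . import kmerlib

log = get_logger("anchorsmith.orthology")


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_tsv(self, path) -> None:
        rows = [[lab] + [f"{v:.6f}" for v in row] for lab, row in zip(self.labels, self.values)]
        write_tsv(path, ["id"] + list(self.labels), rows)


@dataclass
class OrthologGroup:
    locus_id: str
    members: dict  # sample -> member id (at most one per sample)
    anchor_reference: str
    paralogs: list = field(default_factory=list)  # flagged ids not kept


def build_distance_matrix(consensi: Sequence[SequenceRecord], k: int = 20) -> DistanceMatrix:
    """Pairwise 20-mer Jaccard distances over canonical k-mer sets.

    A sequence shorter than k has an empty profile and sits at distance 1
    from everything (warned); the diagonal stays 0.
    """
    if len(consensi) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    labels = [rec.id for rec in consensi]
    sets = []
    for rec in consensi:
        if len(rec) < k:
            log.warning("sequence %s shorter than k=%d; all-1 distance row", rec.id, k)
        sets.append(kmerlib.enumerate_kmers(rec, k, canonical=True).distinct)
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            if union == 0:
                d = 1.0
            else:
                d = 1.0 - len(sets[i] & sets[j]) / union
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def _default_sample_of(label: str) -> str:
    return label.split("::", 1)[0]


def cluster_orthologs(
    matrix: DistanceMatrix,
    linkage: str = "average",
    cutoff: float = 0.999,
    reference_ids: Optional[set] = None,
    sample_of: Callable[[str], str] = _default_sample_of,
    locus_of_reference: Optional[dict] = None,
) -> list[OrthologGroup]:
    """Cut an agglomerative tree at ``cutoff`` and keep reference-anchored groups.

    ``reference_ids`` marks the anchor reference sequences included in the
    matrix; a cluster without one belongs to no known locus and is dropped
    (logged).  If a cluster holds two sequences from one sample, the one
    nearer (mean distance) to the rest of the cluster is kept and the other
    flagged as a putative paralog.
    """
    reference_ids = reference_ids or set()
    locus_of_reference = locus_of_reference or {}
    labels = matrix.labels
    n = len(labels)
    if n == 1:
        lab = labels[0]
        return [OrthologGroup(locus_of_reference.get(lab, lab), {sample_of(lab): lab}, lab)]
    condensed = squareform(matrix.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    flat = hierarchy.fcluster(Z, t=cutoff, criterion="distance")
    clusters: dict = {}
    for label, cid in zip(labels, flat):
        clusters.setdefault(cid, []).append(label)

    idx = {lab: i for i, lab in enumerate(labels)}
    groups = []
    for cid in sorted(clusters, key=lambda c: sorted(clusters[c])[0]):
        members = sorted(clusters[cid])
        refs = [m for m in members if m in reference_ids]
        if reference_ids and not refs:
            log.info("cluster %s has no reference member; dropped", members)
            continue
        anchor = refs[0] if refs else members[0]
        if len(refs) > 1:
            log.info("cluster holds %d reference members (%s); using %s", len(refs), refs, anchor)
        locus = locus_of_reference.get(anchor, anchor)
        non_ref = [m for m in members if m not in reference_ids]
        by_sample: dict = {}
        paralogs = []
        for m in non_ref:
            by_sample.setdefault(sample_of(m), []).append(m)
        kept: dict = {}
        for sample, ms in by_sample.items():
            if len(ms) == 1:
                kept[sample] = ms[0]
                continue
            others = [idx[o] for o in members if o not in ms]

            def mean_dist(m):
                if not others:
                    return 0.0
                return float(np.mean([matrix.values[idx[m], o] for o in others]))

            ranked = sorted(ms, key=lambda m: (mean_dist(m), m))
            kept[sample] = ranked[0]
            paralogs.extend(ranked[1:])
            log.info("sample %s duplicated in locus %s; flagged %s", sample, locus, ranked[1:])
        groups.append(OrthologGroup(locus, kept, anchor, paralogs))
    return groups


def groups_to_tsv(groups: Sequence[OrthologGroup], path) -> None:
    rows = []
    for g in groups:
        for sample in sorted(g.members):
            rows.append((g.locus_id, g.members[sample]))
    write_tsv(path, ["locus_id", "member_id"], rows)
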