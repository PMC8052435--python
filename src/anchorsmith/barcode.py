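"""mtCOI barcode utilities: percent identity, the 98-100% species-assignment
rule, and the unique-barcode / barcode-gap report.

A query is considered the same species as its best-matching reference when
their identity reaches the assignment threshold (default 98%); a barcode is
"unique" when no reference matches it at 100%.  The report also carries the
best identity to any reference labelled as a *different* species, the
quantity whose separation from within-species identity constitutes the
barcode gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .io_core import SET_FROM_IUPAC, SequenceRecord, get_logger, write_tsv
from . import kmerlib

log = get_logger("anchorsmith.barcode")

# 4-bit base-set encoding of every IUPAC symbol, for degenerate matching
_IUPAC_BITS = np.zeros(256, dtype=np.uint8)
for _code, _bases in SET_FROM_IUPAC.items():
    _IUPAC_BITS[ord(_code)] = sum(1 << "ACGT".index(b) for b in _bases)


def _match_arrays(xa: np.ndarray, xb: np.ndarray, degenerate: bool) -> np.ndarray:
    if not degenerate:
        return xa == xb
    return (_IUPAC_BITS[xa] & _IUPAC_BITS[xb]) != 0


def percent_identity(
    a: SequenceRecord, b: SequenceRecord, aligned: bool = False, degenerate: bool = False
) -> float:
    """100 x identical positions / compared positions.

    With ``aligned=True`` the sequences are columns of one alignment and
    columns where either has a gap leave the denominator.  Otherwise the
    best gapless overlap (exhaustive offset search, maximising matches) is
    compared.  With ``degenerate=True`` two symbols match whenever their
    IUPAC base sets intersect (used when scoring ambiguity-coded consensi
    against a known haplotype).  Zero compared positions is an error.
    """
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        xa, xb = kmerlib.encode(a.residues), kmerlib.encode(b.residues)
        gap = ord("-")
        compared = (xa != gap) & (xb != gap)
        n = int(compared.sum())
        if n == 0:
            raise ValueError(f"no compared positions between {a.id} and {b.id}")
        return 100.0 * int((_match_arrays(xa, xb, degenerate) & compared).sum()) / n

    xa = kmerlib.encode(a.residues.replace("-", ""))
    xb = kmerlib.encode(b.residues.replace("-", ""))
    la, lb = len(xa), len(xb)
    if la == 0 or lb == 0:
        raise ValueError(f"no compared positions between {a.id} and {b.id}")
    best_matches, best_overlap = -1, 0
    for s in range(-(lb - 1), la):
        a0, a1 = max(0, s), min(la, s + lb)
        o = a1 - a0
        if o <= 0:
            continue
        b0 = a0 - s
        matches = int(np.count_nonzero(_match_arrays(xa[a0:a1], xb[b0 : b0 + o], degenerate)))
        if matches > best_matches or (matches == best_matches and o > best_overlap):
            best_matches, best_overlap = matches, o
    return 100.0 * best_matches / best_overlap


@dataclass
class BarcodeReport:
    query_id: str
    best_match_id: str
    best_identity: float  # percent
    assigned: bool
    unique: bool  # no 100% match among references
    next_closest_other_label: Optional[tuple]  # (label, percent) or None


def _default_label(rec: SequenceRecord) -> str:
    return rec.sample if rec.sample else rec.id


def assign_species(
    query: SequenceRecord,
    references: Sequence[SequenceRecord],
    threshold: float = 0.98,
    label_of: Callable[[SequenceRecord], str] = _default_label,
    aligned: bool = False,
) -> BarcodeReport:
    """Apply the identity-threshold assignment rule against labelled references.

    ``assigned`` is True iff the best identity reaches ``threshold``;
    ``unique`` iff no reference matches at 100%; the next-closest field is
    the best identity among references carrying a different label than the
    best match.  Reference order does not matter (ties break to the
    lexicographically smaller reference id).
    """
    if not references:
        raise ValueError("assign_species requires at least one reference")
    identities = []
    for ref in sorted(references, key=lambda r: r.id):
        identities.append((percent_identity(query, ref, aligned=aligned), ref))
    best_identity = max(ident for ident, _ref in identities)
    best_ref = next(ref for ident, ref in identities if ident == best_identity)
    best_label = label_of(best_ref)
    others = [(ident, ref) for ident, ref in identities if label_of(ref) != best_label]
    next_closest = None
    if others:
        o_ident = max(ident for ident, _ref in others)
        o_ref = next(ref for ident, ref in others if ident == o_ident)
        next_closest = (label_of(o_ref), o_ident)
    return BarcodeReport(
        query_id=query.id,
        best_match_id=best_ref.id,
        best_identity=best_identity,
        assigned=best_identity >= 100.0 * threshold,
        unique=best_identity < 100.0 - 1e-9,
        next_closest_other_label=next_closest,
    )


def barcode_report_tsv(reports: Sequence[BarcodeReport], path) -> None:
    rows = []
    for r in reports:
        nc_label, nc_ident = r.next_closest_other_label or ("NA", "NA")
        rows.append(
            (r.query_id, r.best_match_id, f"{r.best_identity:.2f}", r.assigned, r.unique,
             nc_label, nc_ident if nc_ident == "NA" else f"{nc_ident:.2f}")
        )
    write_tsv(
        path,
        ["query_id", "best_match_id", "best_identity", "assigned", "unique",
         "next_closest_label", "next_closest_identity"],
        rows,
    )
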