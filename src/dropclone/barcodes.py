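"""Barcode extraction, whitelist error correction, and read-to-amplicon assignment.

Read 1 of a droplet amplicon library starts with the cell barcode, followed
by a gene-specific forward primer and the amplicon insert.  Reads are
assigned to (corrected barcode, amplicon) pairs; failures carry a reason
code rather than raising, mirroring how unassignable reads are tallied in
run metrics.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import BASES, AmpliconPanel, BarcodeWhitelist

#: reason codes for read assignment
OK = "ok"
BAD_BARCODE = "bad_barcode"
NO_PRIMER = "no_primer"
OFF_TARGET = "off_target"
REASONS = (OK, BAD_BARCODE, NO_PRIMER, OFF_TARGET)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def correct_barcode(
    observed: str, whitelist: BarcodeWhitelist, max_dist: int = 1
) -> str | None:
    """Error-correct ``observed`` against the whitelist.

    Returns the unique whitelist barcode within Hamming distance
    ``max_dist``, or None when no barcode qualifies, two or more tie at the
    minimum distance, or the observed length does not match the whitelist.

    An exact hit is O(1); otherwise the distance-1 neighbourhood is
    enumerated (O(length x alphabet) lookups), independent of whitelist
    size.  ``max_dist >= 2`` falls back to a full scan.
    """
    if len(observed) != whitelist.length:
        return None
    if observed in whitelist:
        return observed
    if max_dist <= 0:
        return None
    if max_dist == 1:
        hits = []
        for i, base in enumerate(observed):
            for sub in BASES:
                if sub == base:
                    continue
                candidate = observed[:i] + sub + observed[i + 1 :]
                if candidate in whitelist:
                    hits.append(candidate)
        if len(hits) == 1:
            return hits[0]
        return None
    # rare configurable path: exhaustive scan with unique-minimum rule
    best, best_d, tied = None, max_dist + 1, False
    for bc in whitelist.barcodes:
        d = hamming(observed, bc)
        if d < best_d:
            best, best_d, tied = bc, d, False
        elif d == best_d:
            tied = True
    if best is not None and best_d <= max_dist and not tied:
        return best
    return None


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of assigning one read pair."""

    barcode: str | None
    amplicon: str | None
    reason: str
    insert: str = ""


def _match_primer(region_source: str, panel: AmpliconPanel, start: int) -> list[str]:
    """Amplicon names whose forward primer matches at ``start`` within 1 mismatch."""
    hits = []
    for amp in panel.amplicons:
        primer = amp.primer_fwd
        region = region_source[start : start + len(primer)]
        if len(region) < len(primer):
            continue
        mismatches = 0
        for x, y in zip(region, primer):
            if x != y:
                mismatches += 1
                if mismatches > 1:
                    break
        if mismatches <= 1:
            hits.append(amp.name)
    return hits


def assign_read(
    read1: str,
    panel: AmpliconPanel,
    whitelist: BarcodeWhitelist,
    max_dist: int = 1,
) -> ReadAssignment:
    """Assign a read pair to (corrected barcode, amplicon).

    The barcode is corrected first; uncorrectable barcodes short-circuit
    with ``bad_barcode``.  The primer region immediately following the
    barcode must match exactly one panel forward primer within 1 mismatch:
    no match gives ``no_primer``, an ambiguous match gives ``off_target``.
    """
    bl = whitelist.length
    barcode = correct_barcode(read1[:bl], whitelist, max_dist)
    if barcode is None:
        return ReadAssignment(None, None, BAD_BARCODE)
    hits = _match_primer(read1, panel, bl)
    if not hits:
        return ReadAssignment(barcode, None, NO_PRIMER)
    if len(hits) > 1:
        return ReadAssignment(barcode, None, OFF_TARGET)
    amp = hits[0]
    insert = read1[bl + len(panel.by_name[amp].primer_fwd) :]
    return ReadAssignment(barcode, amp, OK, insert)


@dataclass
class CellCountMatrix:
    """Corrected-barcode x amplicon read counts plus unassigned tallies."""

    counts: pd.DataFrame  # index: barcode, columns: amplicon names
    unassigned: dict[str, int] = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        """Reads per barcode (row sums), descending."""
        return self.counts.sum(axis=1).sort_values(ascending=False, kind="stable")

    @property
    def n_assigned(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_reads(self) -> int:
        return self.n_assigned + sum(self.unassigned.values())

    @property
    def assignment_fraction(self) -> float:
        total = self.total_reads
        return self.n_assigned / total if total else float("nan")


def build_count_matrix(
    assignments: Iterable[ReadAssignment], panel: AmpliconPanel
) -> CellCountMatrix:
    """Aggregate read assignments into a barcode x amplicon count matrix.

    Deterministic regardless of read order: barcodes are sorted
    lexicographically, amplicons follow panel order.
    """
    amp_names = [a.name for a in panel.amplicons]
    amp_idx = {name: j for j, name in enumerate(amp_names)}
    unassigned = {BAD_BARCODE: 0, NO_PRIMER: 0, OFF_TARGET: 0}
    tallies: dict[str, np.ndarray] = {}
    for a in assignments:
        if a.reason == OK:
            row = tallies.get(a.barcode)
            if row is None:
                row = tallies[a.barcode] = np.zeros(len(amp_names), dtype=np.int64)
            row[amp_idx[a.amplicon]] += 1
        else:
            unassigned[a.reason] += 1
    barcodes = sorted(tallies)
    data = (
        np.vstack([tallies[b] for b in barcodes])
        if barcodes
        else np.zeros((0, len(amp_names)), dtype=np.int64)
    )
    counts = pd.DataFrame(data, index=barcodes, columns=amp_names)
    return CellCountMatrix(counts, {k: v for k, v in unassigned.items() if v or True})
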