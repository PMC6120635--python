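"""Pseudobulk VAFs and bulk-derived clonal inference.

Removing barcode identity and aggregating reads reproduces what a bulk
sequencing run would measure.  Under a diploid heterozygous assumption a
variant's cell fraction is twice its VAF; the simplest serial-acquisition
model nests variants by descending cell fraction (clone i carries
variants 1..i), giving a pigeonhole clonal architecture that can be
compared against the single-cell clone table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clones import CloneTable
from .genotype import AlleleCounts

HET_TOLERANCE = 0.02


def pseudobulk_vaf(
    counts: AlleleCounts, exclude_cells: Sequence[str] = ()
) -> pd.DataFrame:
    """Aggregate allele depths across barcodes into per-site VAFs.

    ``exclude_cells`` removes flagged barcodes (e.g. spike-in controls)
    before aggregation.  Returns a frame indexed by site id with columns
    ref_depth, alt_depth, vaf.
    """
    drop = set(exclude_cells)
    keep = [b for b in counts.ref.index if b not in drop]
    ref = counts.ref.loc[keep].sum(axis=0)
    alt = counts.alt.loc[keep].sum(axis=0)
    depth = ref + alt
    vaf = np.where(depth > 0, alt / depth.clip(lower=1), np.nan)
    return pd.DataFrame({"ref_depth": ref, "alt_depth": alt, "vaf": vaf})


@dataclass
class InferredClones:
    """Serially nested clonal architecture inferred from bulk VAFs.

    ``clones`` is ordered outermost-first: row i is the clone carrying
    variants 1..i (descending cell fraction), with its exclusive fraction
    (cells in clone i but not i+1).  ``wildtype_fraction`` completes the
    distribution.  Assumes every variant is heterozygous in its carriers
    and mutations were serially acquired.
    """

    clones: pd.DataFrame  # columns: variants (tuple), cell_fraction, exclusive_fraction
    wildtype_fraction: float
    assumptions: tuple[str, ...] = ("heterozygous", "serial_acquisition")

    def distribution(self) -> dict[frozenset, float]:
        """Clone-exclusive fractions keyed by carried-variant set (incl. WT)."""
        out = {frozenset(): self.wildtype_fraction}
        for _, row in self.clones.iterrows():
            out[frozenset(row["variants"])] = row["exclusive_fraction"]
        return out


def infer_clones_from_bulk(
    vafs: Mapping[str, float],
    assume_het: bool = True,
    tolerance: float = HET_TOLERANCE,
) -> InferredClones:
    """Infer a nested clonal architecture from bulk VAFs.

    Cell fraction per variant is 2 x VAF (het assumption; VAFs above
    0.5 + ``tolerance`` raise).  Variants are sorted by descending
    fraction and nested serially: the clone carrying variants 1..i has
    exclusive fraction f_i - f_{i+1}; wild type is 1 - f_1.  Fractions
    are clipped into [0, 1] only after the validity check.
    """
    if not vafs:
        raise ValueError("no VAFs supplied")
    if assume_het:
        for sid, v in vafs.items():
            if v > 0.5 + tolerance / 2:
                raise ValueError(
                    f"VAF {v:.3f} at {sid} violates the heterozygous assumption "
                    f"(2xVAF > 1 + {tolerance})"
                )
    order = sorted(vafs, key=lambda s: (-vafs[s], s))
    fractions = [min(2.0 * vafs[s], 1.0) for s in order]
    rows = []
    for i, sid in enumerate(order):
        nxt = fractions[i + 1] if i + 1 < len(order) else 0.0
        rows.append(
            {
                "variants": tuple(order[: i + 1]),
                "cell_fraction": fractions[i],
                "exclusive_fraction": max(fractions[i] - nxt, 0.0),
            }
        )
    wt = max(1.0 - fractions[0], 0.0) if fractions else 1.0
    return InferredClones(pd.DataFrame(rows), wt)


def _observed_distribution(table: CloneTable) -> dict[frozenset, float]:
    """Clone frequencies keyed by carried-variant set (dosage >= 1)."""
    out: dict[frozenset, float] = {}
    for key, row in table.table.iterrows():
        g = tuple(key) if isinstance(key, tuple) else (key,)
        variants = frozenset(
            sid for sid, dose in zip(table.site_ids, g) if dose >= 1
        )
        out[variants] = out.get(variants, 0.0) + float(row["frequency"])
    return out


def total_variation_distance(
    p: Mapping[frozenset, float], q: Mapping[frozenset, float]
) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


@dataclass
class DiscordanceReport:
    """Disagreement between bulk-inferred and single-cell clone distributions."""

    per_clone: pd.DataFrame  # variants, inferred, observed, difference
    unpredicted: list[tuple[frozenset, float]]  # observed but absent from inference
    unobserved: list[tuple[frozenset, float]]   # inferred but not observed
    tvd: float


def compare_bulk_vs_singlecell(
    inferred: InferredClones, observed: CloneTable
) -> DiscordanceReport:
    """Quantify how the bulk-inferred architecture differs from single-cell.

    Clones are matched by carried-variant set (single-cell genotypes
    collapse dosage to mutation presence, so a het and hom-alt carrier of
    the same variants compare as one clone).  Reports per-clone fractions,
    clones each side misses, and the total variation distance.
    """
    p = inferred.distribution()
    q = _observed_distribution(observed)
    keys = sorted(set(p) | set(q), key=lambda k: (len(k), sorted(k)))
    per_clone = pd.DataFrame(
        {
            "variants": ["+".join(sorted(k)) if k else "WT" for k in keys],
            "inferred": [p.get(k, 0.0) for k in keys],
            "observed": [q.get(k, 0.0) for k in keys],
        }
    )
    per_clone["difference"] = per_clone["observed"] - per_clone["inferred"]
    unpredicted = sorted(
        ((k, q[k]) for k in q if p.get(k, 0.0) == 0.0 and q[k] > 0),
        key=lambda kv: -kv[1],
    )
    unobserved = sorted(
        ((k, p[k]) for k in p if q.get(k, 0.0) == 0.0 and p[k] > 0),
        key=lambda kv: -kv[1],
    )
    return DiscordanceReport(per_clone, unpredicted, unobserved,
                             total_variation_distance(p, q))
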