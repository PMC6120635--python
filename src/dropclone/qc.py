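"""Run-level quality metrics: spike-in detection, allele dropout, multiplets.

Control cells (an immortalized line heterozygous at known SNVs) are mixed
into each sample at a low proportion.  Detecting them measures cell-type
identification; the fraction of control cells miscalled homozygous at the
known het loci measures allele dropout (ADO); a two-line mixing design
measures the multiplet rate after correcting for unobservable same-line
collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype import GenotypeMatrix

#: spike-in signature match modes
ALT_ANY = "alt_any"        # alt allele present (het or hom-alt) at >=1 control site
STRICT_HET = "strict_het"  # every non-missing control site called het


def detect_spikein(
    genotypes: GenotypeMatrix,
    control_site_ids: Sequence[str],
    mode: str = ALT_ANY,
) -> tuple[list[str], float]:
    """Identify spike-in control cells by their control-SNV signature.

    The default ``alt_any`` rule calls a cell spike-in when the alt allele
    is observed (call 1 or 2) at one or more control sites: control SNVs
    are private to the control line, and a dropout-affected control cell
    must still be identifiable for the same cells to support the ADO
    estimate downstream.  ``strict_het`` additionally demands every
    non-missing control call be het (and at least one non-missing).
    Returns (spike-in cells, fraction of all cells).
    """
    calls = genotypes.calls[list(control_site_ids)]
    vals = calls.to_numpy(dtype=float)
    if mode == ALT_ANY:
        hit = np.nansum(vals >= 1, axis=1) >= 1
    elif mode == STRICT_HET:
        nonmissing = ~np.isnan(vals)
        het = vals == 1.0
        hit = nonmissing.any(axis=1) & (het | ~nonmissing).all(axis=1)
    else:
        raise ValueError(f"unknown spike-in match mode {mode!r}")
    spike = list(calls.index[hit])
    fraction = len(spike) / len(calls) if len(calls) else float("nan")
    return spike, fraction


@dataclass
class ADOEstimate:
    """Allele-dropout rates from known heterozygous control loci.

    ``per_locus`` maps each control site to the fraction of spike-in cells
    with a non-missing call that were called homozygous there; ``mean`` is
    the unweighted arithmetic mean across loci.  ``undefined`` flags the
    degenerate case of no evaluable spike-in call at any locus.
    """

    per_locus: dict[str, float]
    mean: float
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # (hom, nonmissing)
    undefined: bool = False


def estimate_ado(
    genotypes: GenotypeMatrix,
    spikein_cells: Sequence[str],
    control_site_ids: Sequence[str],
) -> ADOEstimate:
    """Estimate the locus-level ADO rate from spike-in control cells.

    Per locus: (# spike-in cells called hom-ref or hom-alt) / (# spike-in
    cells with a non-missing call); missing calls are excluded from both
    numerator and denominator.  Loci are averaged with equal weight.
    """
    if not control_site_ids:
        raise ValueError("estimate_ado needs at least one control locus")
    calls = genotypes.calls.loc[list(spikein_cells), list(control_site_ids)]
    per_locus: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for sid in control_site_ids:
        col = calls[sid].to_numpy(dtype=float)
        nonmissing = ~np.isnan(col)
        n = int(nonmissing.sum())
        hom = int(np.isin(col[nonmissing], (0.0, 2.0)).sum())
        counts[sid] = (hom, n)
        per_locus[sid] = hom / n if n else float("nan")
    rates = [r for r in per_locus.values() if not np.isnan(r)]
    if not rates:
        return ADOEstimate(per_locus, float("nan"), counts, undefined=True)
    return ADOEstimate(per_locus, float(np.mean(rates)), counts)


@dataclass
class MultipletEstimate:
    """Two-line mixing result: observed mixed fraction and corrected rate."""

    rate: float
    mixed_fraction: float
    p_a: float
    p_b: float
    n_a: int
    n_b: int
    n_mixed: int


def estimate_multiplets(
    genotypes: GenotypeMatrix,
    signature_a: Sequence[str],
    signature_b: Sequence[str],
) -> MultipletEstimate:
    """Multiplet rate from a two-cell-line mixing design.

    Each line carries private het SNVs (``signature_a`` / ``signature_b``
    site ids).  Barcodes showing alt alleles from both signatures are
    mixed; the observed mixed fraction m underestimates collisions between
    cells of the same line, so the rate is m / (2 p_a p_b) with p_a, p_b
    the line proportions among single-line barcodes.
    """
    vals = genotypes.calls
    a_hit = (vals[list(signature_a)].to_numpy(dtype=float) >= 1).any(axis=1)
    b_hit = (vals[list(signature_b)].to_numpy(dtype=float) >= 1).any(axis=1)
    n_mixed = int((a_hit & b_hit).sum())
    n_a = int((a_hit & ~b_hit).sum())
    n_b = int((b_hit & ~a_hit).sum())
    classified = n_a + n_b + n_mixed
    if classified == 0:
        return MultipletEstimate(float("nan"), float("nan"), float("nan"),
                                 float("nan"), 0, 0, 0)
    m = n_mixed / classified
    single = n_a + n_b
    p_a = n_a / single if single else 0.5
    p_b = 1.0 - p_a
    if n_mixed == 0:
        rate = 0.0
    else:
        rate = m / (2 * p_a * p_b) if p_a and p_b else float("nan")
    return MultipletEstimate(rate, m, p_a, p_b, n_a, n_b, n_mixed)


@dataclass
class RunMetrics:
    """Key per-run metrics, mirroring a run-summary table."""

    total_reads: int
    assignment_fraction: float
    total_cells_found: int
    genotyped_cells: int
    spikein_fraction: float
    ado: ADOEstimate | None = None

    def __post_init__(self) -> None:
        if self.genotyped_cells > self.total_cells_found:
            raise ValueError("genotyped cells cannot exceed total cells found")
        for name in ("assignment_fraction", "spikein_fraction"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        """Flat key-value form for JSON output (percentages in %)."""
        out = {
            "total_reads": self.total_reads,
            "assignment_fraction_pct": round(100 * self.assignment_fraction, 4),
            "total_cells_found": self.total_cells_found,
            "genotyped_cells": self.genotyped_cells,
            "spikein_detection_rate_pct": round(100 * self.spikein_fraction, 4),
        }
        if self.ado is not None and not self.ado.undefined:
            out["allele_dropout_rate_pct"] = round(100 * self.ado.mean, 4)
            for sid, r in self.ado.per_locus.items():
                out[f"allele_dropout_rate_pct.{sid}"] = round(100 * r, 4)
        return out
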