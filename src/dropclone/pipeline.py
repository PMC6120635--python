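"""In-memory orchestration of the count-level analysis chain.

Mirrors the CLI stages (cells -> genotype -> qc -> clones) for callers
that already hold a count matrix and allele depths, e.g. simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import cellcall, clones, qc
from .barcodes import CellCountMatrix
from .genotype import (
    DEFAULT_HET_BAND,
    DEFAULT_MIN_DEPTH,
    AlleleCounts,
    GenotypeMatrix,
    call_genotype_matrix,
)
from .panel import AmpliconPanel


@dataclass
class RunAnalysis:
    """Everything the per-run analysis produces."""

    calls: cellcall.CellCalls
    genotyped_cells: list[str]
    genotypes: GenotypeMatrix
    spikein_cells: list[str]
    spikein_fraction: float
    ado: qc.ADOEstimate
    clone_table: clones.CloneTable

    def metrics(self, total_reads: int = 0,
                assignment_fraction: float = float("nan")) -> qc.RunMetrics:
        return qc.RunMetrics(
            total_reads=total_reads,
            assignment_fraction=assignment_fraction,
            total_cells_found=self.calls.n_cells,
            genotyped_cells=len(self.genotyped_cells),
            spikein_fraction=self.spikein_fraction,
            ado=self.ado,
        )


def analyze_count_run(
    matrix: CellCountMatrix,
    allele_counts: AlleleCounts,
    panel: AmpliconPanel,
    min_reads_floor: int = cellcall.DEFAULT_MIN_READS_FLOOR,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
    spikein_mode: str = qc.ALT_ANY,
) -> RunAnalysis:
    """Cell calling, genotyping, spike-in/ADO QC, and clone enumeration."""
    calls = cellcall.call_cells(matrix, min_reads_floor)
    site_ids = [s.id for s in panel.variant_sites]
    genotyped = cellcall.genotypeable_subset(
        calls.cells, allele_counts, site_ids, min_depth
    )
    gm = call_genotype_matrix(allele_counts.restrict(genotyped), min_depth, het_band)
    control = [s.id for s in panel.control_sites]
    spike, frac = qc.detect_spikein(gm, control, spikein_mode)
    ado = qc.estimate_ado(gm, spike, control)
    analysis = [s.id for s in panel.analysis_sites]
    table = clones.enumerate_clones(gm, analysis, spike)
    return RunAnalysis(calls, genotyped, gm, spike, frac, ado, table)
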