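"""Reference simulation scenarios for AML-style longitudinal runs.

These presets encode the study conditions the simulator emulates: two
heterozygous TP53 control SNVs in a ~2.4% (patient-1-style) or ~1.5%
(patient-2-style) spike-in of control cells, locus-level allele dropout
of 7-9%, thousands of cells per run over a long background-barcode tail,
and clonal structures dominated by a triple-mutant population.  The
patient-1 panel carries a germline homozygous ASXL1 polymorphism in every
tumour clone (present in all cells, so it never splits clones and is
excluded from bulk clonal inference).
"""

from __future__ import annotations

from .panel import AmpliconPanel, BarcodeWhitelist, example_panel, random_whitelist
from .simdata import SimConfig, ado_prob_from_locus_rate

#: patient-1-style run conditions (three longitudinal runs)
P1_SPIKEIN_FRACTION = 0.024
P1_ADO_LOCUS_RATE = 0.07
P1_CELLS_PER_RUN = 4500
P1_GENOTYPED_PER_RUN = 4456

#: patient-2-style run conditions (diagnosis + relapse)
P2_SPIKEIN_FRACTION = 0.015
P2_ADO_DIAGNOSIS = 0.08
P2_ADO_RELAPSE = 0.09
P2_ADO_MEAN = 0.085
P2_CELLS_PER_RUN = 1500

#: patient-2 relapse clonal structure: dominant triple mutant, shrunken
#: double- and single-mutant populations, wild-type remainder
P2_RELAPSE_TRIPLE_FRACTION = 0.64
P2_RELAPSE_CLONES = [
    ({}, 0.26),
    ({"IDH2_R140Q": 1}, 0.02),
    ({"IDH2_R140Q": 1, "NRAS_G13R": 1}, 0.08),
    ({"IDH2_R140Q": 1, "NRAS_G13R": 1, "ASXL1_G646fs": 1},
     P2_RELAPSE_TRIPLE_FRACTION),
]

#: patient-1 clonal structure: TP53 -> +DNMT3A -> +FLT3/ITD serial chain,
#: ASXL1 polymorphism homozygous in every patient cell
P1_CLONES = [
    ({"ASXL1_L815P": 2}, 0.30),
    ({"TP53_H47R": 1, "ASXL1_L815P": 2}, 0.08),
    ({"TP53_H47R": 1, "DNMT3A_R899C": 1, "ASXL1_L815P": 2}, 0.08),
    ({"TP53_H47R": 1, "DNMT3A_R899C": 1, "FLT3_ITD": 1, "ASXL1_L815P": 2}, 0.54),
]

#: rank-curve conditions: tight cell plateau over a long background tail
RANK_CELL_MEAN = 2000.0
RANK_CELL_DISPERSION = 200.0
RANK_BACKGROUND_MEAN = 20.0
RANK_N_BACKGROUND = 50_000


def shared_whitelist(seed: int = 3, size: int = 20_000) -> BarcodeWhitelist:
    return random_whitelist(size, seed=seed)


def patient1_config(
    seed: int,
    panel: AmpliconPanel | None = None,
    whitelist: BarcodeWhitelist | None = None,
    n_cells: int = P1_CELLS_PER_RUN,
    depth_per_site: float = 50.0,
    n_background: int = 10_000,
) -> SimConfig:
    """One patient-1-style run: 2.4% spike-in, 7% locus-level dropout."""
    panel = panel or example_panel(n_amplicons=8, patient=1)
    return SimConfig(
        n_cells=n_cells,
        clone_spec=P1_CLONES,
        panel=panel,
        spikein_fraction=P1_SPIKEIN_FRACTION,
        ado_prob=ado_prob_from_locus_rate(P1_ADO_LOCUS_RATE),
        doublet_rate=0.03,
        n_background_barcodes=n_background,
        reads_per_cell_mean=depth_per_site * len(panel.amplicons),
        background_reads_mean=20.0,
        seq_error_rate=0.001,
        whitelist=whitelist or shared_whitelist(),
        rng_seed=seed,
    )


def patient2_config(
    seed: int,
    ado_locus_rate: float = P2_ADO_MEAN,
    panel: AmpliconPanel | None = None,
    whitelist: BarcodeWhitelist | None = None,
    n_cells: int = P2_CELLS_PER_RUN,
    depth_per_site: float = 50.0,
    n_background: int = 5_000,
) -> SimConfig:
    """One patient-2-style run (relapse structure by default)."""
    panel = panel or example_panel(n_amplicons=8, patient=2)
    return SimConfig(
        n_cells=n_cells,
        clone_spec=P2_RELAPSE_CLONES,
        panel=panel,
        spikein_fraction=P2_SPIKEIN_FRACTION,
        ado_prob=ado_prob_from_locus_rate(ado_locus_rate),
        doublet_rate=0.03,
        n_background_barcodes=n_background,
        reads_per_cell_mean=depth_per_site * len(panel.amplicons),
        background_reads_mean=20.0,
        seq_error_rate=0.001,
        whitelist=whitelist or shared_whitelist(),
        rng_seed=seed,
    )


def rank_curve_config(
    seed: int,
    n_cells: int = P1_GENOTYPED_PER_RUN,
    panel: AmpliconPanel | None = None,
    whitelist: BarcodeWhitelist | None = None,
) -> SimConfig:
    """Two-population rank curve: ``n_cells`` true cells over 50k background."""
    panel = panel or example_panel(n_amplicons=8, patient=1)
    return SimConfig(
        n_cells=n_cells,
        clone_spec=[({}, 1.0)],
        panel=panel,
        spikein_fraction=0.0,
        ado_prob=0.0,
        doublet_rate=0.0,
        n_background_barcodes=RANK_N_BACKGROUND,
        reads_per_cell_mean=RANK_CELL_MEAN,
        reads_per_cell_dispersion=RANK_CELL_DISPERSION,
        background_reads_mean=RANK_BACKGROUND_MEAN,
        whitelist=whitelist or shared_whitelist(),
        rng_seed=seed,
    )
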