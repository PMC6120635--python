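"""Generative-model checks: degenerate configs, binomial oracles, read structure."""

import math

import numpy as np
import pytest

import dropclone as dc
from dropclone.simdata import locus_rate_from_ado_prob


def _one_clone_config(panel, whitelist, **kw):
    defaults = dict(
        n_cells=200,
        clone_spec=[({}, 1.0)],
        panel=panel,
        spikein_fraction=0.0,
        ado_prob=0.0,
        doublet_rate=0.0,
        n_background_barcodes=0,
        reads_per_cell_mean=300.0,
        seq_error_rate=0.0,
        barcode_error_rate=0.0,
        whitelist=whitelist,
        rng_seed=5,
    )
    defaults.update(kw)
    return dc.SimConfig(**defaults)


def test_degenerate_config_gives_identical_cells(panel_p1, whitelist):
    """No dropout/doublets/spike-in and one clone: uniform truth, no dropout events."""
    cfg = _one_clone_config(
        panel_p1, whitelist, clone_spec=[({"TP53_H47R": 1}, 1.0)]
    )
    cells, truth = dc.simulate_cells(cfg)
    assert len(cells) == cfg.n_cells
    assert truth.genotypes.nunique().eq(1).all()
    assert (truth.genotypes["TP53_H47R"] == 1).all()
    assert truth.dropout_events().empty
    assert not cells["is_spikein"].any()
    assert not cells["is_doublet"].any()


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(n_cells=0), "n_cells"),
        (dict(spikein_fraction=1.5), "spikein_fraction"),
        (dict(ado_prob=-0.1), "ado_prob"),
        (dict(doublet_rate=2.0), "doublet_rate"),
        (dict(reads_per_cell_mean=0.0), "reads_per_cell_mean"),
        (dict(n_background_barcodes=-1), "n_background_barcodes"),
        (dict(clone_spec=[({}, 0.5)]), "clone_spec"),
        (dict(clone_spec=[({"nope": 1}, 1.0)]), "nope"),
    ],
)
def test_invalid_config_names_offending_field(panel_p1, whitelist, kwargs, field):
    base = dict(
        n_cells=10, clone_spec=[({}, 1.0)], panel=panel_p1, whitelist=whitelist
    )
    base.update(kwargs)
    with pytest.raises(ValueError, match=field):
        dc.SimConfig(**base)


def test_spikein_count_within_binomial_band(panel_p1, whitelist):
    """Binomial(5000, 0.01): spike-in count within 3 sigma of 50."""
    cfg = _one_clone_config(
        panel_p1, whitelist, n_cells=5000, spikein_fraction=0.01, rng_seed=42
    )
    cells, _ = dc.simulate_cells(cfg)
    n, p = 5000, 0.01
    sigma = math.sqrt(n * p * (1 - p))
    assert abs(cells["is_spikein"].sum() - n * p) <= 3 * sigma


def test_het_locus_rendered_hom_at_closed_form_rate(panel_p1, whitelist):
    """Per-allele dropout p makes a het locus hom at rate 2p(1-p)+p^2."""
    p = 0.035
    cfg = _one_clone_config(
        panel_p1,
        whitelist,
        n_cells=4000,
        clone_spec=[({"TP53_H47R": 1}, 1.0)],
        ado_prob=p,
        rng_seed=9,
    )
    run = dc.simulate_count_run(cfg)
    gm = dc.call_genotype_matrix(run.allele_counts)
    calls = gm.calls["TP53_H47R"].dropna()
    hom_rate = float(np.isin(calls, (0.0, 2.0)).mean())
    expected = 2 * p * (1 - p) + p**2
    assert expected == pytest.approx(0.069, abs=1e-3)
    sigma = math.sqrt(expected * (1 - expected) / len(calls))
    assert abs(hom_rate - expected) <= 3 * sigma
    assert locus_rate_from_ado_prob(dc.ado_prob_from_locus_rate(0.07)) == pytest.approx(0.07)


def test_het_alt_depth_binomial_half(panel_p1, whitelist):
    """Without dropout or error, het alt depth is Binomial(depth, 1/2)."""
    cfg = _one_clone_config(
        panel_p1, whitelist, n_cells=1000,
        clone_spec=[({"DNMT3A_R899C": 1}, 1.0)], rng_seed=17,
    )
    run = dc.simulate_count_run(cfg)
    alt = run.allele_counts.alt["DNMT3A_R899C"].to_numpy(dtype=float)
    depth = run.allele_counts.depth["DNMT3A_R899C"].to_numpy(dtype=float)
    frac = alt.sum() / depth.sum()
    sigma = math.sqrt(0.25 / depth.sum())
    assert abs(frac - 0.5) <= 3 * sigma


def test_hom_ref_cells_emit_zero_alt_without_error(panel_p1, whitelist):
    cfg = _one_clone_config(panel_p1, whitelist, rng_seed=2)
    run = dc.simulate_count_run(cfg)
    assert int(run.allele_counts.alt.to_numpy().sum()) == 0


def test_pseudobulk_matches_dosage_closed_form(panel_p2, whitelist):
    """With ado=0 and error=0, site VAF converges to sum(frac * dosage / 2)."""
    spec = [
        ({"IDH2_R140Q": 1}, 0.5),
        ({"IDH2_R140Q": 2, "NRAS_G13R": 1}, 0.2),
        ({}, 0.3),
    ]
    cfg = _one_clone_config(
        panel_p2, whitelist, n_cells=3000, clone_spec=spec, rng_seed=21
    )
    run = dc.simulate_count_run(cfg)
    bulk = dc.pseudobulk_vaf(run.allele_counts)
    for site, expected in [("IDH2_R140Q", 0.5 * 0.5 + 0.2 * 1.0), ("NRAS_G13R", 0.1)]:
        depth = bulk.loc[site, "ref_depth"] + bulk.loc[site, "alt_depth"]
        sigma = math.sqrt(expected * (1 - expected) / depth)
        # cell-to-cell clone sampling adds variance beyond the read binomial
        assert bulk.loc[site, "vaf"] == pytest.approx(expected, abs=max(6 * sigma, 0.01))


def test_emit_reads_structure_and_conservation(panel_p1, whitelist, tmp_path):
    """Clean reads start with the true barcode; pair counts match truth."""
    cfg = _one_clone_config(
        panel_p1, whitelist, n_cells=20, reads_per_cell_mean=40.0, rng_seed=8
    )
    cells, truth = dc.simulate_cells(cfg)
    f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    reads = dc.emit_reads(cells, truth, cfg, f1, f2)
    n_lines = f1.read_text().count("\n")
    assert n_lines == 4 * len(reads)  # conservation: every truth read written once
    barcodes = set(cells["barcode"])
    from dropclone.io import read_fastq_pairs

    for _, seq1, seq2 in read_fastq_pairs(f1, f2):
        assert seq1[: whitelist.length] in barcodes
    # per-barcode totals match the truth table
    by_bc = reads.groupby("barcode").size()
    assert int(by_bc.sum()) == len(reads)


def test_itd_read_contains_tandem_duplicated_block(panel_p1, whitelist, tmp_path):
    """An ITD allele lengthens the insert by 21 bp and repeats the block in tandem."""
    cfg = _one_clone_config(
        panel_p1,
        whitelist,
        n_cells=5,
        clone_spec=[({"FLT3_ITD": 2}, 1.0)],
        reads_per_cell_mean=60.0,
        rng_seed=4,
    )
    cells, truth = dc.simulate_cells(cfg)
    site = panel_p1.site_by_id["FLT3_ITD"]
    ref_insert = panel_p1.by_name["FLT3_1"].insert
    mutant = panel_p1.mutant_insert(site)
    assert len(mutant) == len(ref_insert) + 21
    block = ref_insert[site.offset : site.offset + 21]
    assert mutant.count(block) >= 2
    present, dup = dc.find_tandem_duplication(mutant, ref_insert, min_dup_len=10)
    assert present and dup == 21


def test_identical_seeds_reproduce_identical_output(panel_p1, whitelist, tmp_path):
    cfg = _one_clone_config(panel_p1, whitelist, n_cells=50, rng_seed=33)
    run_a = dc.simulate_count_run(cfg)
    run_b = dc.simulate_count_run(cfg)
    assert run_a.matrix.counts.equals(run_b.matrix.counts)
    assert run_a.allele_counts.alt.equals(run_b.allele_counts.alt)
    cells, truth = dc.simulate_cells(cfg)
    for sub in ("x", "y"):
        d = tmp_path / sub
        d.mkdir()
        dc.emit_reads(cells, truth, cfg, d / "r1.fastq", d / "r2.fastq")
    assert (tmp_path / "x" / "r1.fastq").read_bytes() == (
        tmp_path / "y" / "r1.fastq"
    ).read_bytes()


def test_doublet_barcode_hosts_two_truth_cells(panel_p1, whitelist):
    cfg = _one_clone_config(
        panel_p1, whitelist, n_cells=2000, doublet_rate=0.2, rng_seed=6
    )
    cells, truth = dc.simulate_cells(cfg)
    assert len(cells) == 2000
    sizes = cells.groupby("barcode").size()
    assert set(sizes.unique()) <= {1, 2}
    doublet_bcs = set(sizes[sizes == 2].index)
    flagged = set(cells.loc[cells["is_doublet"], "barcode"])
    assert doublet_bcs == flagged
    # rate within 3 sigma of configured value
    n_pairs = (sizes == 2).sum()
    p = 0.2
    sigma = np.sqrt(len(sizes) * p * (1 - p))
    assert abs(n_pairs - p * len(sizes)) <= 3 * sigma
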