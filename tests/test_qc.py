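"""Spike-in detection, ADO estimation, and multiplet-rate recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import dropclone as dc
from dropclone.qc import STRICT_HET


def _gm(rows: dict[str, list[float]], sites: list[str]) -> dc.GenotypeMatrix:
    return dc.GenotypeMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=sites)
    )


CTRL = ["ctrlA", "ctrlB"]


def test_het_at_controls_is_spikein_homref_is_not():
    gm = _gm({"raji": [1, 1], "tumor": [0, 0], "half": [1, 0]}, CTRL)
    spike, frac = dc.detect_spikein(gm, CTRL)
    assert "raji" in spike and "tumor" not in spike
    assert "half" in spike  # dropout at one locus must not hide a control cell
    assert frac == pytest.approx(2 / 3)
    strict, _ = dc.detect_spikein(gm, CTRL, mode=STRICT_HET)
    assert strict == ["raji"]


def test_ado_direct_count_example():
    """20 spike-ins; locus A: 2 hom calls, locus B: 0 -> 10% and 0%, mean 5%."""
    rows = {f"s{i}": [1.0, 1.0] for i in range(20)}
    rows["s0"][0] = 0.0
    rows["s1"][0] = 2.0
    gm = _gm(rows, CTRL)
    est = dc.estimate_ado(gm, list(rows), CTRL)
    assert est.per_locus["ctrlA"] == pytest.approx(0.10)
    assert est.per_locus["ctrlB"] == pytest.approx(0.0)
    assert est.mean == pytest.approx(0.05)
    assert est.counts["ctrlA"] == (2, 20)


def test_missing_calls_excluded_from_both_sides():
    rows = {"a": [1.0, float("nan")], "b": [0.0, float("nan")]}
    est = dc.estimate_ado(_gm(rows, CTRL), ["a", "b"], CTRL)
    assert est.per_locus["ctrlA"] == pytest.approx(0.5)
    assert math.isnan(est.per_locus["ctrlB"])
    assert est.mean == pytest.approx(0.5)  # only the evaluable locus contributes


def test_no_evaluable_spikein_flagged_undefined():
    rows = {"a": [float("nan"), float("nan")]}
    est = dc.estimate_ado(_gm(rows, CTRL), ["a"], CTRL)
    assert est.undefined


def test_zero_ado_simulation_estimates_exactly_zero(panel_p1, whitelist):
    cfg = dc.SimConfig(
        n_cells=800,
        clone_spec=[({}, 1.0)],
        panel=panel_p1,
        spikein_fraction=0.05,
        ado_prob=0.0,
        doublet_rate=0.0,
        n_background_barcodes=0,
        reads_per_cell_mean=400.0,
        seq_error_rate=0.0,
        whitelist=whitelist,
        rng_seed=31,
    )
    run = dc.simulate_count_run(cfg)
    gm = dc.call_genotype_matrix(run.allele_counts)
    ctrl = [s.id for s in panel_p1.control_sites]
    spike, _ = dc.detect_spikein(gm, ctrl)
    assert dc.estimate_ado(gm, spike, ctrl).mean == 0.0


def test_ado_estimator_tracks_generative_rate(panel_p1, whitelist):
    """Spike-in-rich runs: mean estimate within 3 sigma of the locus rate."""
    r = 0.07
    hom_calls, n_obs = 0, 0
    for seed in range(20):
        cfg = dc.SimConfig(
            n_cells=2000,
            clone_spec=[({}, 1.0)],
            panel=panel_p1,
            spikein_fraction=0.5,
            ado_prob=dc.ado_prob_from_locus_rate(r),
            doublet_rate=0.0,
            n_background_barcodes=0,
            reads_per_cell_mean=400.0,
            whitelist=whitelist,
            rng_seed=200 + seed,
        )
        run = dc.simulate_count_run(cfg)
        gm = dc.call_genotype_matrix(run.allele_counts)
        ctrl = [s.id for s in panel_p1.control_sites]
        spike, _ = dc.detect_spikein(gm, ctrl)
        est = dc.estimate_ado(gm, spike, ctrl)
        for sid in ctrl:
            hom, n = est.counts[sid]
            hom_calls += hom
            n_obs += n
    pooled = hom_calls / n_obs
    sigma = math.sqrt(r * (1 - r) / n_obs)
    assert abs(pooled - r) <= 3 * sigma


def test_multiplet_collision_arithmetic():
    """50:50 mix with 5% mixed barcodes -> corrected rate 10%."""
    sites = ["a1", "b1"]
    rows = {}
    for i in range(475):
        rows[f"A{i}"] = [1.0, 0.0]
        rows[f"B{i}"] = [0.0, 1.0]
    for i in range(50):
        rows[f"M{i}"] = [1.0, 1.0]
    est = dc.estimate_multiplets(_gm(rows, sites), ["a1"], ["b1"])
    assert est.mixed_fraction == pytest.approx(0.05)
    assert est.rate == pytest.approx(0.10)
    none = dc.estimate_multiplets(_gm({"A": [1.0, 0.0]}, sites), ["a1"], ["b1"])
    assert none.n_mixed == 0 and none.rate == 0.0


def test_multiplet_rate_recovered_from_simulation(panel_p2, whitelist):
    """Two-line design at doublet_rate 0.04: recovery within 3 sigma.

    Mixed barcodes carry each line's het SNV at allele fraction ~0.25, so
    the mixing experiment needs depth well above the routine 50x for the
    het band's lower edge (0.2) not to swallow doublets.
    """
    d = 0.04
    spec = [({"IDH2_R140Q": 1}, 0.5), ({"NRAS_G13R": 1}, 0.5)]
    n_mixed, n_class = 0, 0
    rates = []
    for seed in (41, 42, 43):
        cfg = dc.SimConfig(
            n_cells=4000,
            clone_spec=spec,
            panel=panel_p2,
            spikein_fraction=0.0,
            ado_prob=0.0,
            doublet_rate=d,
            n_background_barcodes=0,
            reads_per_cell_mean=3200.0,
            reads_per_cell_dispersion=50.0,
            seq_error_rate=0.0,
            whitelist=whitelist,
            rng_seed=seed,
        )
        run = dc.simulate_count_run(cfg)
        gm = dc.call_genotype_matrix(run.allele_counts)
        est = dc.estimate_multiplets(gm, ["IDH2_R140Q"], ["NRAS_G13R"])
        rates.append(est.rate)
        n_mixed += est.n_mixed
        n_class += est.n_a + est.n_b + est.n_mixed
    # expected mixed fraction is d/2 (A+B pairs among barcodes) within binomial noise
    sigma_rate = 2 * math.sqrt((d / 2) * (1 - d / 2) / n_class)
    assert abs(float(np.mean(rates)) - d) <= 3 * sigma_rate + 0.005


def test_metrics_invariant_to_cell_order(panel_p1, whitelist):
    cfg = dc.SimConfig(
        n_cells=500,
        clone_spec=[({"TP53_H47R": 1}, 0.5), ({}, 0.5)],
        panel=panel_p1,
        spikein_fraction=0.05,
        n_background_barcodes=0,
        reads_per_cell_mean=400.0,
        whitelist=whitelist,
        rng_seed=51,
    )
    run = dc.simulate_count_run(cfg)
    gm = dc.call_genotype_matrix(run.allele_counts)
    shuffled = dc.GenotypeMatrix(gm.calls.sample(frac=1, random_state=1))
    ctrl = [s.id for s in panel_p1.control_sites]
    s1, f1 = dc.detect_spikein(gm, ctrl)
    s2, f2 = dc.detect_spikein(shuffled, ctrl)
    assert sorted(s1) == sorted(s2) and f1 == f2
    assert dc.estimate_ado(gm, s1, ctrl).mean == dc.estimate_ado(shuffled, s2, ctrl).mean


def test_run_metrics_validation():
    with pytest.raises(ValueError, match="genotyped"):
        dc.RunMetrics(100, 0.9, 10, 11, 0.01)
    m = dc.RunMetrics(100, 0.747, 4500, 4456, 0.024)
    d = m.to_dict()
    assert d["assignment_fraction_pct"] == pytest.approx(74.7)
    assert d["genotyped_cells"] == 4456
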