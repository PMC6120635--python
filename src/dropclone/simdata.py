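"""Synthetic droplet-run generator with ground truth.

Emulates a targeted single-cell DNA sequencing run on a bone-marrow
sample: a mixture of tumour clones (each a genotype vector over panel
variant sites), a small spike-in of control cells heterozygous at known
control SNVs, doublet barcodes hosting two cells, a long tail of low-count
background barcodes, per-allele amplification dropout, and sequencing
error.  Two output paths exist: ``emit_counts`` draws per-cell allele
depths directly (fast, used for large runs) and ``emit_reads`` writes
paired FASTQ with the full read structure (barcode + primer + insert).

Allele dropout is modelled per allele copy: each of a cell's two template
copies at a locus independently fails with probability ``ado_prob`` = p.
A heterozygous locus is then observed homozygous with probability
2p(1-p) + p^2 = 1 - (1-p)^2: when both copies fail, a single stray
template is resampled from the cell's own pre-dropout copies (uniform
over the two alleles of a het, always the cell's allele at a hom locus),
so the locus still yields a confident homozygous call rather than going
missing.  The locus-level miscall rate r relates to p via
p = 1 - sqrt(1 - r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import CellCountMatrix
from .genotype import AlleleCounts
from .panel import BASES, AmpliconPanel, BarcodeWhitelist, random_whitelist

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ado_prob_from_locus_rate(rate: float) -> float:
    """Per-allele dropout probability giving locus-level hom-miscall rate ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("locus-level rate must be in [0, 1)")
    return 1.0 - math.sqrt(1.0 - rate)


def locus_rate_from_ado_prob(p: float) -> float:
    """Locus-level het->hom miscall rate 2p(1-p) + p^2 for per-allele prob p."""
    return 1.0 - (1.0 - p) ** 2


def _validate_prob(name: str, value: float, *, open_top: bool = False) -> None:
    top_ok = value < 1 if open_top else value <= 1
    if not (0 <= value and top_ok):
        raise ValueError(f"{name} must be a probability, got {value}")


@dataclass
class SimConfig:
    """Generative parameters for one droplet run.

    ``clone_spec`` maps each clone to (genotype dict over analysis site
    ids -> dosage in {0,1,2}, population fraction); fractions must sum to
    one.  Spike-in cells are drawn independently with probability
    ``spikein_fraction`` and carry ``spikein_genotypes`` (default:
    heterozygous at every control site, reference elsewhere).
    """

    n_cells: int
    clone_spec: list[tuple[dict[str, int], float]]
    panel: AmpliconPanel
    spikein_fraction: float = 0.024
    spikein_genotypes: dict[str, int] | None = None
    ado_prob: float = ado_prob_from_locus_rate(0.07)
    doublet_rate: float = 0.03
    n_background_barcodes: int = 50_000
    reads_per_cell_mean: float = 2000.0
    reads_per_cell_dispersion: float = 10.0
    background_reads_mean: float = 20.0
    seq_error_rate: float = 0.001
    barcode_error_rate: float = 0.02
    whitelist: BarcodeWhitelist | None = None
    whitelist_size: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not self.clone_spec:
            raise ValueError("clone_spec must list at least one clone")
        total = sum(frac for _, frac in self.clone_spec)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone_spec fractions must sum to 1, got {total}")
        site_ids = set(s.id for s in self.panel.variant_sites)
        for genotype, frac in self.clone_spec:
            if not 0 <= frac <= 1:
                raise ValueError(f"clone_spec fraction out of range: {frac}")
            for sid, dose in genotype.items():
                if sid not in site_ids:
                    raise ValueError(f"clone_spec references unknown site {sid!r}")
                if dose not in (0, 1, 2):
                    raise ValueError(f"clone_spec dosage must be 0/1/2, got {dose}")
        _validate_prob("spikein_fraction", self.spikein_fraction)
        _validate_prob("ado_prob", self.ado_prob, open_top=True)
        _validate_prob("doublet_rate", self.doublet_rate)
        _validate_prob("seq_error_rate", self.seq_error_rate)
        _validate_prob("barcode_error_rate", self.barcode_error_rate)
        if self.n_background_barcodes < 0:
            raise ValueError("n_background_barcodes must be nonnegative")
        for name in ("reads_per_cell_mean", "reads_per_cell_dispersion",
                     "background_reads_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spikein_genotypes is not None:
            for sid, dose in self.spikein_genotypes.items():
                if sid not in site_ids:
                    raise ValueError(f"spikein_genotypes references unknown site {sid!r}")
                if dose not in (0, 1, 2):
                    raise ValueError(f"spikein_genotypes dosage must be 0/1/2")

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.panel.variant_sites]

    def spikein_vector(self) -> np.ndarray:
        geno = self.spikein_genotypes
        if geno is None:
            geno = {s.id: 1 for s in self.panel.control_sites}
        return np.array([geno.get(sid, 0) for sid in self.site_ids], dtype=np.int64)

    def clone_matrix(self) -> np.ndarray:
        """(n_clones, n_sites) dosage matrix in panel site order."""
        return np.array(
            [[g.get(sid, 0) for sid in self.site_ids] for g, _ in self.clone_spec],
            dtype=np.int64,
        )


@dataclass
class SimulationTruth:
    """Ground truth for one simulated run.

    ``cells`` has one row per truth cell (doublet partners share a
    barcode); ``genotypes`` the true dosage per cell and site;
    ``surviving_ref``/``surviving_alt`` the template copies left after
    dropout.  ``reads`` is populated by ``emit_reads``.
    """

    cells: pd.DataFrame  # cell_id, barcode, clone, is_spikein, is_doublet
    genotypes: pd.DataFrame  # index: cell_id, columns: site ids
    surviving_ref: np.ndarray  # (n_cells, n_sites)
    surviving_alt: np.ndarray
    seed: int
    reads: pd.DataFrame | None = None

    @property
    def site_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def dropout_events(self) -> pd.DataFrame:
        """Long-format record of allele copies lost to dropout."""
        geno = self.genotypes.to_numpy()
        lost_ref = (2 - geno) - self.surviving_ref
        lost_alt = geno - self.surviving_alt
        cell_idx, site_idx = np.nonzero((lost_ref > 0) | (lost_alt > 0))
        return pd.DataFrame(
            {
                "cell_id": self.genotypes.index.to_numpy()[cell_idx],
                "site": np.array(self.site_ids)[site_idx],
                "ref_copies_lost": lost_ref[cell_idx, site_idx],
                "alt_copies_lost": lost_alt[cell_idx, site_idx],
            }
        )

    def barcode_genotypes(self) -> pd.DataFrame:
        """True dosage per barcode (doublets: summed copies, capped at 2 per allele)."""
        g = self.genotypes.copy()
        g["barcode"] = self.cells.set_index("cell_id")["barcode"]
        return g.groupby("barcode").sum().clip(upper=2)


def simulate_cells(config: SimConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw the cell population and its post-dropout template copies.

    Returns ``(cells, truth)`` where ``cells`` is the truth cell table
    (clone identity, spike-in and doublet flags, barcode) — one row per
    cell, ``config.n_cells`` rows in total.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_cells
    site_ids = config.site_ids

    # clone / spike-in identity
    is_spike = rng.random(n) < config.spikein_fraction
    fractions = np.array([f for _, f in config.clone_spec])
    clone_idx = rng.choice(len(fractions), size=n, p=fractions / fractions.sum())
    clone_idx[is_spike] = -1
    genotype = config.clone_matrix()[np.where(is_spike, 0, clone_idx)]
    genotype[is_spike] = config.spikein_vector()

    # doublet layout: each barcode hosts two cells with prob doublet_rate
    pair_flags = rng.random(n) < config.doublet_rate
    barcode_of = np.empty(n, dtype=np.int64)
    is_doublet = np.zeros(n, dtype=bool)
    bc, i = 0, 0
    while i < n:
        if pair_flags[i] and i + 1 < n:
            barcode_of[i] = barcode_of[i + 1] = bc
            is_doublet[i] = is_doublet[i + 1] = True
            i += 2
        else:
            barcode_of[i] = bc
            i += 1
        bc += 1
    n_barcodes = bc

    whitelist = config.whitelist
    if whitelist is None:
        whitelist = random_whitelist(config.whitelist_size, seed=config.rng_seed + 1)
    pool = np.array(sorted(whitelist.barcodes))
    if n_barcodes > len(pool):
        raise ValueError("whitelist smaller than number of barcodes required")
    chosen = pool[rng.choice(len(pool), size=n_barcodes, replace=False)]
    barcodes = chosen[barcode_of]

    # per-allele dropout on every template copy
    ref_copies = 2 - genotype
    alt_copies = genotype
    keep = 1.0 - config.ado_prob
    surviving_ref = rng.binomial(ref_copies, keep)
    surviving_alt = rng.binomial(alt_copies, keep)

    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n)],
            "barcode": barcodes,
            "clone": clone_idx,
            "is_spikein": is_spike,
            "is_doublet": is_doublet,
        }
    )
    genotypes = pd.DataFrame(genotype, index=cells["cell_id"], columns=site_ids)
    truth = SimulationTruth(
        cells=cells,
        genotypes=genotypes,
        surviving_ref=surviving_ref,
        surviving_alt=surviving_alt,
        seed=config.rng_seed,
    )
    return cells, truth


def _negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (size) k; var = m + m^2/k."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _background_barcodes(
    rng: np.random.Generator, n: int, length: int, taken: set[str]
) -> list[str]:
    out: list[str] = []
    seen = set(taken)
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            bc = "".join(BASES[i] for i in row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _site_amplicon_index(panel: AmpliconPanel) -> np.ndarray:
    amp_order = {a.name: j for j, a in enumerate(panel.amplicons)}
    return np.array([amp_order[s.amplicon] for s in panel.variant_sites], dtype=np.int64)


def _pooled_templates(
    cells: pd.DataFrame, truth: SimulationTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surviving template copies pooled per barcode, with stray resampling.

    Doublet partners contribute to one pool.  Where dropout removed every
    copy at a locus, a single stray template is resampled from the
    barcode's own pre-dropout copies — a heterozygous locus then yields a
    confident homozygous call on either allele with equal probability,
    while a homozygous locus can only re-amplify its own allele.
    Returns (barcodes, effective_ref, effective_alt) in sorted barcode order.
    """
    bc = cells["barcode"].to_numpy()

    def pool(values: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(values, columns=truth.site_ids)
        df["barcode"] = bc
        return df.groupby("barcode", sort=True).sum()

    surv_ref = pool(truth.surviving_ref)
    surv_alt = pool(truth.surviving_alt)
    orig_geno = pool(truth.genotypes.to_numpy())
    barcodes = surv_ref.index.to_numpy()

    eff_ref = surv_ref.to_numpy(dtype=float)
    eff_alt = surv_alt.to_numpy(dtype=float)
    n_copies = 2.0 * np.asarray(
        cells.groupby("barcode", sort=True).size(), dtype=float
    )[:, None]
    empty = (eff_ref + eff_alt) == 0
    if empty.any():
        orig_alt_frac = orig_geno.to_numpy(dtype=float) / n_copies
        stray_is_alt = rng.random(int(empty.sum())) < orig_alt_frac[empty]
        eff_alt[empty] = stray_is_alt.astype(float)
        eff_ref[empty] = 1.0 - eff_alt[empty]
    return barcodes, eff_ref, eff_alt


def emit_counts(
    cells: pd.DataFrame, truth: SimulationTruth, config: SimConfig
) -> tuple[CellCountMatrix, AlleleCounts]:
    """Draw the barcode x amplicon count matrix and per-site allele depths.

    Site depth equals the read count of the site's amplicon (amplicons are
    short, every read covers its sites).  The alt-read fraction at a site
    is the alt share of the barcode's surviving template copies (summed
    over doublet partners); an empty pool resamples one stray template
    uniformly.  Sequencing error flips each read's allele with probability
    ``seq_error_rate``.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    panel = config.panel
    n_amp = len(panel.amplicons)
    amp_names = [a.name for a in panel.amplicons]
    site_amp = _site_amplicon_index(panel)

    # pool surviving template copies per barcode (stray-resampled when empty)
    cell_barcodes, ref_pool, alt_pool = _pooled_templates(cells, truth, rng)
    n_cells_bc = len(cell_barcodes)
    total_pool = ref_pool + alt_pool
    alt_frac = alt_pool / total_pool

    e = config.seq_error_rate
    f_eff = alt_frac * (1 - e) + (1 - alt_frac) * e

    totals = _negative_binomial(
        rng, config.reads_per_cell_mean, config.reads_per_cell_dispersion, n_cells_bc
    )
    amp_counts = rng.multinomial(totals, panel.weights)
    site_depth = amp_counts[:, site_amp]
    alt_depth = rng.binomial(site_depth, f_eff)
    ref_depth = site_depth - alt_depth

    # background barcodes: ambient, reference-only material
    n_bg = config.n_background_barcodes
    bg_codes = _background_barcodes(
        rng, n_bg, len(cell_barcodes[0]) if n_cells_bc else 18, set(cell_barcodes)
    )
    bg_totals = _negative_binomial(rng, config.background_reads_mean, 1.0, n_bg)
    bg_amp = rng.multinomial(bg_totals, panel.weights) if n_bg else np.zeros((0, n_amp), int)
    bg_site_depth = bg_amp[:, site_amp]
    bg_alt = rng.binomial(bg_site_depth, e)
    bg_ref = bg_site_depth - bg_alt

    all_codes = np.concatenate([cell_barcodes, np.array(bg_codes, dtype=object)])
    counts = pd.DataFrame(
        np.vstack([amp_counts, bg_amp]), index=all_codes, columns=amp_names
    )
    ref_df = pd.DataFrame(
        np.vstack([ref_depth, bg_ref]), index=all_codes, columns=truth.site_ids
    )
    alt_df = pd.DataFrame(
        np.vstack([alt_depth, bg_alt]), index=all_codes, columns=truth.site_ids
    )
    return CellCountMatrix(counts), AlleleCounts(ref_df, alt_df)


@dataclass
class SimRun:
    """Convenience bundle: one simulated run at count level."""

    config: SimConfig
    truth: SimulationTruth
    matrix: CellCountMatrix
    allele_counts: AlleleCounts


def simulate_count_run(config: SimConfig) -> SimRun:
    cells, truth = simulate_cells(config)
    matrix, allele_counts = emit_counts(cells, truth, config)
    return SimRun(config, truth, matrix, allele_counts)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def emit_reads(
    cells: pd.DataFrame,
    truth: SimulationTruth,
    config: SimConfig,
    fastq1: str | Path,
    fastq2: str | Path,
    read_length: int = 250,
) -> pd.DataFrame:
    """Write paired FASTQ for the run and return the per-read truth table.

    Read 1 = barcode + forward primer + insert prefix; read 2 = insert
    suffix, reverse-complemented.  Per-barcode read totals follow the same
    negative binomial as ``emit_counts``; reads sample amplicons by panel
    weight and alleles from the surviving template pool.  Substitution
    errors hit primer+insert bases at ``seq_error_rate``; the barcode
    receives one random substitution with probability
    ``barcode_error_rate``.  Intended for modest run sizes; large runs use
    ``emit_counts``.
    """
    rng = np.random.default_rng(config.rng_seed + 3)
    panel = config.panel
    amp_names = [a.name for a in panel.amplicons]
    weights = panel.weights
    sites_by_amp: dict[str, list[int]] = {name: [] for name in amp_names}
    for j, s in enumerate(panel.variant_sites):
        sites_by_amp[s.amplicon].append(j)
    site_list = panel.variant_sites

    by_bc: dict[str, list[int]] = {}
    for i, bc in enumerate(cells["barcode"]):
        by_bc.setdefault(bc, []).append(i)
    pooled_codes, eff_ref, eff_alt = _pooled_templates(cells, truth, rng)
    pool_row = {code: i for i, code in enumerate(pooled_codes)}

    records = []
    fastq1, fastq2 = Path(fastq1), Path(fastq2)
    read_no = 0
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:

        def write_pair(name: str, r1: str, r2: str) -> None:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")

        for bc in sorted(by_bc):
            row = pool_row[bc]
            total = int(
                _negative_binomial(
                    rng, config.reads_per_cell_mean, config.reads_per_cell_dispersion, 1
                )[0]
            )
            amp_draw = rng.multinomial(total, weights)
            for amp_j, n_reads in enumerate(amp_draw):
                amp = panel.amplicons[amp_j]
                for _ in range(int(n_reads)):
                    # allele per site from the barcode's surviving pool
                    insert = amp.insert
                    alleles = []
                    for sj in sites_by_amp[amp.name]:
                        pool = eff_ref[row, sj] + eff_alt[row, sj]
                        is_alt = rng.random() < eff_alt[row, sj] / pool
                        if is_alt:
                            insert = panel.mutant_insert(site_list[sj])
                            alleles.append(site_list[sj].id)
                    obs_bc = bc
                    if rng.random() < config.barcode_error_rate:
                        obs_bc = _substitute_one(rng, obs_bc)
                    payload = _mutate(
                        rng, amp.primer_fwd + insert, config.seq_error_rate
                    )
                    r1 = (obs_bc + payload)[:read_length]
                    r2 = revcomp(_mutate(rng, insert, config.seq_error_rate))[:read_length]
                    name = f"sim{read_no:08d}"
                    read_no += 1
                    write_pair(name, r1, r2)
                    records.append(
                        (name, bc, amp.name, ",".join(alleles) if alleles else "ref")
                    )

        # background barcodes: off-whitelist random sequences, reference reads
        bg_codes = _background_barcodes(
            rng, config.n_background_barcodes, len(bc) if by_bc else 18, set(by_bc)
        )
        bg_totals = _negative_binomial(
            rng, config.background_reads_mean, 1.0, len(bg_codes)
        )
        for bc, total in zip(bg_codes, bg_totals):
            amp_draw = rng.multinomial(int(total), weights)
            for amp_j, n_reads in enumerate(amp_draw):
                amp = panel.amplicons[amp_j]
                for _ in range(int(n_reads)):
                    payload = _mutate(rng, amp.primer_fwd + amp.insert, config.seq_error_rate)
                    r1 = (bc + payload)[:read_length]
                    r2 = revcomp(_mutate(rng, amp.insert, config.seq_error_rate))[:read_length]
                    name = f"sim{read_no:08d}"
                    read_no += 1
                    write_pair(name, r1, r2)
                    records.append((name, bc, amp.name, "background"))

    reads = pd.DataFrame(records, columns=["read_id", "barcode", "amplicon", "allele"])
    truth.reads = reads
    return reads


def _substitute_one(rng: np.random.Generator, seq: str) -> str:
    i = int(rng.integers(0, len(seq)))
    choices = [b for b in BASES if b != seq[i]]
    return seq[:i] + choices[rng.integers(0, 3)] + seq[i + 1 :]
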