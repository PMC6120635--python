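"""Per-cell genotype calling, variant discovery, and tandem-duplication detection.

Genotypes are alt-allele dosages: 0 (hom-ref), 1 (het), 2 (hom-alt), with
NaN for missing (insufficient depth).  Calling is a hard allele-fraction
threshold: with depth d = ref + alt >= ``min_depth`` and f = alt/d, the
call is 0 below the het band, 1 inside it, 2 above it.  Variant discovery
scores each site with a binomial log-likelihood ratio against a
sequencing-error-only model and sets the reporting threshold at the lowest
score among known control variants.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcodes import OK, ReadAssignment
from .panel import AmpliconPanel, VariantSite

MISSING = float("nan")
DEFAULT_HET_BAND = (0.2, 0.8)
DEFAULT_MIN_DEPTH = 10


@dataclass
class AlleleCounts:
    """Per-barcode, per-variant-site ref/alt read depths."""

    ref: pd.DataFrame  # index: barcode, columns: site ids
    alt: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ref.index.equals(self.alt.index) or not self.ref.columns.equals(
            self.alt.columns
        ):
            raise ValueError("ref and alt depth frames must be aligned")
        if (self.ref.to_numpy() < 0).any() or (self.alt.to_numpy() < 0).any():
            raise ValueError("negative depths")

    @property
    def depth(self) -> pd.DataFrame:
        return self.ref + self.alt

    @property
    def barcodes(self) -> list[str]:
        return list(self.ref.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.ref.columns)

    def restrict(self, barcodes: Sequence[str]) -> "AlleleCounts":
        return AlleleCounts(self.ref.loc[list(barcodes)], self.alt.loc[list(barcodes)])


@dataclass
class GenotypeMatrix:
    """Called cells x variant sites; values in {0, 1, 2, NaN=missing}."""

    calls: pd.DataFrame  # float dtype; NaN marks missing

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")

    @property
    def cells(self) -> list[str]:
        return list(self.calls.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.calls.columns)

    def restrict(self, cells: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(cells)])


def call_genotype(
    ref_depth: int,
    alt_depth: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> float:
    """Call one site in one cell; returns 0.0/1.0/2.0 or NaN (missing)."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be nonnegative")
    depth = ref_depth + alt_depth
    if depth < min_depth:
        return MISSING
    lo, hi = het_band
    f = alt_depth / depth
    if f < lo:
        return 0.0
    if f > hi:
        return 2.0
    return 1.0


def call_genotype_matrix(
    counts: AlleleCounts,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> GenotypeMatrix:
    """Vectorised allele-fraction caller over all cells and sites."""
    ref = counts.ref.to_numpy(dtype=float)
    alt = counts.alt.to_numpy(dtype=float)
    depth = ref + alt
    lo, hi = het_band
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    calls = np.full(ref.shape, 1.0)
    calls[f < lo] = 0.0
    calls[f > hi] = 2.0
    calls[depth < min_depth] = np.nan
    return GenotypeMatrix(
        pd.DataFrame(calls, index=counts.ref.index, columns=counts.ref.columns)
    )


def _binom_llr_quality(alt: int, depth: int, error_rate: float) -> float:
    """log10 likelihood ratio, Binomial(depth, f_hat) vs Binomial(depth, error).

    Binomial coefficients cancel; f_hat is clipped to [error, 1) so a site
    with fewer alt reads than expected under error alone scores 0.
    """
    if depth == 0:
        return 0.0
    f = min(max(alt / depth, error_rate), 1.0 - 1e-12)
    e = min(max(error_rate, 1e-12), 1.0 - 1e-12)

    def loglik(p: float) -> float:
        return alt * np.log(p) + (depth - alt) * np.log1p(-p)

    return float((loglik(f) - loglik(e)) / np.log(10.0))


def discover_variants(
    pseudobulk: pd.DataFrame,
    control_site_ids: Sequence[str] = (),
    error_rate: float = 0.001,
    default_threshold: float = 20.0,
) -> pd.DataFrame:
    """Score candidate sites and report those clearing a control-calibrated bar.

    ``pseudobulk`` has one row per site id with columns ``ref_depth`` and
    ``alt_depth``.  Each site gets a binomial log10 likelihood-ratio
    quality; the reporting threshold is the minimum quality among the known
    control variants, falling back to ``default_threshold`` (and setting
    ``threshold_fallback``) when no control sites are supplied.

    Returns a frame with columns vaf, quality, reported, plus attrs
    ``threshold`` and ``threshold_fallback``.
    """
    qualities = {}
    for site_id, row in pseudobulk.iterrows():
        depth = int(row["ref_depth"]) + int(row["alt_depth"])
        qualities[site_id] = _binom_llr_quality(int(row["alt_depth"]), depth, error_rate)
    out = pseudobulk.copy()
    depth = out["ref_depth"] + out["alt_depth"]
    out["vaf"] = np.where(depth > 0, out["alt_depth"] / depth.clip(lower=1), np.nan)
    out["quality"] = pd.Series(qualities)
    controls = [s for s in control_site_ids if s in out.index]
    if controls:
        threshold = float(out.loc[controls, "quality"].min())
        fallback = False
    else:
        threshold, fallback = float(default_threshold), True
    out["reported"] = out["quality"] >= threshold
    out.attrs["threshold"] = threshold
    out.attrs["threshold_fallback"] = fallback
    return out


def find_tandem_duplication(
    insert: str, reference: str, min_dup_len: int = 10
) -> tuple[bool, int]:
    """Detect an internal tandem duplication in ``insert`` relative to ``reference``.

    A read supports an ITD when it is longer than the reference insert by
    d >= ``min_dup_len`` bases and contains some d-long block immediately
    repeated.  Returns (present, duplication length).  Reads no longer than
    the reference (including truncated ones) count as reference alleles.
    """
    d = len(insert) - len(reference)
    if d < min_dup_len:
        return False, 0
    for i in range(len(insert) - 2 * d + 1):
        if insert[i : i + d] == insert[i + d : i + 2 * d]:
            return True, d
    return False, 0


@dataclass
class ItdCallResult:
    """Per-cell ITD genotypes for one amplicon plus the modal duplication length."""

    genotypes: pd.Series  # index: barcode; values 0/1/2/NaN
    dup_length: int
    support: pd.DataFrame  # per barcode: itd_reads, total_reads


def detect_itd(
    inserts_by_cell: dict[str, Sequence[str]],
    reference: str,
    min_dup_len: int = 10,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> ItdCallResult:
    """Genotype an ITD-capable amplicon from per-cell insert sequences.

    Each insert either supports an ITD (tandem block, length gain) or the
    reference.  The per-cell genotype applies the het-band logic to the
    supporting-read fraction; ``dup_length`` is the modal duplicated-block
    length across supporting reads (0 when none).
    """
    rows = {}
    dup_lengths: dict[int, int] = {}
    for barcode, inserts in inserts_by_cell.items():
        itd_reads = 0
        for ins in inserts:
            present, d = find_tandem_duplication(ins, reference, min_dup_len)
            if present:
                itd_reads += 1
                dup_lengths[d] = dup_lengths.get(d, 0) + 1
        rows[barcode] = (itd_reads, len(inserts))
    support = pd.DataFrame.from_dict(
        rows, orient="index", columns=["itd_reads", "total_reads"]
    ).sort_index()
    genotypes = pd.Series(
        [
            call_genotype(total - itd, itd, min_depth, het_band)
            for itd, total in support.itertuples(index=False)
        ],
        index=support.index,
        dtype=float,
    )
    dup_length = max(dup_lengths, key=lambda d: (dup_lengths[d], -d)) if dup_lengths else 0
    return ItdCallResult(genotypes, dup_length, support)


def allele_counts_from_reads(
    assignments: Iterable[ReadAssignment],
    panel: AmpliconPanel,
    min_dup_len: int = 10,
) -> AlleleCounts:
    """Tally per-cell ref/alt depths at every panel variant site from reads.

    SNV alleles are read off the insert base at the site offset; ITD
    alleles via tandem-duplication detection on the full insert.  Reads too
    short to cover a site do not contribute to it.
    """
    sites_by_amp: dict[str, list[VariantSite]] = {}
    for s in panel.variant_sites:
        sites_by_amp.setdefault(s.amplicon, []).append(s)
    site_ids = [s.id for s in panel.variant_sites]
    idx = {sid: j for j, sid in enumerate(site_ids)}
    refs: dict[str, np.ndarray] = {}
    alts: dict[str, np.ndarray] = {}
    amap = panel.by_name
    for a in assignments:
        if a.reason != OK or a.amplicon not in sites_by_amp:
            continue
        if a.barcode not in refs:
            refs[a.barcode] = np.zeros(len(site_ids), dtype=np.int64)
            alts[a.barcode] = np.zeros(len(site_ids), dtype=np.int64)
        for s in sites_by_amp[a.amplicon]:
            j = idx[s.id]
            if s.kind == "ITD":
                present, _ = find_tandem_duplication(
                    a.insert, amap[s.amplicon].insert, min_dup_len
                )
                (alts if present else refs)[a.barcode][j] += 1
            else:
                if s.offset >= len(a.insert):
                    continue
                base = a.insert[s.offset]
                if base == s.alt:
                    alts[a.barcode][j] += 1
                elif base == s.ref:
                    refs[a.barcode][j] += 1
                # other bases: sequencing error to a third allele, ignored
    barcodes = sorted(refs)
    ref_df = pd.DataFrame(
        np.vstack([refs[b] for b in barcodes]) if barcodes else
        np.zeros((0, len(site_ids)), dtype=np.int64),
        index=barcodes, columns=site_ids,
    )
    alt_df = pd.DataFrame(
        np.vstack([alts[b] for b in barcodes]) if barcodes else
        np.zeros((0, len(site_ids)), dtype=np.int64),
        index=barcodes, columns=site_ids,
    )
    return AlleleCounts(ref_df, alt_df)
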