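"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are TSV with headers; metrics are flat JSON; variant
calls are minimal VCF 4.2.  Writers are deterministic (stable row order,
floats at 6 significant digits) so identical inputs give byte-identical
outputs.  Coordinates are 0-based half-open internally and 1-based only
in VCF POS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .barcodes import CellCountMatrix
from .clones import CloneTable
from .genotype import AlleleCounts, GenotypeMatrix
from .panel import Amplicon, AmpliconPanel, BarcodeWhitelist, VariantSite

FLOAT_FMT = "%.6g"

PANEL_COLUMNS = ["name", "chrom", "start", "end", "primer_fwd", "primer_rev",
                 "insert_seq", "weight"]
SITE_COLUMNS = ["id", "amplicon", "offset", "ref", "alt", "kind", "itd_length",
                "is_control"]


class FormatError(ValueError):
    """A malformed input file; the message carries the offending line."""


def write_panel(panel: AmpliconPanel, amplicon_path: str | Path,
                sites_path: str | Path | None = None) -> None:
    rows = [
        [a.name, a.chrom, a.start, a.end, a.primer_fwd, a.primer_rev, a.insert, a.weight]
        for a in panel.amplicons
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(
        amplicon_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    if sites_path is not None:
        srows = [
            [s.id, s.amplicon, s.offset, s.ref, s.alt, s.kind, s.itd_length,
             int(s.is_control)]
            for s in panel.variant_sites
        ]
        pd.DataFrame(srows, columns=SITE_COLUMNS).to_csv(
            sites_path, sep="\t", index=False
        )


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_panel(amplicon_path: str | Path,
               sites_path: str | Path | None = None) -> AmpliconPanel:
    df = _read_tsv(amplicon_path, PANEL_COLUMNS)
    amplicons = []
    for i, row in df.iterrows():
        try:
            amplicons.append(
                Amplicon(
                    name=row["name"], chrom=row["chrom"],
                    start=int(row["start"]), end=int(row["end"]),
                    primer_fwd=row["primer_fwd"], primer_rev=row["primer_rev"],
                    insert=row["insert_seq"], weight=float(row["weight"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{amplicon_path}: line {i + 2}: {exc}") from exc
    sites = []
    if sites_path is not None:
        sdf = _read_tsv(sites_path, SITE_COLUMNS[:7])
        for i, row in sdf.iterrows():
            try:
                sites.append(
                    VariantSite(
                        id=row["id"], amplicon=row["amplicon"],
                        offset=int(row["offset"]), ref=row["ref"], alt=row["alt"],
                        kind=row["kind"], itd_length=int(row["itd_length"] or 0),
                        is_control=bool(int(row.get("is_control", "0") or 0)),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{sites_path}: line {i + 2}: {exc}") from exc
    return AmpliconPanel(amplicons, sites)


def write_whitelist(whitelist: BarcodeWhitelist, path: str | Path) -> None:
    with open(path, "w") as fh:
        for bc in sorted(whitelist.barcodes):
            fh.write(bc + "\n")


def read_whitelist(path: str | Path) -> BarcodeWhitelist:
    barcodes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            bc = line.strip()
            if not bc:
                continue
            barcodes.append(bc)
            if len(bc) != len(barcodes[0]):
                raise FormatError(
                    f"{path}: line {lineno}: barcode length {len(bc)} != "
                    f"{len(barcodes[0])}"
                )
    try:
        return BarcodeWhitelist(frozenset(barcodes))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_fastq_pairs(
    fastq1: str | Path, fastq2: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Stream (read id, seq1, seq2) from a FASTQ pair.

    Raises FormatError naming the shorter file when the pair counts differ.
    """
    it1 = SeqIO.parse(str(fastq1), "fastq")
    it2 = SeqIO.parse(str(fastq2), "fastq")
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            shorter = fastq1 if r1 is None else fastq2
            raise FormatError(f"FASTQ pair count mismatch; {shorter} is shorter")
        yield r1.id, str(r1.seq), str(r2.seq)


def write_count_matrix(matrix: CellCountMatrix, path: str | Path) -> None:
    out = matrix.counts.sort_index()
    out.to_csv(path, sep="\t", index_label="barcode")


def read_count_matrix(path: str | Path) -> CellCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    return CellCountMatrix(df)


def write_allele_counts(counts: AlleleCounts, path: str | Path) -> None:
    """Wide TSV: one row per barcode, columns ``<site>.ref`` / ``<site>.alt``."""
    ref = counts.ref.add_suffix(".ref")
    alt = counts.alt.add_suffix(".alt")
    cols = [c for pair in zip(ref.columns, alt.columns) for c in pair]
    pd.concat([ref, alt], axis=1)[cols].sort_index().to_csv(
        path, sep="\t", index_label="barcode"
    )


def read_allele_counts(path: str | Path) -> AlleleCounts:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    ref_cols = [c for c in df.columns if c.endswith(".ref")]
    sites = [c[:-4] for c in ref_cols]
    ref = df[ref_cols]
    ref.columns = sites
    alt = df[[s + ".alt" for s in sites]]
    alt.columns = sites
    return AlleleCounts(ref, alt)


def write_genotype_matrix(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Cells as rows, sites as columns; values 0/1/2 and '.' for missing."""
    calls = genotypes.calls.sort_index()
    out = calls.map(lambda v: "." if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="cell")


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cell", dtype=str, keep_default_na=False)
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, v in enumerate(df[col]):
            if v == ".":
                continue
            if v not in ("0", "1", "2"):
                raise FormatError(
                    f"{path}: line {i + 2}: invalid genotype {v!r} (expected 0/1/2/.)"
                )
            values[i, j] = float(v)
    return GenotypeMatrix(pd.DataFrame(values, index=df.index, columns=df.columns))


def write_clone_table(table: CloneTable, path: str | Path) -> None:
    out = table.table.reset_index()
    out.insert(0, "genotype", ["/".join(str(int(g)) for g in k) for k in table.table.index])
    out = out.drop(columns=table.site_ids)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_clone_table(table_path: str | Path, site_ids: list[str]) -> CloneTable:
    df = pd.read_csv(table_path, sep="\t")
    keys = [tuple(int(x) for x in g.split("/")) for g in df["genotype"]]
    table = pd.DataFrame(
        {
            "label": df["label"].to_numpy(),
            "count": df["count"].to_numpy(),
            "frequency": df["frequency"].to_numpy(),
        },
        index=pd.MultiIndex.from_tuples(keys, names=site_ids),
    )
    return CloneTable(table, site_ids)


def write_metrics(metrics: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_vcf(
    discovered: pd.DataFrame, panel: AmpliconPanel, path: str | Path
) -> None:
    """Minimal VCF 4.2 for reported sites (POS is 1-based genomic).

    ``discovered`` is the frame from ``genotype.discover_variants``; only
    rows with ``reported`` True are written.  ITD alt alleles are the
    symbolic ``<DUP>`` with SVLEN in INFO.
    """
    amap = panel.by_name
    smap = panel.site_by_id
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SITEQ,Number=1,Type=Float,Description="Binomial LR quality (log10)">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Aggregate variant allele frequency">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Tandem duplication length">',
        '##ALT=<ID=DUP,Description="Internal tandem duplication">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for sid, row in discovered[discovered["reported"]].iterrows():
        site = smap[sid]
        amp = amap[site.amplicon]
        pos = amp.start + site.offset + 1
        info = f"SITEQ={row['quality']:.6g};VAF={row['vaf']:.6g}"
        alt = site.alt
        if site.kind == "ITD":
            alt = "<DUP>"
            info += f";SVLEN={site.itd_length}"
        lines.append(
            f"{amp.chrom}\t{pos}\t{sid}\t{site.ref}\t{alt}\t"
            f"{row['quality']:.6g}\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (CLI `--config` YAML)."""

    fastq1: str | None = None
    fastq2: str | None = None
    whitelist: str | None = None
    panel: str | None = None
    sites: str | None = None
    out_dir: str = "dropclone_out"
    max_dist: int = 1
    min_depth: int = 10
    het_band: tuple[float, float] = (0.2, 0.8)
    min_reads_floor: int = 100
    alpha: float = 0.05
    error_rate: float = 0.001
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "het_band" in kwargs:
            kwargs["het_band"] = tuple(kwargs["het_band"])
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)
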