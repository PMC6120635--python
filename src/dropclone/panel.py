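"""Amplicon panel domain types.

A targeted single-cell DNA panel is a set of short PCR amplicons, each
identified by a gene-specific forward primer that immediately follows the
cell barcode on read 1.  Variant sites (SNVs or internal tandem
duplications) are addressed by an offset into the amplicon's reference
insert sequence.  Genomic coordinates are 0-based half-open throughout;
they are rendered 1-based only when writing VCF.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"

#: Genes recurrently mutated in adult AML; used to name synthetic amplicons.
AML_GENES = [
    "TP53", "DNMT3A", "FLT3", "NPM1", "IDH1", "IDH2", "NRAS", "KRAS",
    "ASXL1", "TET2", "RUNX1", "CEBPA", "WT1", "KIT", "U2AF1", "SRSF2",
    "SF3B1", "STAG2", "BCOR", "PHF6", "RAD21", "PTPN11", "GATA2",
]


@dataclass(frozen=True)
class VariantSite:
    """A genotyped position within one amplicon insert.

    ``kind`` is ``"SNV"`` (ref/alt are single differing bases) or ``"ITD"``
    (the alt allele is a tandem duplication of the ``itd_length`` bases
    starting at ``offset``).  Control sites carry known heterozygous
    genotypes in the spike-in cell line and drive ADO/spike-in QC.
    """

    id: str
    amplicon: str
    offset: int
    ref: str
    alt: str
    kind: str = "SNV"
    itd_length: int = 0
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "ITD"):
            raise ValueError(f"variant site {self.id}: unknown kind {self.kind!r}")
        if self.kind == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError(f"variant site {self.id}: SNV alleles must be single bases")
            if self.ref == self.alt:
                raise ValueError(f"variant site {self.id}: ref and alt are identical")
        if self.kind == "ITD" and self.itd_length <= 0:
            raise ValueError(f"variant site {self.id}: itd_length must be positive")
        if self.offset < 0:
            raise ValueError(f"variant site {self.id}: negative offset")


@dataclass(frozen=True)
class Amplicon:
    """One targeted locus: primer pair, reference insert, genomic interval."""

    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    primer_fwd: str
    primer_rev: str
    insert: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"amplicon {self.name}: empty interval")
        if self.weight <= 0:
            raise ValueError(f"amplicon {self.name}: weight must be positive")
        if not self.insert:
            raise ValueError(f"amplicon {self.name}: empty insert")


@dataclass
class AmpliconPanel:
    """The targeted loci plus the variant sites they carry."""

    amplicons: list[Amplicon]
    variant_sites: list[VariantSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise ValueError("duplicate amplicon names")
        by_chrom: dict[str, list[Amplicon]] = {}
        for a in self.amplicons:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, amps in by_chrom.items():
            amps = sorted(amps, key=lambda a: a.start)
            for left, right in itertools.pairwise(amps):
                if right.start < left.end:
                    raise ValueError(
                        f"amplicons {left.name} and {right.name} overlap on {chrom}"
                    )
        amap = self.by_name
        site_ids = [s.id for s in self.variant_sites]
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate variant site ids")
        for s in self.variant_sites:
            if s.amplicon not in amap:
                raise ValueError(f"variant site {s.id}: unknown amplicon {s.amplicon}")
            ins = amap[s.amplicon].insert
            if s.offset >= len(ins):
                raise ValueError(f"variant site {s.id}: offset outside insert")
            if s.kind == "SNV" and ins[s.offset] != s.ref:
                raise ValueError(
                    f"variant site {s.id}: insert base {ins[s.offset]!r} != ref {s.ref!r}"
                )
            if s.kind == "ITD" and s.offset + s.itd_length > len(ins):
                raise ValueError(f"variant site {s.id}: duplicated block exceeds insert")

    @property
    def by_name(self) -> dict[str, Amplicon]:
        return {a.name: a for a in self.amplicons}

    @property
    def site_by_id(self) -> dict[str, VariantSite]:
        return {s.id: s for s in self.variant_sites}

    @property
    def control_sites(self) -> list[VariantSite]:
        return [s for s in self.variant_sites if s.is_control]

    @property
    def analysis_sites(self) -> list[VariantSite]:
        return [s for s in self.variant_sites if not s.is_control]

    def sites_on(self, amplicon: str) -> list[VariantSite]:
        return [s for s in self.variant_sites if s.amplicon == amplicon]

    @property
    def weights(self) -> np.ndarray:
        w = np.array([a.weight for a in self.amplicons], dtype=float)
        return w / w.sum()

    def mutant_insert(self, site: VariantSite) -> str:
        """Insert sequence carrying the alt allele of ``site``."""
        ins = self.by_name[site.amplicon].insert
        if site.kind == "SNV":
            return ins[: site.offset] + site.alt + ins[site.offset + 1 :]
        # tandem duplication: the block [offset, offset+len) occurs twice
        end = site.offset + site.itd_length
        return ins[:end] + ins[site.offset :]


@dataclass(frozen=True)
class BarcodeWhitelist:
    """Known cell barcodes, all of one fixed length over {A,C,G,T}."""

    barcodes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent barcode lengths: {sorted(lengths)}")
        bad = next((b for b in self.barcodes if set(b) - set(BASES)), None)
        if bad is not None:
            raise ValueError(f"non-ACGT barcode: {bad!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.barcodes)))

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def random_whitelist(n: int = 100_000, length: int = 18, seed: int = 0) -> BarcodeWhitelist:
    """Draw ``n`` distinct random barcodes of ``length`` nt."""
    rng = np.random.default_rng(seed)
    codes: set[str] = set()
    while len(codes) < n:
        block = rng.integers(0, 4, size=(n - len(codes), length))
        codes.update("".join(BASES[i] for i in row) for row in block)
    return BarcodeWhitelist(frozenset(itertools.islice(sorted(codes), n)))


def example_panel(
    n_amplicons: int = 62,
    insert_len: int = 200,
    primer_len: int = 20,
    seed: int = 7,
    patient: int = 1,
) -> AmpliconPanel:
    """Build a synthetic AML-style targeted panel.

    Mirrors the structure of a 62-amplicon AML panel: two heterozygous
    control SNVs on TP53 amplicons (the spike-in line's known variants)
    plus patient analysis sites.  ``patient=1`` gives TP53/DNMT3A SNVs and
    a 21-bp FLT3 ITD; ``patient=2`` gives IDH2/NRAS/ASXL1 SNVs.
    """
    if patient == 1:
        required = ["TP53", "TP53", "DNMT3A", "FLT3", "ASXL1"]
    elif patient == 2:
        required = ["TP53", "TP53", "IDH2", "NRAS", "ASXL1"]
    else:
        raise ValueError(f"patient must be 1 or 2, got {patient}")
    if n_amplicons < len(required):
        raise ValueError(f"panel needs at least {len(required)} amplicons")
    genes = list(required)
    for i in range(n_amplicons - len(required)):
        genes.append(AML_GENES[i % len(AML_GENES)])

    rng = np.random.default_rng(seed)
    amplicons = []
    pos = 10_000
    counter: dict[str, int] = {}
    for i, gene in enumerate(genes):
        counter[gene] = counter.get(gene, 0) + 1
        name = f"{gene}_{counter[gene]}"
        insert = _random_seq(rng, insert_len)
        amplicons.append(
            Amplicon(
                name=name,
                chrom=f"chr{i % 22 + 1}",
                start=pos,
                end=pos + insert_len,
                primer_fwd=_random_seq(rng, primer_len),
                primer_rev=_random_seq(rng, primer_len),
                insert=insert,
                weight=1.0,
            )
        )
        pos += insert_len + 1000
    amap = {a.name: a for a in amplicons}

    def snv(sid: str, amp: str, offset: int, *, control: bool = False) -> VariantSite:
        ref = amap[amp].insert[offset]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        return VariantSite(sid, amp, offset, ref, alt, "SNV", is_control=control)

    sites = [
        snv("TP53_ctrl1", "TP53_1", 60, control=True),
        snv("TP53_ctrl2", "TP53_2", 80, control=True),
    ]
    if patient == 1:
        flt3 = amap["FLT3_1"]
        sites += [
            snv("TP53_H47R", "TP53_1", 120),
            snv("DNMT3A_R899C", "DNMT3A_1", 90),
            VariantSite(
                "FLT3_ITD", "FLT3_1", 50,
                ref=flt3.insert[50], alt="<DUP>", kind="ITD", itd_length=21,
            ),
            snv("ASXL1_L815P", "ASXL1_1", 70),
        ]
    else:
        sites += [
            snv("IDH2_R140Q", "IDH2_1", 100),
            snv("NRAS_G13R", "NRAS_1", 40),
            snv("ASXL1_G646fs", "ASXL1_1", 70),
        ]
    return AmpliconPanel(amplicons, sites)
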