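# dropclone

Single-cell targeted DNA amplicon analysis for droplet barcoding runs:
barcode-to-cell assignment, knee-point cell calling, per-cell genotyping
with allele-dropout QC, internal-tandem-duplication (ITD) detection,
clone enumeration, and comparison of single-cell clonal architecture
against bulk variant-allele-frequency (VAF) inference.

## The problem

Droplet workflows barcode the amplified genomic DNA of thousands of
individual tumour cells over a targeted panel (tens of amplicons covering
recurrently mutated loci, e.g. in AML: *TP53*, *DNMT3A*, *IDH2*, *NRAS*,
*ASXL1*, *FLT3*).  Sequencing returns a soup of reads whose only link to
cells is an error-prone barcode.  Reconstructing per-cell genotypes — and
from them the tumour's clonal architecture — requires:

1. **Barcode correction** against a whitelist (unique match within
   Hamming distance 1, via O(length × alphabet) neighbourhood lookup).
2. **Cell calling** from the reads-per-barcode rank curve: the knee is
   the point of maximum perpendicular distance from the chord joining the
   first and last points of the (log₁₀ rank, log₁₀ count) curve.
3. **Genotyping** each cell × site from allele depths: with depth
   d = ref + alt ≥ d_min and f = alt/d, call hom-ref (f < 0.2), het
   (0.2 ≤ f ≤ 0.8), hom-alt (f > 0.8), else missing.  ITD alleles are
   recognised as inserts longer than the reference containing a tandem
   repeated block.
4. **QC with spiked-in control cells** carrying known heterozygous SNVs:
   their detection rate measures cell identification; the fraction of
   control cells miscalled homozygous at a known het locus is the
   **allele dropout (ADO)** rate r.  A het locus survives intact with
   probability (1−r), so a clone heterozygous at k sites is observed
   intact with probability (1−r)^k — dropout systematically deflates
   multi-mutant clone frequencies and creates spurious derivative clones.
5. **Clone analysis**: cells sharing a genotype vector form a clone;
   binomial tests decide whether a small clone is explainable as dropout
   from a parent (P(X ≥ observed), X ~ Binomial(parent count, q), q the
   product of per-site miscall rates/2); an optional deconvolution step
   inverts the per-site dropout channel to recover pre-dropout clone
   frequencies.
6. **Bulk comparison**: pseudobulk VAFs (barcodes removed), the simplest
   serial-acquisition inference (cell fraction = 2 × VAF under the het
   assumption, clones nested by descending fraction), and the total
   variation distance between inferred and observed clone distributions.

Because real patient runs live behind controlled access, the package
ships a generative simulator (`dropclone.simdata`) producing count
matrices or paired FASTQ with full ground truth — clone identities,
spike-in/doublet flags, per-allele dropout events — so every stage is
testable end to end.

## Worked example

Three simulated relapse-style runs (1,500 cells each, 1.5% control
spike-in, locus-level ADO 9%, a triple-mutant clone at 64%):

```python
import dropclone as dc
from dropclone import presets
from dropclone.pipeline import analyze_count_run

panel = dc.example_panel(n_amplicons=8, patient=2)
wl = presets.shared_whitelist()
analyses = []
for seed in (11, 12, 13):
    cfg = presets.patient2_config(seed, ado_locus_rate=0.09, panel=panel, whitelist=wl)
    run = dc.simulate_count_run(cfg)
    analyses.append(analyze_count_run(run.matrix, run.allele_counts, panel))
```

Printing per-run metrics and the pooled, dropout-corrected clone table:

```text
run seed 11: 1090 cells called, 1090 genotyped, spike-in 1.28%, ADO 14.29%
run seed 12: 1071 cells called, 1071 genotyped, spike-in 1.59%, ADO 8.82%
run seed 13: 1136 cells called, 1136 genotyped, spike-in 1.85%, ADO 7.14%

pooled clone table (top rows):
                                                                    label  count  frequency
IDH2_R140Q NRAS_G13R ASXL1_G646fs
1          1         1                  IDH2_R140Q+NRAS_G13R+ASXL1_G646fs   1581   0.487211
0          0         0                                                 WT    845   0.260401
1          1         0                               IDH2_R140Q+NRAS_G13R    299   0.092142
                     2             IDH2_R140Q+NRAS_G13R+ASXL1_G646fs(hom)     85   0.026194
0          1         1                             NRAS_G13R+ASXL1_G646fs     84   0.025886
1          0         0                                         IDH2_R140Q     80   0.024653

fitted locus-level ADO: 8.09%
triple-mutant frequency, raw:       48.7%
triple-mutant frequency, corrected: 62.2%
```

Reading the numbers: the per-run spike-in detection (1.3–1.9%) and ADO
estimates (7–14%) scatter around their generative values (1.5%, 9%)
because each run contains only ~20 control cells — pooling is essential.
The raw triple-mutant frequency (48.7%) is the generative 64% attenuated
by (1−0.09)³ ≈ 0.75, with the lost cells visible as hom-alt derivative
rows like `…+ASXL1_G646fs(hom)`; fitting the dropout rate from those
derivatives (8.1%) and deconvolving recovers 62.2%.

The same stages run from the shell on FASTQ input:

```bash
dropclone run-all --out demo --seed 5 --n-cells 400
dropclone simulate --out sim --n-cells 500 --patient 2
dropclone process --fastq1 sim/reads_R1.fastq --fastq2 sim/reads_R2.fastq \
    --whitelist sim/whitelist.txt --panel sim/panel.tsv --sites sim/sites.tsv --out work
```

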