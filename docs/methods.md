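# Methods

## Generative model

A simulated run draws `n_cells` truth cells.  Each cell is independently
a spike-in control with probability `spikein_fraction` (heterozygous at
every control site, reference elsewhere) or a tumour cell whose genotype
vector comes from `clone_spec` (a categorical over clones; dosages in
{0,1,2} per panel variant site).  With probability `doublet_rate` a
barcode hosts two cells whose template pools merge — a single-rate
abstraction of Poisson loading.  Barcodes are sampled without
replacement from a whitelist of fixed-length (default 18 nt) random
barcodes; background barcodes are random off-whitelist sequences.

**Allele dropout.** Each of a cell's two template copies at a locus
independently fails to amplify with probability p (`ado_prob`).  A
heterozygous locus is consequently observed homozygous with probability
2p(1−p) + p² = 1 − (1−p)², split evenly between hom-ref and hom-alt.
When both copies fail, one stray template is resampled from the cell's
own pre-dropout copies: a het cell then yields a confident homozygous
call on either allele with equal probability, while a homozygous cell
can only re-amplify its own allele (it cannot invent the allele it does
not carry).  This keeps the locus-level miscall rate exactly
r = 1 − (1−p)², the quantity the ADO estimator measures; configurations
are specified by r and back-computed to p = 1 − √(1−r).

**Read depth.** Per-barcode read totals are negative binomial
(mean `reads_per_cell_mean`, dispersion k; variance m + m²/k), allocated
to amplicons by panel weight; a site's depth is its amplicon's count.
The alt-read count is binomial in the barcode's surviving-template alt
fraction, with sequencing error flipping each read's allele at
`seq_error_rate`.  Background barcodes draw geometric-like totals
(dispersion 1, mean `background_reads_mean`) of reference-only material.
The read-level path (`emit_reads`) writes the same model as paired FASTQ
— read 1 = barcode + forward primer + insert, read 2 = reverse-
complemented insert — with per-base substitution errors and one random
barcode substitution at `barcode_error_rate`; it is intended for modest
run sizes, while `emit_counts` is the fast path for thousands of cells.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| barcode length / whitelist | 18 nt / 100,000 | typical split-and-pool inventory; single contiguous barcode |
| `spikein_fraction` | 0.024 | the measured three-run detection average for a ~1% nominal spike-in; detection rates are what the pipeline is compared on |
| `ado_prob` | p(r = 0.07) ≈ 0.036 | locus-level 7% dropout, the patient-1-style average |
| `doublet_rate` | 0.03 | typical droplet co-encapsulation at these loading densities |
| `reads_per_cell_mean` | 2,000 (dispersion 10) | MiSeq-scale depth over a ~62-amplicon panel |
| het band / min depth | [0.2, 0.8] / 10 | standard amplicon het calling; below 2× per allele a call is unreliable |
| `min_reads_floor` | 100 reads/barcode | with ~62 amplicons, fewer than ~2 reads/amplicon cannot be genotyped |
| barcode `max_dist` | 1 | unique single-substitution correction; ties rejected to avoid misassignment |
| explainability α | 0.05, no multiplicity correction | few candidate clones per sample; Bonferroni available via the α argument |

Reference scenarios (`dropclone.presets`) encode the study conditions
the acceptance script replays: patient-1-style runs (4,500 cells, 2.4%
spike-in, 7% ADO, a TP53→DNMT3A→FLT3/ITD serial clone chain with a
germline homozygous ASXL1 polymorphism in every tumour cell) and
patient-2-style relapse runs (1,500 cells, 1.5% spike-in, 8.5–9% ADO,
triple-mutant IDH2+NRAS+ASXL1 clone at 64%).  Simulations there use a
compact 8-amplicon panel with the full variant-site structure; depth per
site (~50×) is what matters to the callers, not panel width, and the
small panel keeps the whole acceptance run under a few seconds.

## Numerical and design choices

**Knee point.** The rank curve's knee is the rank maximising
perpendicular distance from the chord joining the first and last
(log₁₀ rank, log₁₀ count) points; ties break toward the larger rank.
Cells are the barcodes strictly above the knee (the chord's endpoints
have distance zero, so the maximum falls on the first tail point; for a
single dominant barcode over a flat tail this calls exactly that
barcode).  The method is parameter-free but mildly conservative: on a
sorted negative-binomial plateau the maximum sits slightly into the
cliff, undercalling by ~5% at dispersion 200 and more as the plateau
slopes (~25% at dispersion 10).  Rank-curve recovery scenarios therefore
use dispersion 200 — a tight, PCR-saturated plateau, which is also the
regime where a knee is well defined; downstream per-cell metrics are
unaffected by where exactly the cut lands because the cut is independent
of genotype.

**Spike-in detection** defaults to "alt allele present at ≥1 control
site".  A strict all-sites-het rule would exclude exactly the
dropout-affected control cells the ADO estimator needs, forcing the
estimate to zero; under alt-any, only cells hom-ref at *every* control
locus are missed (probability (r/2)² ≈ 0.1%), and patient cells cannot
reach the band at realistic error rates.  The residual conditioning bias
on the ADO estimate is ≈ −r²/4.  Doublet barcodes containing one control
cell are detected as spike-ins (they are), which raises the detected
fraction slightly above the nominal mixing fraction and adds a small
upward ADO bias (mixed barcodes sit at allele fraction ~0.25, near the
het band's lower edge).

**ADO estimation** averages loci with equal weight: per control locus,
(# spike-in cells called hom) / (# with a non-missing call).

**Multiplet rate** from a two-line mixing design scales the observed
mixed fraction m by 1/(2 p_A p_B) for unobservable same-line collisions.
Mixed barcodes dilute each line's het SNV to fraction ~0.25, adjacent to
the 0.2 band edge, so mixing experiments need depth well above the
routine 50× (the recovery test uses ~400×) — a property of the design,
not of the estimator.

**Clone deconvolution.** Dropout maps a true clone distribution f to the
observed distribution M(r)·f, where M factorises as a Kronecker product
of per-site channels (het → het w.p. 1−r, → hom-ref or hom-alt w.p. r/2;
hom calls unaffected).  `deconvolve_ado` inverts this by nonnegative
least squares and renormalises.  When no rate is supplied it is
profile-fitted from the clone table itself (`fit_ado_rate`): spurious
hom-alt derivatives of large het clones are produced almost exclusively
by dropout, so they pin r far more tightly (σ ≈ 0.5 pp) than the handful
of spike-in cells in a 1,500-cell run does (σ ≈ 2.5 pp, which the
correction would amplify roughly threefold).  The fit restricts the
underlying clones to het-carrier vectors ({0,1}^k) — without that
constraint every homozygous observation is "explained" by a matching
true clone and the likelihood degenerates to r = 0.  Tables containing
genuine homozygous somatic clones therefore need an externally supplied
rate.  Raw frequencies remain the default output of `enumerate_clones`;
the corrected table is an explicit extra step.

**Explainability.** A candidate clone derivable from a parent by
converting k het sites to hom is tested against
Binomial(parent count, q), q = ∏ (locus rate/2) over the converted
sites; p = P(X ≥ observed), "explainable" when p ≥ α.  The default
parent is the largest clone whose genotype dominates the candidate.

**Bulk inference** formalises the simplest serial-acquisition model:
cell fraction = 2 × VAF (het assumption, tolerance 0.02 on the 0.5
bound), variants sorted by descending fraction, clone i carrying
variants 1..i, exclusive fractions by differencing, wild type as the
remainder.  Germline homozygous sites (VAF ≈ 1) violate the het
assumption and are excluded from clonal inference.  Discordance against
the single-cell table matches clones by carried-variant set (dosage
collapsed to presence) and reports per-clone differences, one-sided
unpredicted/unobserved lists, and the total variation distance.

**Variant discovery** scores each site with a binomial log₁₀
likelihood-ratio (observed alt fraction vs. sequencing error alone) and
reports sites at or above the minimum quality among known control
variants — the control-calibrated threshold rule — falling back to a
configured default when no controls exist.  Multi-allelic sites are out
of scope (first alt allele only).

**ITD detection** is length-and-repeat based, not alignment based: a
read supports an ITD when it exceeds the reference insert by
d ≥ `min_dup_len` bases and contains a d-long block immediately repeated;
per-cell genotypes apply the same het-band logic to the supporting-read
fraction.  Reads shorter than the reference count as reference.

**Determinism.** One seed drives every random draw in a simulation
(recorded in the truth object); identical seeds give byte-identical
FASTQ and count output.  Writers order rows stably and format floats to
6 significant digits, so outputs are reproducible byte for byte.

## What the simulator does and does not capture

It reproduces the features the estimators rely on: whitelist barcode
errors, a two-population rank curve, panel-weighted depth, per-allele
dropout with the exact locus-level miscall rate, doublet pooling,
spike-in mixtures, and sequencing error.  It does **not** model PCR
jackpotting or chimeras, GC- or length-dependent amplicon bias beyond
static weights, index hopping, ambient cross-contamination between
barcodes, cell-cycle DNA content, or copy-number variation; dropout is
independent across loci and cells, whereas real dropout correlates with
amplicon performance.  Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to every
artefact of real libraries.  The read-level path emits uniform 'I'
quality strings; quality scores carry no information here.

## Known limitations

- The chord knee undercalls sloped plateaus (see above); a floor on
  reads/barcode protects downstream stages.
- ADO estimates from runs with ~20 control cells have percentage-point
  scale noise; pool runs before interpreting them.
- `fit_ado_rate` assumes somatic clones are heterozygous at mutated
  sites and a single shared rate across loci.
- Primer matching allows one mismatch and requires uniqueness; panels
  with near-identical primers would inflate the `off_target` tally.
- SNV and ITD evidence is read from read 1 only; inserts must fit in a
  single read (≤ ~210 bp at 250-bp reads with an 18-nt barcode).
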