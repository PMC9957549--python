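# Methods

## The inference problem

A red-blood-cell alloantigen system defines alleles serologically: an
alloantiserum agglutinates cells carrying its cognate antigen, so an
individual is typed as carrying one or two allele names (D1, D2, D3, ...)
with no DNA-level information. Identifying the gene behind such a system
means finding a locus whose variation co-segregates perfectly with the
serology across pedigrees and breeding lines. `alloanchor` decomposes that
inference into four stages — pooled-intensity association, candidate-gene
screening, panel haplotyping, and haplotype–serology mapping — each usable
standalone on real files or end-to-end on simulated studies.

## Pooled-intensity GWAS

**Model.** Array intensity for a biallelic SNP is treated as a B-allele
signal fraction in [0, 1], linear in allele dosage. For a DNA pool the
signal is the equimolar mean of its members' signals. Writing `c_i` for the
expected B-allele count of pool *i* at the focal locus (0, 1 or 2, implied
by the serology used to assemble the pool) and `x_ij` for pool *i*'s
intensity at SNP *j*, each SNP is scored by ordinary least squares of `c`
on `x_j`; the score is `r²_j`, the squared Pearson correlation. A SNP in
strong linkage with the focal locus makes `x_j` nearly proportional to
`c`, driving `r²_j → 1`; an unlinked SNP's `r²` follows the null
`Beta(1/2, (n−2)/2)` for *n* pools (checked against the first two moments
at *n* = 9 in the test suite).

Degenerate regressions (fewer than three usable pools, or zero variance in
either variable) are reported with `r² = 0` and a flag rather than an
error, so whole-array scans never abort. Missing intensities drop the pool
from that SNP's regression; nothing is imputed.

**Confirmation scan.** On individually genotyped samples, calls are recoded
0/1/2 (copies of the B allele) and the serology-derived focal-allele count
is regressed on dosage; significance is a two-sided F test with (1, n−2)
degrees of freedom. Monomorphic markers are skipped with a logged notice;
p-values that underflow are reported as the smallest positive normal double
rather than zero. Quality control retains markers with minor-allele
frequency ≥ 0.1 and missing fraction ≤ 0.1 (both configurable), MAF being
computed from the B-allele frequency over non-missing calls.

**Region delimiting.** No standard algorithmic definition exists for "the
peak region", so the package uses an explicit rule: the smallest interval
covering the maximal run of markers whose score passes a threshold
(default r² ≥ 0.8), where consecutive passing markers may be at most
`max_gap_bp` apart (default 1 Mb). Longer runs win; ties break by higher
peak score, then leftmost position. Returning no region (nothing passes)
is a result, not an exception. All coordinates are 1-based inclusive.

## Candidate-gene screen

Variant impact is a rule-based mapping from sequence-ontology coding
effects: missense → MODERATE; stop-gained, frameshift → HIGH; splice-region
and synonymous → LOW; intronic/intergenic → MODIFIER. Only HIGH/MODERATE
variants enter the screen, since the antigenic difference must be a protein
difference. Membrane annotation is a term-set intersection on GO cellular
components; the default set is {plasma membrane, integral component of
membrane, cell surface} and is configurable.

Line consistency is operationalised as four boolean checks over a gene's
impactful variants, evaluated against per-line genotype columns:

- **same-allele identity** — lines fixed for the same serological allele are
  homozygous with identical genotype vectors;
- **cross-allele difference** — lines fixed for different alleles differ at
  at least one variant;
- **segregation present** — every line known to segregate shows a
  heterozygous call somewhere in the gene, or both homozygous classes;
- **fixation respected** — fixed lines carry no heterozygous call.

A gene passes on the conjunction. Missing calls are excluded per check and
counted, never treated as evidence. The screen is monotone: adding a line
profile can only remove candidates. Candidates are ordered by the number of
impactful variants supporting the pattern; the full per-gene audit is always
reported, and an empty candidate set is a valid outcome. Gene attribution
follows the `GENE=` tag on each variant (single-sourced annotation) rather
than re-intersecting positions with spans.

## Panel haplotyping

The packaged CD99 panel has 8 assays (7 SNPs and 1 splice-region indel,
exons 2–11); the indel is treated as a biallelic marker with alleles
{ref, del}. Panel order follows the assay design (exon order); because the
coding strand runs against increasing coordinates here, positions decrease
along the panel. One assay (E124G) has an alternate allele absent from all
11 registered haplotypes; operations tolerate registry-monomorphic markers.
The fixture files are verified by SHA-256 at load time. The extracted
source table for this panel left one cell ambiguous; the packaged H06 row
is the unique completion consistent with every stated relationship among
the haplotypes (11 distinct vectors, H06 protein-identical to H03, H10 and
H11 each one synonymous SNP from another haplotype). The indel's genomic
coordinate, absent from the source, is placed inside its bracketing intron;
no computation depends on it.

**Phasing** is Clark parsimony with deterministic order: individuals are
processed by ascending heterozygous-site count (ties by id), repeatedly to
a fixed point. Fully homozygous, fully typed individuals seed the known
set. A heterozygote resolves when exactly one pair of known haplotypes
explains its genotype, or — for complete genotypes — when exactly one known
haplotype plus a single new complement does, the complement then joining
the registry. Genotypes admitting two or more known-pair explanations are
reported unresolved with the candidate pairs; nothing is guessed. Two pairs
of registry haplotypes have identical genotype sums (H03+H10 ≡ H04+H06 and
H04+H09 ≡ H05+H08), so such diplotypes are intrinsically unresolvable
without pedigree information — the simulator's default line structure never
co-segregates them within one mating pool, which mirrors the real breed
structure these haplotypes were observed in.

Labels are stable: re-registering a known vector keeps its label; new
vectors get the next index after the highest used (gaps are preserved,
registries never renumber).

The **non-synonymous projection** of a haplotype is its sub-vector at
missense markers. Equal projections mean identical encoded proteins, hence
serological indistinguishability; the fixture's 11 haplotypes collapse to 5
protein classes. Hamming distances can be restricted to missense or
synonymous sites.

## Serology mapping and concordance

Anchoring uses the strongest evidence first: a line serologically fixed for
allele S and carrying exactly one haplotype H pins H → S; conflicting
anchors are a hard error listing the evidence, and anchors are never
overwritten. Extension proceeds in two moves: (1) protein-class
inheritance — an unmapped haplotype whose projection class already maps
consistently to one allele inherits it; (2) co-segregation search — all
injective assignments of the remaining unmapped haplotypes to serological
names not yet in the map's image are scored by exact diplotype agreement,
and the unique maximiser is adopted (ties are reported, not guessed;
uncovered haplotypes stay unmapped).

Concordance translates each diplotype through the map and compares
unordered pairs. A single-allele record agrees with the matching
homozygote; a partial ("X and/or Y") record agrees with any compatible
completion and is counted separately. Disagreements are classified:
*second_allele_missed* (one allele reported, contained in the translated
pair), *homozygote_misidentified* (translated pair homozygous, serology
heterozygous or disjoint), *second_allele_wrong* (otherwise — exactly one
shared allele in the typical case). Under heterozygote-only typing error
the homozygote_misidentified class is provably empty and the expected
agreement is `1 − ε·P(het)`, which the audit reproduces within binomial
error at n = 10⁴.

## Synthetic data: what it emulates, and what it does not

The generator draws per-line diplotypes under Hardy–Weinberg from
configured haplotype frequencies; two-generation families transmit one
uniformly chosen haplotype per parent; pools of 3–8 members are assembled
from serology classes; member intensities are `dosage/2 + N(0, σ)`
truncated to [0, 1] (default σ = 0.05) and pool intensities add
`N(0, σ_pool)` (default 0.02) to the member mean; serology error is
heterozygote-only with probability ε (default 0.1), dropping or duplicating
one true allele. The variant table gives the causal gene missense variants
that track haplotype identity exactly, membrane-flagged decoys whose
genotypes cannot fit the line serology, and serology-tracking decoys
without membrane annotation — so exactly one gene survives both screens by
construction. The default nine-line structure mirrors the breed inventory
in which the CD99 haplotypes were observed (five elite White Leghorn lines,
one inbred D1 line, Rhode Island Red and White Plymouth Rock lines without
serology, one unrelated typed group), covering all 11 haplotypes.

Not emulated: linkage disequilibrium around the causal locus (background
SNPs are independent of pool class, so region recovery is driven by the
causal SNP alone), recombination within the panel (~11 kb, treated as fully
linked), mutation, genotyping error on panel assays, partially resolved
pool members, and antiserum cross-reactivity. Passing tests therefore
demonstrate correctness of the inference machinery under the stated noise
model, not robustness to array artefacts or cryptic structure in real data.

Randomness: one master seed; each stage derives its generator from
`SeedSequence([seed, offset])` with fixed documented offsets, so outputs
are byte-identical across runs for a fixed configuration.

## Study sizes used by the tests and acceptance script

Chosen to make Monte-Carlo error small relative to the margins being
checked while keeping runs fast: 200 replicates of 9 pools × (2000
background + 1 causal) SNPs for pooled-GWAS recovery; 1000 null markers ×
50 samples for the trend-test size; 50 seeds for screen recovery; ~500
individuals (9 lines plus two families) for phasing recovery; n = 10⁴ per
line for the concordance calibration.

## Known limitations

- The co-segregation search is exhaustive over injective assignments and is
  meant for the small allele inventories typical of blood-group systems
  (≤ ~6 unmapped names); it would not scale to large registries.
- Phasing has no statistical model (no EM/HMM, no imputation): individuals
  whose genotypes are genuinely ambiguous stay unresolved, and pedigree
  information is not used to break ties.
- The pooled model assumes DNA equimolarity within pools and a linear
  intensity response; saturation or dye bias in real arrays is not
  modelled.
- The region rule's defaults (r² ≥ 0.8, 1 Mb gap) are exposed parameters,
  not estimates; on sparse arrays the delimited interval can collapse to a
  single marker's position.
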