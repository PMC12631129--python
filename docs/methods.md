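# Methods

## Junction-read model

All splicing evidence comes from alignments with a reference skip
(CIGAR `N`): the skipped interval is the intron, and the read supports
exactly that junction. Reads inside alternative exons are never
counted, which is what makes the quantification robust to the strong
5′→3′ coverage decay of 5′-capture protocols — for any one event, the
inclusion and exclusion junctions sit at (nearly) the same transcript
position, so the coverage bias cancels in the ratio. Reference skips
shorter than 20 nt are treated as deletions, not introns (standard
splice-aware-aligner convention). Secondary and supplementary
alignments are ignored. No mapping-quality filter is applied by
default.

In single-cell mode, all reads sharing (cell barcode, UMI) — tags
`CB`/`UB` by default — are one molecule: a molecule supports a
junction if any of its reads spans it, at most once; a molecule whose
reads span contradictory junctions supports each once (no
arbitration). Bulk mode skips UMI unification and counts every primary
read.

Coordinates are 1-based inclusive everywhere (GTF convention);
BAM 0-based half-open coordinates are converted once, at the read
boundary in `junctions.py`.

## Event detection and classification

For every filtered junction X taken as exclusion, inclusion candidates
are junctions sharing `intron_start` or `intron_end` with X and nested
strictly inside it. When more than two share one splice position, the
two with the highest read counts are kept (ties: shorter intron, then
leftmost — determinism). A compatible left+right pair is a CE
candidate; unpaired single-side candidates become A5SS/A3SS/AFE/ALE/UN
by where their two alternative positions fall in the annotation index
(first-exon boundaries → AFE, last-exon → ALE, donors → A5SS,
acceptors → A3SS, checked in that order since terminal-exon boundaries
are also donors/acceptors). Events linking no gene, or two genes, are
UN (the latter flagged ambiguous). Novel events in IG/TCR/HLA regions
are discarded (likely DNA recombination or mapping artifacts); known
events there are kept.

MXE and IR are taken from annotation only, since junction reads alone
cannot delimit them: IR when an intron of one transcript is fully
exonic in another transcript of the same gene; MXE when two
non-overlapping internal exons share both flanking exons and never
co-occur. Junction-defined candidates whose junctions all coincide
with an annotated MXE's diagnostic junctions are superseded by the MXE
event — otherwise the MXE's own junction pairs would re-surface as
spurious A5SS/A3SS calls.

Per single-side event, the inclusion isoform is the shorter-intron
junction (more retained exonic sequence); for AFE/ALE this makes the
proximal alternative exon the inclusion side, matching the
proximal-as-inclusion counting convention. The MXE inclusion exon is
the 5′-most alternative exon (recorded in output; a pure convention).

## Counting and PSI

CE inclusion uses the one junction with the larger pooled total across
all cells — a per-cell choice would make PSI incomparable between
cells. IR inclusion is, per cell, the maximum of the two exon–intron
boundary-span counts (a span must cover the boundary base and its
neighbor contiguously in one aligned block). PSI = I/(I+E) with the
exact Clopper–Pearson interval from beta quantiles (the interval R's
`binom.test` reports). Aggregation over cells sums counts; PSI is
always computed from summed counts, never averaged over per-cell PSIs.

## Coding effect and NMD

The representative transcript of an event is the linking transcript
with the longest frame-complete CDS. The event's differing region
(cassette exon, A5SS/A3SS stub, retained intron, or MXE exon pair) is
classified: outside the genomic span of every CDS of the gene →
noncoding (the span, not the CDS intervals, because a retained intron
between CDS exons overlaps no CDS base yet clearly disrupts coding);
containing the start codon → coding-disruptive; otherwise by the
length change mod 3.

NMD uses the 50-nt rule: the event is applied to the representative
transcript, the altered isoform is translated from the annotated start
codon, and NMD is predicted iff the stop codon ends more than 50 nt
upstream of the altered transcript's final exon–exon junction (so
never when the stop lies in, or straddles into, the last exon; a
single-exon altered isoform — e.g. full intron retention in a two-exon
gene — is never NMD). Distances are measured from the base after the
stop codon to the junction.

## Beta-binomial embedding layer

Units are (sample × cell type) aggregates, filtered to samples with
≥10⁶ junction reads, units with ≥5000, and events detected in ≥80% of
retained samples. The per-event prior Beta(a, b) is fitted by direct
maximum likelihood of the beta-binomial (L-BFGS-B on log(a), log(b)
from a method-of-moments start, bounded to [1e-3, 1e6]; hitting a
bound — all-0 or all-1 PSIs — is flagged). The posterior median
(numerical inversion of the beta CDF) is the inferred PSI; zero
coverage yields the prior median. The permutation null draws
p ~ Beta(a, b) then I′ ~ Binomial(I+E, p) per unit, preserving every
coverage total exactly while destroying splicing information; priors
are not refit on permuted data. PCA/tSNE on the resulting matrix is
delegated to standard numerics.

## Differential splicing

Filters: pooled I ≥ 10, pooled E ≥ 10, and each group's junction-read
total ≥ 10; then the four-condition noise filter on the two groups'
pooled-PSI CI bounds (L_A > 0.05 or L_B > 0.05; H_A < 0.95 or
H_B < 0.95; L_A > 0.05 or H_A < 0.95; L_B > 0.05 or H_B < 0.95).
Conditions 3/4 exclude events whose group interval spans nearly the
whole unit range (uninformative); an event pinned at 0 in one group
and 1 in the other passes — that is a maximal real difference, not
noise.

The test is a binomial GLM with logit link on per-row (I, E):
H1 `~ sample + group` vs H0 `~ sample`, LRT with df = extra
parameters (1 for a two-level group), BH correction, and the specific
call at FDR < 0.01 and |ΔPSI| > 0.2 with ΔPSI from pooled counts. The
sample covariate identifies only when some sample is observed in both
groups (cell-type-within-sample designs); for group-of-samples designs
it is collinear with the group and is omitted (H0 = intercept-only).
Complete separation (a group entirely at PSI 0 or 1) adds 0.5 to every
I and E and flags the row. Rows with I+E = 0 are dropped.

Enrichment testing matches the background to the test genes'
expression-decile distribution by down-sampling, then applies
one-tailed Fisher tests per gene set with BH at FDR < 0.05.

## T-cell indices

Splicing distance: PSIs are mapped by the fixed affine transform
[0, 1] → [0.01, 0.99] then logit-transformed; the distance between two
subtypes is the Euclidean norm over events expressed in both (read
floor 5). The fixed map was chosen over a per-event min/max stretch:
with two subtypes a min/max stretch sends every differing PSI pair to
exactly {0.01, 0.99}, collapsing all information and breaking the
triangle inequality, while the fixed map reproduces the boundary
identity (0/1 → 0.01/0.99) and is a true metric.

Similarity score: per event, the sample's pooled PSI is placed
linearly between the two anchor PSIs, clamped to [0, 1], oriented from
anchor A toward anchor B (so relabeling the axis complements the
score). The sample score is the mean over events with ≥5 reads;
samples with more than one third of axis events under the floor are
excluded.

## Antigen chain

Detectability gate per cell type: I ≥ 5, E ≥ 5, and the PSI 95% CI
inside (0.05, 0.95). An isoform side (proportion p = PSI or 1−PSI) is
atypical against normal tissues iff p ≥ 10 × the mean normal
proportion and its CI lower bound ≥ 4 × the proportion in every
individual tissue (events absent from a normal table count as 0 there);
against stroma the folds are 5× (mean) and 2× (per patient), and the
isoform must additionally have zero supporting reads in every sample
of the tissue-of-origin reference ("undetectable" read strictly).
When both sides pass, both become candidates.

Eligible events (CE/A5SS/A3SS/IR in coding regions, not NMD-predicted)
are translated from the representative transcript with the event
applied; candidate peptides are all 8–11-mers present in the atypical
protein but absent from the normal isoform's protein and absent as
substrings of every reference-proteome sequence. MHC binding is a
pluggable (peptide, allele) → %rank table — external predictors are
consumed, never re-implemented; the best rank over a patient's ≤6
alleles decides strong binding (%rank < 0.5). ATB per sample is the
sum over strong-binding candidates of proportion × gene CPM
(CPM = 10⁶ × gene count / library total in the cancer cells).

## Synthetic fixtures

The generator emulates the study conditions at desk scale: one 100-kb
chromosome, eleven genes realizing CE (in-frame, frameshift-NMD,
frameshift-non-NMD, 3′UTR/noncoding, minus-strand), A5SS, A3SS, AFE,
ALE, MXE and IR, plus one annotation-free junction pair (UN); 200
cells (100 cancer, 100 stromal) across 4 samples, 10 molecules per
cell per event, every junction-bearing molecule emitting duplicate
reads to exercise UMI merging. "Exact" mode plants deterministic
counts (I = round(PSI·n)) for oracle tests; "sampled" mode draws
binomially for statistical tests.

Sequence design guarantees that the only stop codons in any forward
reading frame are the planted ones: the background never contains T
followed by A or G, and the two bases at every exon edge are fixed to
C so no stop can straddle a spliced junction either. Coding
consequences (frameshift PTC distances of 277 nt and a last-exon stop)
are laid out by hand and recorded in the manifest. The CDS features in
the generated GTF include the stop codon (Ensembl splits it out; the
loader accepts both conventions).

What the fixture does *not* emulate: sequencing errors, barcode
collisions, multimapping, splice-site motifs, expression heterogeneity
between genes, and real annotation complexity (overlapping genes,
thousands of isoforms). Passing the planted-truth tests therefore
demonstrates correctness of the counting/classification logic under
clean input, not robustness to alignment artifacts.

Count-level simulators provide the statistical study conditions
directly: the embedding fixture (50 events, 8 samples, 2 cell types,
coverage 200, 20% of events shifted by 0.4 PSI between cell types) and
the differential fixture (200 events; null ΔPSI = 0 for calibration,
ΔPSI = 0.3 at 20 samples × coverage 50 for power).

## Numerical choices

- Clopper–Pearson bounds via scipy beta quantiles; the test oracle is
  an independent 60-step bisection on the regularized incomplete beta
  (agreement ≤ 1e-9 over all I+E ≤ 200).
- Beta-binomial likelihood via `scipy.stats.betabinom`; posterior
  medians via `beta.ppf(0.5, ...)` (CDF inversion well below 1e-10).
- GLM fits via statsmodels with explicit design matrices (no formula
  layer); LRT statistic clipped at 0 against round-off.
- Event ids are deterministic strings built from coordinates and type,
  so joins across samples and reruns are stable; tie-breaks (top-two
  junctions, CE inclusion choice) are fully ordered.
- Problem sizes in tests and the acceptance script (200-cell fixture,
  200-event simulations, 10 prior-recovery replicates) keep the whole
  suite at well under a minute per layer on one CPU.

## Known limitations

- Multi-exon-skipping CEs are emitted as the maximal event plus any
  nested events that independently pass filters, deduplicated by id.
- AFE events whose two first exons straddle the shared exon at equal
  distance have no defined proximal side; such events are flagged
  rather than decided.
- NMD prediction evaluates the isoform opposite to the representative
  transcript; when the atypical side coincides with the representative
  structure the prediction describes its partner isoform.
- The noise filter, GLM and antigen folds all assume two groups;
  multi-level designs are decomposed into pairwise comparisons by the
  caller.
- `enrichment_test` matches expression distributions proportionally
  per decile; with very small test sets individual bins may be empty
  and are skipped.
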