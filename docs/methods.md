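# Methods

This note documents the models behind each stage, the assumptions of the
synthetic-data generator, the numerical choices, and what the test suite
does and does not demonstrate.

## Allele-dosage model

Every read-count expectation in the package follows one mixture model. A
tumor sample is a mixture of tumor cells at purity *p* and normal cells at
1 − *p*. At a locus where the tumor carries *C* total copies of which *m*
carry the variant allele, and the normal carries m_normal of 2 (1 for a
germline het, 0 for a somatic variant), the expected variant allele
fraction is

    VAF = (p·m·f + (1−p)·m_normal) / (p·C + 2·(1−p))

where *f* is the fraction of tumor cells in the clone carrying the variant
(1 for truncal events). Consequences used throughout:

- a biallelic truncal variant in a copy-neutral LOH region (m = 2, C = 2,
  f = 1) has expected VAF = p, which is why the truncal variant is a
  purity estimator;
- a germline het on the haplotype lost in copy-neutral LOH has expected
  VAF (1 − p)/2, so the deviation from 0.5 is p/2 — LOH at the 0.1
  deviation threshold becomes callable at purity ≥ 0.2 in the noiseless
  limit;
- a one-copy deletion pushes het VAFs to 1/(2 − p) or (1 − p)/(2 − p);
  an unbalanced gain to 3 copies gives deviation |((2p+1−p)/(p·3+2−2p)) − 0.5|,
  ≈ 0.14 at p = 0.8. Allelic imbalance from unbalanced gains therefore
  crosses the LOH threshold at high purity and is classed gain-LOH.

## Synthetic tumor generator

The generator (`canosa.synthetic`) emulates the statistical structure the
analysis stages assume, not reads or alignments:

- **Reference**: iid random sequence per chromosome with configurable GC
  (default 0.41, a mammalian-like composition); the build carries the
  32-context pyrimidine-folded trinucleotide frequencies recomputed from
  the realized sequence.
- **Germline hets**: a Poisson process at density 1/2000 bp, each assigned
  a haplotype uniformly; haplotype 1 is by convention the one lost in
  deletions and LOH, haplotype 0 the one duplicated in gains.
- **Somatic SNVs**: organized into clones with per-lesion cell fractions.
  The default scenario has one fully shared truncal clone (15 variants), a
  small primary-private clone (2 variants at fraction 0.25), and three
  metastasis-private clones (4 + 4 + 3 variants at fractions
  0.55/0.30/0.15), giving 17 primary vs 26 metastatic variants with 15
  shared — the same set arithmetic as a two-lesion osteosarcoma case.
  Substitution contexts are drawn from a signature mixture (default 0.7
  aging-like + 0.2 + 0.1 synthetic components) and placed by rejection
  sampling on positions whose reference trinucleotide matches.
- **Copy number / LOH truth**: the default 3 × 10 Mb genome carries 4.5 Mb
  of one-copy loss, 1.6 Mb of 3-copy gain and a 100 kb focal 6-copy
  amplification (15% loss, 5.67% gain — within the 12–19% / 5–9% range
  aneuploid genomes of this tumor type show), one 3 Mb copy-neutral LOH
  block holding the biallelic truncal variant, and one deletion-LOH
  region. Segment coordinates are multiples of the 10 kb window so window
  summaries align with truth.
- **Noise**: per-site depth ~ Poisson(coverage); variant reads ~
  Binomial(depth, expected VAF). Coverage defaults: 60× WGS, 120× WES.
  An optional per-base error rate (default 0) adds background support in
  samples where a variant is absent. There is no mappability structure,
  GC-coverage bias, strand bias, FFPE damage, or alignment artifact — so
  passing recovery tests demonstrates correctness of the statistical
  logic under the stated model, not robustness to real sequencing
  artifacts.
- **Determinism**: every function takes an explicit seed; identical
  (scenario, seed) pairs give byte-identical outputs. Exported truth
  (BED/JSON/FASTA) round-trips exactly.

## Change-point engine

The LOH deviation track and the CN window track are both segmented by an
exact PELT-style penalized search with an L2 (within-segment sum of
squares) cost. Two numerical choices matter:

- the cost is divided by a robust noise-variance estimate, the median
  absolute deviation of first differences scaled to variance; this makes
  one penalty, β·log n with β = 3, work across tracks whose noise differs
  by an order of magnitude (binomial VAF noise at 60× has σ ≈ 0.04 per
  marker; Poisson window-depth ratios at 10 kb × 60× have σ ≈ 0.01);
- a minimum segment length (5 markers for LOH, 2 windows for CN) and a
  merge pass joining adjacent segments whose means differ by less than
  0.02 (LOH) / 0.25 (CN) suppress short spurious excursions that a pure
  penalized search occasionally keeps.

Genomic boundaries between change points are placed at the midpoint
between the flanking markers; chromosome ends extend to the marker span.
Segmentation is per chromosome; chromosomes with fewer than 10 markers
are skipped with a warning.

## Filter semantics

Removal criteria within a caller-level rule set are joined by OR — any
triggered condition removes the variant, and all triggered conditions are
reported as reason codes. The one textual ambiguity (whether high normal
VAF and low normal coverage must co-occur in the WES rule) is exposed as
`conjunctive_normal_rule` (default off, i.e. independent conditions).
Printed thresholds are inclusive removal bounds: "variant reads ≤ 4
removed" keeps 5. In the cascade, a variant survives the caller-level
stage if it survives the rule set of at least one DNA platform on which
both the lesion and the normal have support — mirroring a merge of
per-platform call lists. The consequence whitelist is matched as exact
full strings (the annotator's combined consequence labels, including
comma-joined forms), shipped verbatim as a data file.

## Copy number

The estimator is deliberately simple: per-window CN =
2 · (tumor/normal mean depth) / median autosomal ratio, with an optional
LOESS-style GC correction (off by default; the synthetic generator has no
GC-coverage bias to correct). It reports the purity-mixed copy number —
a one-copy loss at purity p reads as 2 − p copies — so the
classification thresholds 1.5/2.5 correspond to events at purity ≥ 0.5^-;
no purity back-correction or subclonal deconvolution is attempted.
Percent aneuploidy uses the summed length of assessed (windowed) genome
as its denominator; loss is CN ≤ 1.5, gain is CN ≥ 2.5, both inclusive.

## Signatures

Spectra are built on the pyrimidine strand in the standard 96-class
order. Composition renormalization multiplies each class count by the
target/source frequency ratio of its trinucleotide and rescales to
preserve the total. Exposure refitting is forward-selection NNLS on the
spectrum fractions: signatures are added greedily while they reduce the
Euclidean reconstruction error by more than 1e-4; weights below 0.06 are
zeroed and the rest refit; weights are capped to sum ≤ 1, with the
shortfall reported as unexplained residual. The shipped signature matrix
is synthetic (one aging-like C>T-at-NpCpG column, one T>G-at-NpTpT
column, one flat column, plus sparse random columns) — a stand-in used
by tests and demos, not a reference catalogue; any 96 × K probability
matrix can be supplied instead.

Kataegis detection uses the field's conventional rule — a maximal run of
≥ 6 same-chromosome variants with every inter-mutation distance ≤ 1 kb
and ≥ 50% C>T/C>G at TpC — since the phenomenon is defined by example in
the literature rather than by a canonical algorithm; all three knobs are
parameters.

## Comparison, tiers, drivers

Percent shared uses the union as denominator (verified against the
published per-lesion counts: (17, 26, 28) → 54%, (34, 22, 37) → 51%) and
rounds half away from zero. Expression tiers use the gene's minimum
descending rank over the gene count as its percentile (the 25th-highest
of 1000 genes sits at exactly 2.5%, the boundary of the moderate tier);
ties share the minimum rank, so a degenerate all-equal sample puts every
gene in the high tier. Driver scores count four boolean evidence flags;
cross-platform concordance is (amplified ∧ high expression) ∨ (deleted ∧
low expression) ∨ (SNV ∧ LOH overlap); ties rank alphabetically.

## Fusion triage

"Adjacent" for read-through means annotation-order neighbors on the same
strand and chromosome with no intervening gene, plus a 500 kb gap cap.
The homology rule is a local alignment (match 1, mismatch −1, gap −2)
between supplied partner sequences with identity ≥ 0.8 over ≥ 50 bp —
a transcript-level approximation of a cross-partner read search. When no
family tags exist, the family rule falls back to comparing symbol stems
after stripping trailing digits (paralog numbering); this heuristic can
false-positive on unrelated genes that share a stem. An empty SV call
set fails every candidate on the no-explaining-SV rule by construction.

## Problem sizes in the test suite

Recovery suites run at the generator's default study-like conditions:
3 × 10 Mb genomes, coverage 60×, het density 1/2000, purities spanning
0.6–1.0 over 20 seeds for LOH recovery; purity recovery uses 50 seeds per
true purity at 200×; signature recovery uses 20 seeded 3-component
mixtures of 5000 mutations. Unit tests use 3 × 400 kb genomes with the
same event structure scaled down.

## Known limitations

- The depth-ratio CN estimator is a stand-in for a production
  copy-number caller; it has no mappability/GC machinery and reports
  purity-mixed copies.
- LOH calling is unphased; it measures allelic imbalance, so unbalanced
  gains are reported (as gain-LOH) even though no allele is fully lost.
- The binomial noise model understates overdispersion of real read
  counts; thresholds validated here may need margin on real data.
- Kataegis and homology rules are conventional reconstructions, exposed
  as parameters, not reproductions of a specific published algorithm.
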