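# Methods

This note documents the models, conventions and numerical choices behind
`ssrmarkers`, and what the synthetic-data generator does and does not
emulate.

## Repeat mining

The scanner reports *maximal perfect* tandem repeats of a fixed unit length
(default trinucleotides, ≥ 10 units). Maximality means the tract cannot be
extended by one full unit on either side; compound or interrupted repeats are
never merged, and a run is broken at any `N`. Units that are whole-number
repetitions of a shorter word (for trinucleotides: homopolymers `AAA`, `CCC`,
`GGG`, `TTT`) are excluded — they are mononucleotide runs in disguise.
Overlapping phases of one repeat tract are resolved greedily: candidates are
taken left to right, the longest phase at each position wins, and anything
overlapping an accepted locus is dropped. Coordinates are 0-based half-open.

Candidate deduplication uses exact string equality of the flanking sequences
(default 50 bp per side). Near-duplicate clustering — which would catch
flanks differing by a SNP — is deliberately not attempted; exact-flank
equality is a conservative, reproducible criterion. Amplicon feasibility is a
bp-arithmetic screen only (repeat ≤ 300 bp; repeat + available flanks
≥ 100 bp); actual primer design is out of scope.

The canonical motif class of a trinucleotide is the lexicographic minimum
over the six strings formed by the three rotations of the unit and of its
reverse complement, so loci detected in either orientation or phase report
one class.

## Allele binning

Allele labels are nominal fragment sizes (integer bp), not repeat counts,
because ladder-based nomenclature is how alleles are harmonized across
instruments and labs. Ladder construction is single-linkage clustering in one
dimension: sorted observed sizes merge while the inter-size gap is below half
the repeat step (1.5 bp for trinucleotides); a rung's nominal size is the
median of its members rounded to 0.1 bp. Binning assigns an observed size to
the nearest rung when the deviation is within the tolerance (default 1.0 bp,
kept strictly below step/2 so neighbouring rungs cannot both claim a size);
midpoint ties go to the lower rung. Sizes outside tolerance raise an
off-ladder error rather than being silently assigned — a new allele or an
artifact must be a deliberate decision.

One peak is scored as a homozygote. This is an assumption, not an
observation: a null allele paired with an amplifying allele is
indistinguishable from a homozygote with codominant scoring. It is the
standard convention for inbred variety panels, where near-total homozygosity
is expected a priori.

## Diversity statistics

Frequencies count both alleles of every non-missing call; missing calls are
excluded from the denominator. PIC uses the Botstein et al. (1980) form

    PIC = 1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²,

the form implemented by the standard parentage/identity software for
codominant markers. PIC ≤ He holds for every frequency vector, with equality
only in degenerate cases; both are 0 exactly when k = 1.

Group summary rows report the mean and the median; the median is the middle
order statistic (panels here have an odd locus count). Min/max/sum are
available from the same summary helper.

## Identity analysis and pID

Every unordered accession pair is compared over the loci typed in both; the
per-locus mismatch is 2 minus the multiset intersection of the two allele
pairs (0, 1 or 2). A pair "matches at t" when its summed mismatch is ≤ t, so
pair counts are non-decreasing in t by construction. Pairs sharing fewer than
`min_shared_loci` typed loci (default 10) are reported as incomparable rather
than matched — matching on a handful of loci is not evidence of identity.

pID is the naive Hardy–Weinberg estimator per locus,
pID_l = Σ pᵢ⁴ + Σ_{i<j} (2 pᵢ pⱼ)², multiplied across loci under
independence. Because bred varieties are emphatically not a randomly mating
population, the sibling variant
pID_sib = 0.25 + 0.5 s₂ + 0.5 s₂² − 0.25 s₄ (s₂ = Σ pᵢ², s₄ = Σ pᵢ⁴) is
always reported alongside as the conservative bound; neither should be
over-interpreted for pedigree-related material.

## Error rates

Between a reference and a replicate typing of n accessions typed t times,
e_a = m_a/2nt (allelic mismatches over replicated allele count) and
e_l = m_l/nt (single-locus genotypes with ≥ 1 mismatch). A genotype called in
exactly one dataset is counted as a failure — m_l += 1 and m_a += 2 — since
amplification failure is the dominant real-world error mode and must be
visible in the rates; genotypes missing in both datasets are excluded from n.
These conventions imply e_l/2 ≤ e_a ≤ e_l per locus. Means are unweighted
across loci.

## Transferability

A marker transfers to a species only when it amplified in *every* lab (AND
consensus) — single-lab signals are treated as unconfirmed. Summary
percentages are computed over a focal congener set (amplifies in all, in all
but one, in at least one) plus a cross-genus percentage: markers amplifying
in at least one species of every genus present in the panel. Percentages are
rounded to two decimals.

## Marker QC

Three screens, all tunable: `MULTIPEAK` (any sample with ≥ 3 peaks —
multi-locus amplification), `LOW_POLYMORPHISM` (fewer than 3 alleles in the
focal group), and `IMPLAUSIBLE_HET` (heterozygote fraction above 0.5 in
material expected to be near-fully homozygous — a heterozygous-looking
profile at most accessions of an inbred panel indicates paralogous
co-amplification, not genuine heterozygosity).

## Clustering and PCA

Binary encoding scores allele presence per (locus, allele) column; trinary
encoding scores dosage (homozygote 1, each heterozygote allele 0.5), so every
non-missing locus contributes a row sum of 1. A locus missing in an accession
leaves all its columns 0 and is flagged; no imputation.

Dice distance d = 1 − 2a/(2a+b+c) is computed on the binary encoding; two
all-zero profiles have no defined similarity and raise an error. Linkage
methods available: single, complete, UPGMA, WPGMA. Merge heights are the
inter-cluster distance at merge, so cophenetic distances live on the scale of
the input matrix; Newick export uses the half-height convention (leaf-to-leaf
path length = cophenetic distance). Linkage selection maximizes the
cophenetic correlation CC (Pearson, upper triangle) and breaks ties by the
smaller Mather delta, delta_q = √(Σ(d^q − c^q)²/Σ d^{2q}), q ∈ {0.5, 1}; a
residual full tie (e.g. ultrametric input, which every method reproduces
exactly) resolves to UPGMA.

Bootstrap supports resample *loci* (not allele columns) with replacement,
preserving within-locus dependence between allele columns, and count how
often each reference clade reappears; results are seeded and reproducible.

PCA operates on the column-centered trinary matrix with no column scaling
(covariance PCA): columns are already on one dosage scale, and scaling would
inflate rare-allele columns. Percent variance is reported per axis over all
axes; component signs are fixed so the largest-magnitude loading of each
component is positive.

## Synthetic data

The generator states a world and sticks to it:

- 17 loci with per-locus allele counts (10, 9, 5, 10, 7, 8, 3, 8, 9, 6, 7,
  6, 6, 3, 6, 6, 9) — the scale of a published trinucleotide panel (118
  alleles, 3–10 per locus) — alleles 3 bp apart inside 100–300 bp;
- allele frequencies per locus from a symmetric Dirichlet with α = 1
  (uniform over the simplex; no value is dictated by the emulated panels, and
  α = 1 produces the mix of common and rare alleles typical of variety
  collections);
- an accession is homozygous at *all* loci with probability 0.71; otherwise
  heterozygous at one or two loci (probabilities 0.6/0.4). Heterozygosity is
  modelled at the accession level, not as independent per-locus HWE, because
  in real inbred panels residual heterozygosity concentrates in a few
  accessions — locus-independent heterozygosity would badly under-produce
  fully homozygous accessions;
- isoline pairs are verbatim profile copies; congeneric species draw from an
  allele pool shifted by a configurable offset and can fail to amplify per
  locus;
- replicate error injection: per genotype, amplification failure with
  probability ε_fail, else each allele substituted with probability ε_sub by
  a uniformly drawn different allele of the locus.

What it does **not** emulate: stutter and other electrophoretic artifacts,
null alleles, linkage between loci, pedigree structure among varieties, and
population subdivision beyond the species split. A green test on synthetic
data therefore establishes the correctness of the computations and their
statistical calibration under the stated model — not the biological claims
one could make from a real panel.

## Numerical conventions

- Genotype calls are stored as lexically sorted label pairs; files code
  missing as `0` for both alleles, and a half-missing call is a format error.
- All stochastic operations take a seed or a `numpy` Generator and are pure
  functions of (configuration, seed).
- Percentages in transferability summaries are rounded to 2 decimals;
  nominal ladder sizes to 0.1 bp; allele labels to integer bp.
- Summary medians use the middle order statistic for odd counts (midpoint of
  the central pair for even counts).

## Known limitations

- The exact-flank deduplication criterion understates duplication when
  flanks carry sequencing errors.
- The binning tolerance/tie policy is a stated convention; commercial
  panel-analysis software may differ in edge cases.
- pID/pID_sib assume HWE and locus independence and are reported for
  comparability, not as forensic-grade probabilities for bred material.
- With very small groups the unbiased-vs-naive distinction in He is ignored
  (the naive estimator is used).
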