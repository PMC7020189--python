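# ssrmarkers

Tools for developing and evaluating codominant microsatellite (SSR) marker
panels for cultivar identification in highly homozygous, self-pollinating
crops (e.g. opium poppy and its congeners).

Marker panels of this kind are built in stages, each with its own
computational step:

1. **Mining** — scan EST/genomic FASTA sequences for perfect trinucleotide
   repeats with ≥ 10 units, deduplicate candidates by flanking sequence and
   check feasibility of a 100–300 bp amplicon.
2. **Binning** — convert capillary-electrophoresis fragment sizes to named
   alleles against per-locus allelic ladders (3 bp spacing, 1 bp tolerance),
   collapsing peak lists to diploid calls (0 peaks = missing, 1 = homozygote,
   2 = heterozygote, ≥ 3 = multi-locus artifact).
3. **Diversity statistics** — per locus and accession group: allele count
   *k*, observed heterozygosity *Ho = n_het / n_typed*, expected
   heterozygosity *He = 1 − Σ pᵢ²* and polymorphic information content
   (Botstein form) *PIC = 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ²*.
4. **Identity analysis** — all-pairs profile matching with 0–5 allowed
   allelic mismatches, plus the probability of identity
   *pID = Πₗ (Σ pᵢ⁴ + Σᵢ<ⱼ (2 pᵢ pⱼ)²)* and its sibling variant.
5. **Reproducibility** — error rate per allele *e_a = m_a / 2nt* and per
   locus *e_l = m_l / nt* between reference and replicate typings; a call
   missing in exactly one dataset counts as a full locus error.
6. **Transferability** — cross-species amplification with a conservative
   both-labs consensus (a marker transfers only when every lab saw a
   product).
7. **Multivariate discrimination** — Dice distances
   (*d = 1 − 2a/(2a+b+c)*) on binary allele presence, hierarchical
   clustering with the linkage chosen by the highest cophenetic correlation
   (ties by Mather's delta), bootstrap clade supports over loci, and PCA on
   the trinary (0/0.5/1) allele-dosage encoding.

A seeded synthetic-data generator (`ssrmarkers.simulate`) emulates the
structure such panels actually have — ~71 % of accessions homozygous at all
loci, residual heterozygotes at one or two loci, isoline pairs with identical
profiles, congeners with shifted allele pools — so every stage is testable
without proprietary genotype data.

## Worked example

```sh
ssrmarkers simulate --seed 7 --accessions 30 --out geno.csv
ssrmarkers identity --genotypes geno.csv --out identity.tsv
```

prints

```
seed=7: 30 accessions -> geno.csv
28 unique profiles out of 30 accessions
matching pairs at t=0..5: 1, 1, 1, 1, 1, 1
```

meaning exactly one accession pair (the simulated isoline pair) shares an
identical 17-locus profile and no further pair becomes indistinguishable even
when up to five allelic mismatches are tolerated. The same matrix can be
pushed through the rest of the pipeline:

```sh
ssrmarkers stats   --genotypes geno.csv --out table.tsv
ssrmarkers cluster --genotypes geno.csv --method auto --bootstrap 1000 \
                   --seed 42 --newick tree.nwk
ssrmarkers pca     --genotypes geno.csv --components 2 --out scores.tsv
```

The library API mirrors the CLI one-to-one; see the module docstrings in
`src/ssrmarkers/`.

## Acceptance script

`scripts/acceptance.py` exercises the whole pipeline from scratch on a
seeded 47-accession × 17-locus synthetic panel — diversity report, pID,
identity analysis, replicate error rates, linkage selection with bootstrap
supports, and PCA — and writes its JSON result map:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
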