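# dnmpipe

Trio-based de novo mutation (DNM) analysis with a built-in synthetic
multi-platform cohort simulator. The package reimplements, as a tested
pipeline, a published tri-platform DNM inference procedure:

- **Synthetic cohorts** (`dnmpipe.cohort`, `dnmpipe.reads`, `dnmpipe.bundle`)
  — pedigrees of quads/trios, germline and postzygotic (mosaic) truth
  variants with paternal bias and parental-age effects, annotation tracks
  (segmental duplications with % identity, tandem repeats, RepeatMasker,
  homopolymers, exons), per-read evidence for three platforms (HiFi blood,
  ONT cell line, Illumina blood), informative SNPs at ~1/1200 bp, plus two
  injected artifact classes (dropped parental haplotype runs, recurrent
  cross-sample errors).
- **Discovery & validation** (`dnmpipe.validation`) — candidate selection
  (parents 0/0, child alt, GQ >= 20), the 3-SNVs-in-1-kbp cluster filter,
  per-platform read validation with platform-specific parental alt-read
  ceilings, cross-sample recurrence, allele-balance and homopolymer
  filters, indel and sex-chromosome rules.
- **Phasing** (`dnmpipe.phasing`) — distance-weighted inheritance scores
  over informative SNPs within an 80-kbp window; HiFi first, ONT fallback,
  conflicts excluded.
- **Origin classification** (`dnmpipe.classify`) — per-haplotype read
  composition (a postzygotic mutation shows a third haplotype), a
  cross-platform allele-balance chi-squared concordance test, and a pooled
  one-sided exact binomial test against AB = 0.5.
- **Callable genome & rates** (`dnmpipe.rates`, `dnmpipe.intervals`) —
  per-trio callable masks, track stratification, exact Poisson intervals,
  parent-specific and per-stratum rates with BH-corrected t-tests.
- **Spectra & statistics** (`dnmpipe.spectra`) — strand-collapsed
  dinucleotide spectra with BH-corrected chi-squared enrichment, Ti/Tv,
  multinucleotide-mutation chaining (<= 500 bp) with distance bins,
  parental-age OLS regressions and paternal-bias tests.
- **Orchestration** (`dnmpipe.pipeline`, `dnmpipe.cli`) — end-to-end runs
  with a JSON summary and a reproducibility manifest (config snapshot,
  seed, per-output hashes).

## CLI

```bash
dnmpipe simulate --config config.yaml --out bundle/ --seed 1
dnmpipe validate --bundle bundle/ --out validated.tsv
dnmpipe phase    --bundle bundle/ --validated validated.tsv --out phased.tsv
dnmpipe run-all  --config config.yaml --out run/ --seed 1
dnmpipe compare-truth --run-dir run/ --config config.yaml --seed 1
```

`config.yaml` holds a `simulation:` section (see
`dnmpipe.config.SimulationConfig` for all fields and defaults) and
optionally a `filters:` section (`FilterParams`). Exit codes: 0 success,
2 configuration error, 3 stage failure.

Bundles are plain text: PED, one VCF 4.2 per family (GT:GQ), BED tracks
(half-open, 0-based), and TSV tables for reads, informative SNPs, SNP
observations, truth variants, and the callability panel.

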