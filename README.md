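# contibd

Continuous-genome identity-by-descent (IBD) for two pedigree members:
simulation, exact summary statistics, exact segment likelihoods, and
likelihood-ratio power studies for distinguishing pedigree relationships
when IBD is observed continuously and without error along the autosomes.

The IBD state at each point of a chromosome is driven by a continuous-time
Markov chain on binary inheritance vectors (one bit per meiosis) under
Haldane's recombination model: each bit flips at 0.01 per cM. The observed
IBD0/IBD1 process is a deterministic function of the vector obtained by
dropping founder haplotype labels through the pedigree. On top of this model
the package provides:

- **Relationships** — named families (`PO`, `GP`, `GGP`, `GnGP`, `HS`, `N`,
  `GN`, `GnN`, `HN`, `sC`, `sCtR`, `HsC`, `HsCtR`) or arbitrary two-parent
  pedigrees in a PED-like text format. Pairs with nonzero IBD2 probability
  (e.g. full siblings) are rejected; the observation model is binary.
- **Exact statistics** — identity coefficients by exhaustive enumeration
  (exact rationals), two-locus probabilities and the variance of total IBD
  in closed form via the Walsh spectrum of the IBD1 indicator, the
  probability of no IBD per chromosome and genome-wide via a
  Poisson-truncated (uniformized) forward algorithm, expected segment
  counts from the stationary crossing flux, and Monte-Carlo segment-count
  dispersions.
- **Simulation** — exact continuous-genome simulation by bit-flipping at
  exponential inter-arrival times; a vectorized batch simulator for
  large Monte-Carlo studies.
- **Likelihoods** — the exact likelihood of an observed segment set under
  any accepted relationship (class-restricted forward recursions with exit
  densities at segment boundaries), likelihood ratios, and composite
  (mixture) hypotheses.
- **Power studies** — empirical log10 LR distributions, rates of misleading
  evidence, median log10 LRs, and the accuracy of the LR ≥ 1 classifier,
  pairwise or one-vs-rest.

State spaces are reduced exactly to the meioses that can affect the pair's
IBD state, so even distant relationships (fifth cousins: 24 raw meioses)
run on at most 2^14 states.

## Command line

```sh
contibd coeffs 1C                         # exact kappa coefficients
contibd moments GP,HS,N --map fixture     # total-IBD / segment-count table
contibd simulate 2C --seed 7 --out segs.tsv
contibd loglik 2C --segments segs.tsv
contibd lr --segments segs.tsv --h1 2C --h2 3C
contibd lr --segments segs.tsv --h1 GP --h2 HS,N       # composite H2
contibd power --h1 1C --h2 2C --reps 1000 --seed 1
contibd power --set GP,HS,N --reps 1000 --seed 1       # one-vs-rest
contibd fixtures --outdir fixtures/
```

`--map` accepts `fixture` (packaged 22-autosome map totalling 3391.36 cM),
`toy` (2 chromosomes, fast), or a TSV with columns `chromosome`,
`length_cM`. Segment files are TSVs with columns `chromosome`, `start_cM`,
`end_cM`, `ibd_state`; segments tile each chromosome half-open with
alternating states. A YAML config (`--config`) can supply default option
values. Exit codes: 0 success, 2 validation error, 3 capacity error.

## Layout

| module | contents |
| --- | --- |
| `contibd.pedigree` | pedigrees, relationship parsing/construction, label dropping, PED I/O |
| `contibd.statespace` | IBD-vector chain, intensities, uniformization kernels, Walsh spectra |
| `contibd.genmap` | genetic maps and the packaged fixtures |
| `contibd.segments` | validated alternating segment sets |
| `contibd.simulate` | single-genome and batched simulators |
| `contibd.exact` | identity coefficients, moments, Pr(T=0), segment counts |
| `contibd.likelihood` | segment likelihoods, hypotheses, likelihood ratios |
| `contibd.power` | LR sampling and power summaries |
| `contibd.io` / `contibd.cli` | file formats, fixtures, command-line interface |
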