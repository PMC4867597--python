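# riboclip

Analysis toolkit for asking two linked questions about an RNA-binding protein
and translation:

1. **Where does the protein sit on mRNAs?** CLIP-seq immunoprecipitation reads
   are compared against a matched control with a windowed Poisson test to call
   binding peaks, define the bound ("target") gene set, and profile where
   peaks fall along the 5'-UTR → CDS → 3'-UTR axis.
2. **How does a perturbation change translation?** Ribosome-profiling
   footprints are binned into region-normalized occupancy curves, and
   redistribution of ribosomes between conditions (e.g. wild type vs. a
   mutant) is quantified with Kolmogorov–Smirnov shift tests, 5'-UTR/CDS
   density ratios, half-transit-time regression from labeling time courses,
   and an MA-plot comparison showing whether target mRNA *abundance* (rather
   than translation) changed.

Every analysis can be exercised end-to-end on synthetic data from a seeded
generator that produces annotations, CLIP replicates with ground-truth bound
genes, footprints from a piecewise occupancy model, negative-binomial
expression tables and labeling time courses.

## Worked example

```bash
riboclip simulate --seed 1 --out sim/
riboclip callpeaks \
    --ip sim/clip_ip_rep1.tsv --ip sim/clip_ip_rep2.tsv \
    --control sim/clip_control.tsv --annotation sim/annotation.gtf \
    --out peaks.bed --targets-out targets.txt
riboclip shift \
    --reads WT=sim/ribo_WT.tsv --reads mutant=sim/ribo_mutant.tsv \
    --annotation sim/annotation.gtf --targets targets.txt --out shift
riboclip transit --in sim/transit.tsv --out transit_est.tsv
```

With seed 1 and the default configuration (300 genes, 30 of them bound, two
IP replicates at 0.2 reads/nt, 100,000 footprints per condition) this run
gives:

- CLIP replicate agreement: Pearson r = **0.999** on log2 per-gene counts;
- 30 peaks called; target recovery sensitivity **0.97**, precision **0.97**
  against the simulator's truth table;
- footprint exon preference: intron/CDS density ratio **0** (reads are
  simulated on mature mRNA only);
- occupancy redistribution in the mutant: the 5'-UTR/CDS density ratio rises
  from **0.115** (WT) to **0.519** (mutant), and the CDS KS test gives
  D = 0.070 on both targets and non-targets, p < 1e-25 for both — the
  mutant affects bound and unbound mRNAs alike;
- mRNA stability: **0/300** genes flagged between the two null expression
  conditions (the redistribution is translational, not transcriptional);
- half-transit times: 1.27–1.58 min across conditions (all simulated at
  1.5 min), pairwise bootstrap comparisons non-significant.

The same numbers (and a few more) are written by the acceptance script:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Library layout

| module | contents |
|---|---|
| `riboclip.annotation` | transcript models, 0-based half-open coordinates, GTF/TSV I/O, region binning (floor rule), genomic class partition with fixed precedence |
| `riboclip.reads` | read sets in genomic (BED6) or transcript (TSV) coordinates, single-nucleotide anchoring with P-site offsets |
| `riboclip.clip_peaks` | windowed Poisson peak caller with BH FDR, peak/read densities per genomic class, metagene profiles, target-set definition, replicate correlation |
| `riboclip.ribo_profile` | footprint densities, relative occupancy curves, KS shift tests, multi-condition comparison |
| `riboclip.transit_time` | half-transit-time OLS estimator with bootstrap CIs and condition comparison |
| `riboclip.expression_compare` | FPKM, MA transform, NB replicate-based stability test |
| `riboclip.synthetic` | the seeded generator behind all of the above |
| `riboclip.plotting` | metagene/occupancy/MA figures (Agg backend) |

Methods, model parameters and limitations: [docs/methods.md](docs/methods.md).

## Tests

```bash
python -m pytest -q          # unit + property + acceptance tests (~40 s)
```

`tests/test_acceptance.py` holds the end-to-end statistical properties
(oracle equivalences, FDR/KS/expression calibration, recovery power,
determinism); the remaining files are per-module unit and property tests.
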