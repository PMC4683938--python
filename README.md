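# herdvar

Population-genetic characterization of diverging populations from SNP-chip
genotypes: quality control, diversity metrics, Weir–Cockerham
F-statistics, LD-based effective population size with heterozygosity-decay
forecasting, rarefaction allelic richness, VanRaden genomic relationships,
one-level AMOVA, and allele-frequency population trees — plus an
island-model synthetic-data generator that provides ground truth for every
estimator.

## What is implemented

| Module | Contents |
| --- | --- |
| `herdvar.genotype_io` | `GenotypeMatrix` dosage model, PLINK PED/MAP text reader/writer, dosage-TSV format, subsetting |
| `herdvar.qc` | call-rate / quality / heterozygosity-outlier / Hardy-Weinberg filters, exact HWE test, QC report |
| `herdvar.popstats` | per-population diversity table (MAF, H_obs, H_exp, fixed markers, F_IS), Weir–Cockerham θ/f, pairwise F_ST with locus bootstrap, Nei's standard distance, marker-wise F_ST scan |
| `herdvar.ne_ld` | Burrows composite r², per-chromosome LD-based Ne with the small/large-sample bias corrections, genome averaging, geometric heterozygosity-decay projection |
| `herdvar.rarefaction` | rarefied allelic richness and private allelic richness at a standardized gene-copy count (exact combinatorics) |
| `herdvar.grm` | VanRaden method-1 genomic relationship matrix, per-population summaries, PCA, relatedness screening |
| `herdvar.amova` | one-level AMOVA on squared Euclidean dosage distances with permutation significance |
| `herdvar.phylo` | population frequency matrix, Ward minimum-variance tree, marker-bootstrap clade support, Newick output |
| `herdvar.simdata` | Balding–Nichols generator, forward Wright–Fisher simulator (drift LD), mainland-plus-two-islands packaged scenario, truth manifests |
| `herdvar.pipeline` / `herdvar.cli` | end-to-end orchestration and the `herdvar` command |

## Command line

```bash
# generate a synthetic dataset with known truth
herdvar simulate --preset korean-like --seed 1 --out simdir/

# full pipeline: QC -> diversity -> distances -> Ne -> GRM -> AMOVA -> tree
herdvar run --ped simdir/data.ped --map simdir/data.map \
            --pops simdir/pops.tsv --seed 1 --out results_dir/

# individual stages
herdvar qc        --ped ... --map ... --pops ... --out qc_report.tsv
herdvar diversity --ped ... --map ... --pops ... --out diversity.tsv
herdvar fst       --ped ... --map ... --pops ... --boot 100 --out dist.tsv
herdvar ne        --ped ... --map ... --pops ... --pop island1 --maf-min 0.05
herdvar forecast  --h0 0.306 --ne 7 --horizon 50 --out forecast.tsv
herdvar richness  --ped ... --map ... --pops ... --out richness.tsv
herdvar grm       --ped ... --map ... --pops ... --pca 2 --out grm.tsv
herdvar amova     --ped ... --map ... --pops ... --perm 1000 --out amova.tsv
herdvar tree      --ped ... --map ... --pops ... --boot 10000 --out tree.nwk
```

All stage outputs are plain TSV/JSON/Newick.  Stochastic stages are
seeded and bit-reproducible.

## Notes on conventions

* Dosages count the minor allele as read from PED (ties broken to the
  lexicographically larger label); missing genotypes are a dedicated
  sentinel, never dosage 0.  All statistics are invariant to allele
  relabeling.
* The Ne path uses the Hardy-Weinberg-adjusted composite-r² denominator
  (p(1−p)+D_A per locus) whose null expectation matches the published
  sample-size corrections; the plain p(1−p) form is available via
  `hw_adjust=False`.
* Per-chromosome Ne estimates are combined by arithmetic mean ± sd
  (harmonic mean available), with infinite estimates counted separately.
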