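# xstrpop

Population-genetic and forensic statistics for X-chromosomal STR panels:
from sex-aware genotype tables (hemizygous males, diploid females) to allele
and haplotype frequencies, exact tests, the per-locus forensic statistic
battery, inter-population distances, UPGMA trees, PCoA ordination and Evanno
delta-K post-processing — plus a synthetic-data generator with known ground
truth for every pipeline stage.

## Modules

| module | contents |
| --- | --- |
| `xstrpop.io_formats` | genotype TSV, allele-frequency CSV, PHYLIP/CSV distance matrices, Newick, allele-label parsing |
| `xstrpop.frequencies` | chromosome-dose allele counts (male 1, female 2), pooled frequencies, male linkage-group haplotypes, haplotype diversity |
| `xstrpop.equilibrium_tests` | exact HWE (females), exact two-locus LD (males), EM + permutation LD (females), exact population differentiation, Bonferroni |
| `xstrpop.forensic_params` | PIC/HOM/HET/PE/PI/PD and the four mean-exclusion-chance variants; multi-locus combined parameters |
| `xstrpop.population_comparison` | pairwise Fst (haploid variance components, per locus and multi-locus) with permutation p-values; Nei's unbiased distance |
| `xstrpop.tree_ordination` | UPGMA with deterministic tie-breaking, total branch length, classical PCoA |
| `xstrpop.structure_interop` | STRUCTURE input export for mixed-ploidy X data, Evanno delta-K tables |
| `xstrpop.synthetic_data` | Dirichlet frequencies, HWE-distorted populations, linked male haplotypes, Balding-Nichols divergence |
| `xstrpop.datasets` | bundled published per-locus statistics used for validation |

Exact tests condition on the observed allele counts; small problems are
solved by complete enumeration, larger ones by independent Monte Carlo
resampling from the same conditional null (reported with a binomial
standard error, reproducible by seed).

## CLI

```sh
xstrpop simulate --seed 1 --out runs/sim                 # synthetic dataset
xstrpop freqs     --input runs/sim/genotypes.tsv --out runs/freqs
xstrpop haplotypes --input runs/sim/genotypes.tsv --out runs/haps
xstrpop hwe       --input runs/sim/genotypes.tsv --seed 1 --out runs/hwe
xstrpop ld        --input runs/sim/genotypes.tsv --seed 1 --out runs/ld
xstrpop forensic  --input runs/sim/genotypes.tsv --out runs/forensic
xstrpop compare   --input runs/sim/genotypes.tsv --seed 1 --out runs/fst
xstrpop tree      --matrix runs/fst/fst_matrix.phy --out runs/tree
xstrpop pcoa      --matrix runs/fst/fst_matrix.phy --out runs/pcoa
xstrpop evanno    --runs runs.csv --out runs/evanno
xstrpop report    --freq-table freqs.csv --out runs/report
```

Every subcommand writes CSV (plus Newick where relevant) and a `run.log`;
outputs are never overwritten without `--force`, and stochastic subcommands
require an explicit `--seed`.

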