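# corecollect

Construction, evaluation and QTL-detection benchmarking of germplasm **core
collections** from biallelic SNP panels.

The toolkit covers the full workflow for comparing core-collection
construction strategies on an inbred-line panel:

- **Genotype handling** (`corecollect.genotypes`): VCF / PLINK-text /
  dosage-matrix readers, missingness and MAF filters, mode imputation,
  windowed LD pruning, Rogers distances and the VanRaden genomic relationship
  matrix.
- **Population structure** (`corecollect.structure`): PCA on the standardized
  matrix with Tracy–Widom selection of significant axes, K-means clustering
  with spherical-Gaussian BIC, discriminant-analysis memberships and GWAS
  covariates, Weir–Cockerham Fst and per-cluster diversity summaries.
- **Core selection** (`corecollect.selection`): eight criteria (A-NE, E-NE,
  He, SH, CV, CDmean, Avg_GRM, D-optimality), weighted multi-objective
  scalarization with normalization, and four optimizers (random descent,
  simulated annealing, hill climbing, genetic algorithm), all seeded, with
  support for forced-in accessions and replicate generation.
- **Evaluation** (`corecollect.evaluation`): SH, He, MRD, RAR, CV, KL
  divergence, eigenvalue-weighted PC correlation (COR), phenotypic
  mean-difference ratio (MD), and the seven-component composite index *I*.
- **QTL benchmark** (`corecollect.qtl`): trait simulation with known causal
  SNPs, EMMAX/P3D mixed-linear-model GWAS with kinship and structure
  covariates, genomic-control λ, effective-test-count (simpleM-style)
  significance thresholds, and the common-QTL recovery ratio of each core
  against the whole collection.
- **Synthetic panels** (`corecollect.simulate`): seeded Balding–Nichols
  generator (cluster sizes, target Fst, selfing, AR(1) LD, chromosome map)
  plus cluster-associated passport traits, so everything is testable offline.
- **Pipeline & CLI** (`corecollect.pipeline`, `corecollect.cli`): end-to-end
  orchestration of the twenty canonical method×criterion combinations.

## CLI

```sh
# quality control and structure analysis
corecollect qc --genotypes panel.tsv --format matrix_tsv --out run/
corecollect structure --genotypes panel.tsv --out run/ --seed 1

# build ten replicate cores for one method
corecollect select --genotypes panel.tsv --method SH_CV --size 350 \
    --reps 10 --seed 1 --out run/

# evaluate a core list against the whole collection
corecollect evaluate --genotypes panel.tsv --core run/core_SH_CV_0.ids.txt

# full benchmark sweep (selection + evaluation + QTL benchmark + index)
corecollect sweep --genotypes panel.tsv --methods SH_CV,ENE_HE,CDmean \
    --size 350 --reps 10 --seed 1 --out run/

# final mixed-selection core: fixed pre-list + optimized complement
corecollect final --genotypes panel.tsv --fixed fixed_ids.txt \
    --method SH_CV --size 409 --out run/
```

Genotype formats: VCF 4.x (GT field, biallelic records), PLINK text
`.ped`/`.map`, or a dosage matrix TSV (header of marker ids, optional
`#chrom`/`#pos` comment rows, first column accession id, cells in
`{0,1,2,NA}`).

## Library example

```python
from corecollect import simulate, selection, evaluation, structure
from corecollect.genotypes import filter_maf, rogers_distance, kinship_vanraden

bundle = simulate.standard_fixture(seed=1)     # 600 x 3000, 6 clusters
g = filter_maf(bundle.genotypes, 0.01)
aux = {"distance": rogers_distance(g),
       "kinship": kinship_vanraden(g),
       "pca": structure.pca_with_tw(g)}
cfg = selection.SelectionConfig(size=100, criteria=[("SH", .5), ("CV", .5)],
                                optimizer="local_search", seed=7)
core = selection.optimize(g, aux, cfg)
report = evaluation.evaluate_core(g, g.index_of(core.selected_ids),
                                  aux["distance"], whole_pca=aux["pca"])
```
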