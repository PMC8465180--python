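# degcord

Cross-species concordance analysis of differentially expressed genes
(DEGs). Given a focal domestication study (tame vs. aggressive rats) and
published domestic-vs-wild comparison datasets, the package:

1. **pairs** homologous DEGs between the focal and comparison tables using
   curated symbol-level ortholog/alias/family maps (`homology`);
2. **classifies** each pair by homology multiplicity — orthologs supported
   by multiple homologs vs. single orthologous pairs vs. paralog support;
3. **decomposes** the paired log2 fold changes with a two-variable PCA
   into a common component (PC1) and a variation component (PC2), and runs
   the sign-concordance contingency statistics (`decomposition`);
4. **verifies** selected DEGs against qPCR replicate matrices with
   Mann-Whitney/Z statistics and cross-platform correlations (`qpcr`);
5. **maps** animal divergence directions through human gene-effect
   annotations into a reproductive-potential contingency table
   (`human_selfdom`).

A statistics toolbox (`stats`: exact Fisher, uncorrected Pearson χ²,
exact binomial sign test, Pearson/Spearman/Kendall/Goodman–Kruskal
correlations, exact small-sample Mann-Whitney, two-sample Z) and a
synthetic-data generator (`synthetic_data`) support every stage. The
printed tables of the source study are bundled as checksummed TSV
fixtures (`degcord.fixtures`) so all headline numbers are reproducible
offline.

## CLI

```bash
# full pipeline on the bundled tables
degcord run --fixtures --json report.json

# individual stages
degcord pair --focal focal.tsv --comparison comp.tsv --out pairs.tsv
degcord decompose --pairs pairs.tsv --mode correlation --json out.json
degcord stats table2x2 --counts 7,0,2,5 --tests fisher,chi2,binomial
degcord qpcr-verify --fixtures --genes Ascl3,Apobec1,Defb17
degcord human-map --fixtures
degcord simulate pairs --n 54 --common-fraction 0.7 --seed 1 --out sim.tsv
degcord simulate qpcr --seed 1
```

Input DEG tables are TSV with a header (`symbol`, `log2fc`, optional
`species`/`tissue`/`p_value`/`p_adj`/`source_id` columns; separators and
column names configurable via `core_model.TableDialect`). Homology maps
are JSON with `alias_map`, `ortholog_map` and `family_map` objects.

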