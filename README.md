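# ecoregion-beta

Statistical pipeline for disentangling the environmental and geographical
correlates of **alpha and beta diversity** across ecoregions — territories
with homogeneous climatic, topographic and geological features, scored for
the presence/absence of every taxon in a regional flora. The package targets
the classic question in Mediterranean-type biodiversity hotspots: do
**narrow endemics** and **widespread nonendemics** respond to the same
drivers (climate, elevation, substrate, dispersal limitation), or do their
turnover patterns decouple?

## What it computes

Given a taxon × ecoregion incidence table with endemism flags, per-cell
monthly climate/elevation tables, a lithology composition table and a 1-km²
cell grid, the pipeline runs:

1. **Distance construction** — floristic Sørensen dissimilarity
   `1 − 2a/(2a+b+c)`; lithological Bray–Curtis on substrate surface
   fractions; standardized Euclidean distance on selected environmental
   variables; geographic distance as the mean over all cross pairs of cell
   centers (robust to irregular ecoregion shapes).
2. **Clustering & ordination** — UPGMA dendrograms with multiscale-bootstrap
   **AU (approximately unbiased) p-values** per cluster; correspondence
   analysis and DCA (detrending by segments); correlation-matrix PCA of the
   22 derived environmental/altitudinal variables.
3. **Variable selection** — exhaustive **BIO-ENV**: the variable subset whose
   Euclidean distances maximize Spearman rank correlation with the community
   dissimilarities.
4. **Inference** — alpha-diversity OLS models; **multiple regression on
   distance matrices (MRM)** with matrix-permutation p-values; variance
   partitioning of beta diversity into per-predictor unique contributions,
   joint covariation, and unexplained variance (the three always sum to 1);
   a taxon-resampling robustness check.

Because the motivating floras exist only as printed catalogs, the package
ships a first-class **synthetic-data generator**: gridded landscapes with
elevation ridges, lapse-rate climate, a lithology mosaic, and floras whose
beta-diversity drivers are known by construction — so every stage is
testable end to end, including recovery of the planted drivers.

## Worked example

Generate a dispersal-limited flora and ask which distances explain its
turnover:

```python
import ecoregion_beta as eb

landscape, occ, truth = eb.simulate(eb.distance_decay_scenario(seed=11))
env = eb.build_env_table(landscape.monthly)
lith = eb.build_lithology_table(landscape.lith_surfaces)
res = eb.run_beta_analysis(occ, env, landscape.grid, lith=lith,
                           max_k=3, nperm=999, seed=11)
part = res["nonendemic"].partition
print(f"MRM R2 = {part.r2_full:.3f} (p = {res['nonendemic'].mrm.r2_p:.3f})")
print({k: round(v, 3) for k, v in part.unique.items()})
print(f"joint = {part.joint:.3f}  unexplained = {part.unexplained:.3f}")
```

prints

```
MRM R2 = 0.673 (p = 0.001)
{'climatic': 0.0, 'altitudinal': 0.053, 'geographic': 0.203, 'lithological': 0.0}
joint = 0.417  unexplained = 0.327
```

Reading: 67% of the variance in nonendemic compositional turnover is
explained; the **geographic** distance matrix has by far the largest unique
contribution (0.203) — exactly the distance-decay structure this scenario
plants — while climate and lithology contribute nothing that the other
matrices do not already carry. For the endemic element of the same landscape
the altitudinal matrix dominates instead (unique 0.120), illustrating the
guild contrast the pipeline is built to expose.

The same analysis is available from the shell:

```bash
ecoregion-beta simulate --seed 11 --out data/
ecoregion-beta run --config run.yaml     # full configured pipeline
ecoregion-beta bioenv --community sorensen.tsv --env env.tsv --codes 1-18 --max-k 4
```

## Layout

| module | contents |
| --- | --- |
| `core_data` | occurrence/grid/metadata I/O, `DistanceMatrix`, merging, endemism split, high-elevation filter, pool summary |
| `env_features` | the 22 environmental/altitudinal variables; lithology composition table |
| `synthetic_data` | scenario configs, landscape + flora generators, ground truth |
| `dissimilarity` | Sørensen, Bray–Curtis, standardized Euclidean, geographic distances |
| `bioenv` | exhaustive BIO-ENV subset search |
| `clustering` | UPGMA, multiscale bootstrap, AU/BP support |
| `ordination` | CA, DCA (detrending by segments), correlation PCA |
| `mrm_partition` | alpha regressions, MRM, variance partitioning, resampling robustness |
| `pipeline` / `cli` | YAML-configured end-to-end runner and the `ecoregion-beta` command |

See `docs/methods.md` for the statistical details and design choices.
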