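# florashift

Scenario analysis of **biotic homogenization** in plant communities:
temporal change in species and phylogenetic α- and β-diversity between a
pre-Columbian ("Holocene") baseline flora and a modern ("Anthropocene")
flora that has lost recently extinct and threatened species and gained
naturalized non-natives.

The package is aimed at macroecologists working with cell × species
presence/absence matrices on a TDWG-like spatial hierarchy (grid cells
nested in level-3 botanical regions nested in level-1 continents) and a
rooted, dated phylogeny. Because the global inputs such analyses use
(stacked species distribution models, naturalization checklists, dated
mega-phylogenies) are enormous, the package ships a synthetic flora
generator that reproduces their statistical structure at desk scale, so
every stage of the analysis is runnable and testable from a cold start
with no downloads.

## The quantities computed

For each grid cell and epoch:

- **Species richness** — count of species present.
- **Faith's phylogenetic diversity (PD)** — the summed branch lengths
  (in millions of years, myr) of the union of root-to-tip paths of the
  cell's species on the dated tree (rooted PD).
- **SES-PD** — PD standardized for richness: z = (observed − null mean) /
  null SD, with the null formed by shuffling tip labels on the phylogeny
  (1000 randomizations by default).
- **β-diversity** — each cell's mean pairwise dissimilarity to the other
  cells of its level-3 region, using Simpson turnover
  βsim = min(b, c) / (a + min(b, c)) by default (Sorensen and Jaccard as
  sensitivity variants), at both the species level (a, b, c are shared /
  unique species counts) and the phylogenetic level (a, b, c are shared /
  unique branch lengths).

Temporal change uses relative differences between the Anthropocene (j)
and Holocene (i) epochs:

    Δα = (αj − αi) / αi        Δβ = (βj − βi) / βi

Negative Δβ means cells within a region became compositionally more
similar — biotic homogenization.

Six scenarios define the Anthropocene flora: *no extinctions*
(naturalizations only), *no superinvasives* (excluding non-natives whose
invaded range size within a region exceeds Q3 + 1.5×IQR), *best case*
(recent extinctions + naturalizations), *business as usual* (also losing
CR species), *increased extinction* (CR + EN), and *worst case* (CR + EN +
VU). Category-specific 100-year extinction probabilities (LC 0.001 …
CR 0.999) power an optional stochastic extinction sampler.

Two further analyses:

- **Continental exchange** — donor→recipient flow matrices of naturalized
  species counts and of the PD they carry (branch-set unions, medians
  across a tree set), plus the net PD gained by each recipient per species
  exchanged, and Spearman correlations of the family composition of
  receipts between continents.
- **Darwin's naturalization hypothesis** — per region, the mean patristic
  distance from each non-native to its nearest native neighbor, tested
  against a tip-shuffle null over the regional species pool (add-one
  permutation p-values); plus a one-sided test of whether superinvaders
  are more closely related to other non-natives than chance.

## Worked example

```python
from florashift.synthetic import SimulationConfig, generate_dataset
from florashift.scenarios import build_epoch_matrix
from florashift.beta import region_mean_dissimilarity

tree, natives, status, hierarchy = generate_dataset(SimulationConfig(seed=42))
holo = build_epoch_matrix("HOLOCENE", "BEST_CASE", natives, status, hierarchy)
anthro = build_epoch_matrix("ANTHROPOCENE", "BEST_CASE", natives, status, hierarchy)
for level in ("taxonomic", "phylogenetic"):
    bi = region_mean_dissimilarity(holo, hierarchy, "simpson", level, tree)
    bj = region_mean_dissimilarity(anthro, hierarchy, "simpson", level, tree)
    print(level, round(float(((bj - bi) / bi).median()), 4))
```

prints

```
taxonomic -0.2087
phylogenetic -0.2214
```

i.e. on this simulated flora (200 species, 10 naturalized, 1 recently
extinct) the median cell's within-region Simpson turnover drops by ~21%
(species) and ~22% (phylogenetic) from the Holocene to the best-case
Anthropocene — homogenization driven almost entirely by naturalizations,
since rerunning with `naturalized_fraction=0.0` yields a median Δβ of 0.

The same analyses are packaged as numbered drivers:

```bash
python analysis/01_simulate_flora.py  --seed 0   # writes results/data/
python analysis/02_scenario_changes.py --seed 0  # Δα/Δβ per scenario
python analysis/03_exchange_flows.py  --seed 0   # continental flows
python analysis/04_darwin_tests.py    --seed 0   # regional Darwin tests
```

and as a CLI (`florashift simulate|alpha|beta|exchange|darwin|run`).

## Layout

- `src/florashift/` — the library: `tree` (phylogeny + newick I/O),
  `community` (matrices, statuses, hierarchy, change tables), `synthetic`
  (dataset generator), `scenarios`, `alpha`, `beta`, `exchange`,
  `darwin`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite with brute-force oracles and permutation-null
  calibration checks.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
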