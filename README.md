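# riverdrift

Microbial community drift analysis along lake-to-river transects.

When a river rises from a lake, the planktonic bacterial and protist
communities it inherits do not simply ride downstream: lake-adapted taxa
(*Cyanobium*-like picocyanobacteria, *Verrucomicrobia*, ciliates) fall away
within kilometers, while river-adapted taxa (*Pseudarcicella*-like
*Bacteroidetes*, *Limnohabitans*) rise and quickly dominate. `riverdrift`
packages the statistics needed to quantify that turnover from replicated
16S/18S OTU count tables collected at ordered sites along a transect —
without any wet-lab upstream: the pipeline starts at the OTU table.

It is written for microbial ecologists working on river continua, drinking
water-source surveys, or any ordered environmental gradient with duplicate
amplicon sampling.

## What it computes

* **Preprocessing** — taxon exclusion by lineage rank, seeded rarefaction
  to uniform depth, the duplicate-consistency rule (an OTU counts as
  detected at a site only if present in *all* duplicates), site-level
  averaging of relative proportions, and dominant-OTU subsets (e.g. the
  "0.1% subset" of OTUs holding ≥ 0.1% of all sequences).
* **Community drift** — Bray–Curtis dissimilarity
  `BC(x, y) = 1 − 2·Σᵢ min(xᵢ, yᵢ) / (Σᵢ xᵢ + Σᵢ yᵢ)` between the lake and
  each river site, its Pearson regression against channel distance, UPGMA
  dendrograms (newick export), and detected-OTU richness trends.
* **Trajectory classes** — each OTU's ordered presence/absence series
  (lake → terminal site) is partitioned into **stable** (1…1), **lost**
  (1ᵃ0ᵇ), **emerging** (0ᵃ1ᵇ) or **unstable** (anything else), with
  appearance/disappearance distance brackets and attribution of
  terminal-site OTUs to their upstream origins (lake and/or tributaries).
* **Covariation networks** — pairwise Pearson `r` with two-sided
  `t`-distributed p-values among dominant OTUs and environmental
  parameters, distance-trend classes at p < 0.05, graph edges at p < 0.01,
  and a seeded Fruchterman–Reingold layout weighted by |r|.
* **Absolute abundance kinetics** — theoretical abundances
  (relative proportion × qPCR 16S total, copies/mL; no per-cell copy-number
  correction) and exponential-phase doubling times
  `t_d = transit · ln 2 / ln(n_f / n_0)`.
* **Synthetic transects** — a generator producing replicated count tables,
  environmental gradients and qPCR totals for a parameterized
  lake → river → tributary design, with ground-truth trajectory/trend/origin
  labels for every simulated OTU, so the whole pipeline is testable with no
  external data.

## Worked example

```python
import riverdrift as rd

design = rd.with_seed(rd.default_design(), 7)   # 1 lake + 20 river sites + 4 tributaries
table, metadata, truth = rd.simulate_counts(design)
props = rd.preprocess_pipeline(table, metadata, subset=0.001, seed=7)

series, reg = rd.drift_to_source(props, metadata)
print(f"Bray-Curtis drift: {series.iloc[0]:.3f} at {series.index[0]:.0f} m -> "
      f"{series.iloc[-1]:.3f} at {series.index[-1]:.0f} m (r = {reg.r:.2f}, p = {reg.p_value:.1e})")

profiles = rd.detection_profiles(props, metadata)
print(rd.summarize_classes(profiles).round(3))

td = rd.doubling_time(8.4e3, 1.14e5, 180.0)
print(f"doubling time: {td.minutes:.1f} min")
```

prints

```
Bray-Curtis drift: 0.023 at 48 m -> 0.485 at 11000 m (r = 0.95, p = 9.0e-11)
            count  fraction  lost_lake_only
trajectory
stable         63     0.808               0
unstable        0     0.000               0
emerging        9     0.115               0
lost            6     0.077               0
doubling time: 47.8 min
```

The drift line says community composition moves steadily away from the lake
source: dissimilarity climbs from near-identity 48 m below the outlet to
~0.5 (half the community mass turned over) 11 km downstream, almost
linearly in distance (Pearson r = 0.95). The class table covers the
dominant (0.1%-subset) OTUs: most persist the whole transect, six lake taxa
drop below detection partway down, and nine taxa emerge — risers crossing
the detection limit plus tributary inocula. The doubling time converts an
observed abundance gain (8.4×10³ → 1.14×10⁵ copies/mL over a ~3 h water
transit) into an apparent exponential doubling of ~48 min — implausibly
fast for in-stream growth alone, which is exactly the kind of kinetic
sanity check the function is for.

The same chain is available from a shell:

```sh
riverdrift simulate --seed 7 --out sim/
riverdrift preprocess --otu sim/otu_table.tsv --taxonomy sim/taxonomy.tsv \
    --meta sim/metadata.tsv --subset 0.001 --seed 7 --out props/
riverdrift drift --props props/ --meta sim/metadata.tsv --out drift/
riverdrift classify --props props/ --meta sim/metadata.tsv --out classes/
riverdrift network --props props/ --env sim/env.tsv --meta sim/metadata.tsv --out net/
```

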