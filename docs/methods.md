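# Methods

## Data model and preprocessing

The unit of analysis is an OTU count table (samples × OTUs, non-negative
integers) with duplicate samples per site, plus transect metadata: one lake
site at 0 m, river sites ordered by cumulative channel distance from the
lake, and tributary sites carrying the distance of their confluence.
Distances are meters; sites are always handled upstream → downstream by
increasing distance. Tributary samples never enter distance regressions or
trajectory series; they serve only origin attribution and the dendrogram.

Preprocessing runs in a fixed, enforced order:

1. **filter_taxa** — an OTU is dropped iff any excluded keyword matches a
   whole lineage rank, case-insensitively (`Chloroplast` matches the rank
   `Chloroplast`, not `Chloroplastida`). Untaxonomized OTUs are kept and
   logged.
2. **rarefy** — one seeded multivariate-hypergeometric draw per sample
   (subsampling without replacement) to a common depth; `depth="min"`
   resolves to the smallest sample total. A single draw, not a
   multiple-rarefaction average: downstream detection rules are defined on
   one realized table.
3. **duplicate_consistency** — "detected" means count ≥ 1 in *all*
   duplicates of a site. This is deliberately a per-site rule: a global
   reading (present in every duplicate of every sample) would empty the
   table. OTUs detected at no site are removed entirely.
4. **average_duplicates** — relative proportions per duplicate, arithmetic
   mean per site. Averaging happens after the detection flags are frozen,
   so a non-detected OTU can still carry a (small) proportion.
5. **abundance_subset** — an OTU is kept iff its pre-averaging sequence
   total is ≥ θ × the grand total (θ = 0.001 for the "0.1% subset"). Totals
   are sequence counts, not mean proportions, and each gene domain's table
   is subset against its own grand total. Subsets are nested and composing
   two thresholds equals applying the larger.

Out-of-order calls raise `PipelineOrderError`; each stage records itself in
the table's provenance.

## Drift, clustering, trends

Bray–Curtis dissimilarity BC(x, y) = 1 − 2Σmin(xᵢ, yᵢ)/(Σxᵢ + Σyᵢ) is
computed on site-averaged proportion vectors (optionally on raw duplicate
counts for the duplicate-level dendrogram). Drift-to-source is the series
BC(lake, river site) regressed (Pearson, two-sided t-based p) on distance
over river sites only — the lake's own BC = 0 anchor is excluded so it
cannot inflate the correlation.

All correlation statistics in the package are signed Pearson r with
two-sided p-values from t = r√(n−2)/√(1−r²) on n−2 degrees of freedom.
Zero-variance series raise a dedicated `ConstantSeriesError`, which
callers that document a degenerate NaN (drift, richness, qPCR check)
convert to a flagged NaN.

UPGMA uses scipy's average-linkage agglomeration (deterministic
lowest-index tie-breaking). Dendrogram node heights are half the merge
dissimilarity, so the exported newick is ultrametric and the tip-to-tip
path length between two leaves equals their cophenetic distance; a 2-leaf
tree merged at 0.4 serializes as `(A:0.2,B:0.2);`.

Distance-trend classes: decreasing iff r < 0 and p < 0.05, increasing iff
r > 0 and p < 0.05, else none. Covariation-network edges require p < 0.01.
No multiple-testing correction is applied by default at either threshold —
the raw-p convention of the correlation-network literature — and a
Benjamini–Hochberg option exists but is off, with its effect logged. The
Fruchterman–Reingold layout (networkx, seeded) uses |r| as edge weight so
strongly covarying nodes attract.

## Trajectory classification

Each OTU's detection series s₀…sₙ (s₀ = lake) is classified:
stable = all ones; lost = 1ᵃ0ᵇ (a, b ≥ 1); emerging = 0ᵃ1ᵇ; unstable =
everything else. The four classes partition all 2ⁿ⁺¹ series (verified
exhaustively against a regular-expression oracle up to n = 6). Choices the
definitions leave open, resolved here:

* the lake-only pattern 1 0ⁿ counts as lost, and is flagged separately in
  summaries (`lost_lake_only`);
* emerging is strict: one missed site after first detection demotes the
  OTU to unstable;
* the all-absent series cannot occur after duplicate-consistency filtering
  and is classed unstable if constructed directly.

Lost/emerging OTUs get distance brackets: (last present, first absent] and
(last absent, first present] respectively. Origin classes at the terminal
site: lake_and_tributaries / tributaries_only / lake_only / neither, from
the duplicate-consistent detection flags at the lake and each tributary.

## qPCR scaling

Theoretical absolute abundance = relative proportion × qPCR total
(16S rRNA gene copies per mL of filtered water). No 16S-copies-per-cell
correction is applied — outputs are gene copies, not cells, and the CLI
writes that caveat into every output header. Doubling time over a transit
of T minutes is t_d = T·ln2/ln(n_f/n₀); n_f ≤ n₀ is reported explicitly as
non-growth (negative or infinite t_d) rather than masked. Error
propagation from qPCR standard deviations is a first-order delta-method
option, off by default.

## The synthetic transect generator

The generator emulates a ~11 km lake-fed meandering river: 1 lake + 20
river sites (48 m … 11,000 m, anchor distances matching a realistic
end-of-summer survey), 4 tributaries at 1.2 / 7.0 / 10.0 / 10.95 km each
contributing a flow fraction f = 0.1 (small tributaries at low flow), 2
duplicates per site, and fixed sequencing depth — 36,180 reads for the
bacteria-like table, 10,075 for the eukaryote-like table (typical
post-rarefaction depths for paired 16S/18S surveys).

Mean model (unnormalized mass at distance d, in km):

* `lake_decaying`: p₀·e^(−λd) — λ in 1/km;
* `river_rising`: p_max·σ(k(d − d₀)) — logistic with midpoint d₀ and rate k;
* `stable`: p₀;
* `tributary_seeded`: 0 upstream; f·p_trib at the confluence;
* `rare_intermittent`: p₀, toggled per site by an occupancy probability.

At a confluence with fraction f every mass becomes (1−f)·upstream +
f·tributary; a bulk OTU absorbs the residual at each site so expected
proportions are an exact probability vector (mass lost to decay is
interpreted as growth of the undifferentiated bulk community). Tributary
communities are their seeded OTUs plus a tributary-specific bulk OTU,
which keeps tributaries compositionally distinct (they cluster outside the
lake+river clade, as expected for side streams). Sequencing noise is one
independent multinomial draw per duplicate at fixed depth — matching
rarefied data — with an optional Dirichlet-multinomial overdispersion
switch (off by default; no dispersion estimate to calibrate it against).
When an intermittent OTU is toggled off, its mass moves to the bulk OTU so
every other OTU keeps its exact mean-model proportion.

Environmental parameters are linear in distance with Gaussian noise;
default endpoints mimic a late-summer lake-to-river gradient (temperature
15 → 12 °C and TOC 4.36 → 3.63 mg C/L decreasing; turbidity, total N,
NO₃⁻/NO₂⁻, conductivity, alkalinity, apparent color increasing; pH and
total P trendless), with distinct tributary values. qPCR totals are drawn
around a constant 5.4×10⁵ ± 1.4×10⁵ copies/mL with no distance trend.

### Parameter placement (why these defaults)

Trajectory recoverability is governed by where an OTU's *expected count*
crosses the 1-read detection boundary and how fast it crosses. A decaying
OTU's crossing sits at d* = ln(p₀·depth)/λ, and the realized
presence/absence pattern near d* is stochastic over roughly the sites
where the expected count lies between ~5 and ~0.2 reads. The default
bacteria design therefore uses:

* 6 fast decayers (p₀ 0.04 … 0.006) with crossings staggered at
  2.0–6.8 km — these are the "lost" class; the ±1-site fuzziness at each
  crossing contributes an expected ≲1 misclassified OTU per simulation;
* 7 slow decayers (p₀ 0.08 … 0.015, λ 0.05–0.3/km) that decline throughout
  but never cross the boundary — trajectory-stable, trend-negative. Their
  role is to spread compositional turnover over the full 11 km so the
  Bray–Curtis drift rises progressively (mean-model drift r ≈ 0.95)
  instead of saturating after the first kilometers;
* 2 logistic risers with midpoints at 2–3 km and rates set so the lake
  expectation sits ≥ ~4 nats below one read (emerging, never
  lake-detected);
* 3 tributary-seeded OTUs (Jaune ×2, Nelson ×1) — exactly zero upstream
  mass, so their appearance brackets necessarily contain their confluence;
* 55 stable OTUs (p₀ 0.0015–0.015, geometric), 3 low-abundance
  contaminant OTUs carrying excluded lineages (exercising filter_taxa),
  and 300 rare intermittent OTUs (p₀ ~2–8×10⁻⁵, occupancy 0.3–0.8) that
  produce the dominant "unstable" fraction of the unfiltered table.

With ~75–80 OTUs in the 0.1% subset and ~1 expected boundary
misclassification, ground-truth trajectory recovery exceeds 95% with large
margin for essentially all seeds. The eukaryote design is analogous at
depth 10,075 (1 sharply lost ciliate, 5 slow decayers, 7 risers, 2
tributary inocula, 30 stable, 200 rare).

Ground-truth labels are functions of the design only: the trajectory label
applies the classifier to the expected detection pattern
(depth × mean proportion ≥ 1 read); intermittent-occupancy OTUs are
unstable by construction. The trend label is the sign of the mean-model
slope over river sites, with a 2% relative-range tolerance for flatness —
without the tolerance every OTU would be non-flat because confluence
dilution perturbs all proportions. Note this makes plain stable OTUs
trend-negative on a transect with tributaries: constant-presence taxa are
genuinely diluted ~10% at each confluence.

### What the generator does not emulate

No hydrodynamics (dispersion, storage zones, variable velocity), no
temporal dynamics or seasonality, no sequence-level artifacts (chimeras,
primer bias, copy-number variation), no spatial autocorrelation of the
environmental noise, and no abundance coupling between OTUs beyond the
shared simplex constraint. Passing recovery tests therefore demonstrates
that the statistics recover a known spatial structure under realistic
multinomial sampling noise — not that real rivers satisfy the mean model.

## Numerical and scale choices

* Rarefaction, multinomial draws, occupancy toggles, environmental noise
  and layouts all consume a single seeded `numpy` Generator; identical
  seeds give byte-identical outputs.
* Dissimilarity matrices are validated (symmetry 1e-12, zero diagonal,
  [0, 1], no NaN) before clustering; newick round-trips preserve topology
  and leaf-to-root distances within 1e-9.
* Test problem sizes — 100 random 6×6 matrices for the UPGMA oracle,
  exhaustive series to length 7 for the partition oracle, 1000 null
  variables × 20 sites for calibration, one full-depth simulated transect
  per session — were chosen as the smallest sizes at which each check is
  conclusive; the whole suite runs in well under a minute.
* BIOM input is parsed from the 1.0 JSON dialect (dense and sparse);
  tables, metadata, trees and configs are otherwise plain TSV/newick/YAML.

## Known limitations

* The duplicate-consistency rule assumes a constant number of duplicates
  per site; unpaired duplicates are an error, not a warning.
* Trend classes and network edges use raw p-values by design; with ~10³
  OTU pairs the expected false-edge count at p < 0.01 is material, and the
  BH option should be used when edge lists feed downstream inference.
* `theoretical_abundance` inherits all qPCR biases (extraction efficiency,
  16S copy number); doubling times additionally assume plug-flow transit
  at the quoted travel time.
* The generator's archetypes are monotone in distance (plus intermittent
  noise); it cannot produce mid-transect blooms or U-shaped profiles, so
  classifier behaviour on such patterns is covered only by the exhaustive
  enumeration tests, not by recovery tests.
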