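# Methods

## Scope and data model

The package analyses two-group (PFF-treated vs PBS-control) quantitative
proteomics experiments: TMT 11-plex total and phosphosite tables (ten
analytic channels plus one pooled reference per plex/timepoint) and
label-free runs of the detergent-insoluble fraction.  All intensities are
log2-transformed at ingestion and every statistic operates on the log2
scale, so the published fold-change thresholds apply directly.  Gene
symbols are uppercased at every ingestion point because mouse-derived
tables must join against human-centric PPI resources; symbol-case mismatch
is the dominant join failure in practice.  Each plex/timepoint is analysed
independently — no cross-plex normalization is attempted, and the pooled
channel is removed before testing.

## Preprocessing cascade

Canonical stage order: flag filters → drop pooled channel → zeros→missing →
global observed filter → median normalization → (optional quantile
normalization) → per-condition missingness filter → sample-outlier removal
→ imputation.  Filters must see missingness before imputation erases it,
and normalizing before imputing keeps the imputation per-sample-calibrated.
The source protocols list these steps in mutually inconsistent orders
across the total and phospho descriptions; this order is the one under
which each step's stated precondition holds.

- **Flag filters.** Protein tables drop reverse-decoy, contaminant and
  only-identified-by-site rows and require > 1 peptide and ≥ 1 unique
  peptide.  Phosphosite tables drop only rows whose leading protein is a
  contaminant (site evidence is not peptide-count based).
- **Observed-fraction filters.** "> 50 % observed" and "> 20 % missing"
  are applied with strict inequality on the fraction, matching the printed
  operators; a feature fails the condition filter if any single treatment
  group exceeds the missing bound (a per-run variant is available via
  `condition_missing_scope="all"`).
- **Median normalization** subtracts each sample's median of observed
  values and adds back the grand median of medians (equivalent to
  raw-scale division, numerically stabler; idempotent and order-preserving
  within samples).  Quantile normalization is provided but off by default:
  the protocols' single mention of "quantile-normalized intensities" most
  plausibly refers loosely to the median step, and a rank-destroying second
  normalization is not something to switch on silently.
- **Outlier removal.** PCA on complete features only, samples mean-centred
  per feature; a sample is flagged when the robust z of its PC1–2 centroid
  distance exceeds 4.  The robust scale is `max(1.4826·MAD, 0.25·median)`:
  centroid distances of a homogeneous design form a tight chi-like cloud
  whose MAD can be a tiny fraction of the typical distance, and without the
  floor ordinary samples at 1.5× the median distance get flagged.  With it,
  a flag requires ≥ 2× the typical distance; a gross (+10 log2 unit)
  shifted sample is still flagged by a wide margin.  The source analysis
  removed one PCA outlier without stating a criterion; this rule is the
  package's own.
- **Imputation.** Downshifted normal, the de-facto standard for
  left-censored proteomics missingness: per sample with observed mean m and
  sd s, missing cells draw independently from Normal(m − 1.8·s, (0.3·s)²).
  Width 0.3 and shift 1.8 are the community defaults since the protocols
  give none.  Observed cells are never altered; draws are seeded.

## Differential abundance

Two-group comparison with no covariates.  Per feature the pooled variance
s² has df = n₁+n₂−2.  The variance prior (d₀, s₀²) is fitted by moment
matching on log variances: with e = log s² − ψ(df/2) + log(df/2), the
excess of Var(e) beyond ψ′(df/2) equals ψ′(d₀/2), inverted by Newton
iteration (tolerance 1e−8); s₀² follows from the matched mean.  When the
empirical variance shows no excess, d₀ = ∞ and s₀² is the mean variance.
The moderated statistic uses s²post = (d₀s₀² + df·s²)/(d₀ + df) and is
referred to t(df + d₀), the standard normal in the d₀ → ∞ limit.  With
d₀ = 0 it reduces exactly to the classical pooled t (verified to 1e−10),
and the whole fit matches Bioconductor limma on shared input (cross-checked
in the test suite via Rscript).  BH adjustment is the plain step-up,
shared between the differential and enrichment modules.

Calls: `up` if log2FC > cutoff and padj < 0.05, `down` symmetric, else
`ns`; the insoluble fraction uses ≥ on the fold change, following its
printed operator.  Phosphosite seed lists collapse to leading-protein
symbols, keeping a protein if any site passes — network nodes are proteins.

## Networks, modules, enrichment

Edge confidence filtering uses ≥ so a cutoff of 0.999 retains edges scored
exactly 0.999.  The zero-order network is the induced subgraph on seeds;
the first-order network is the induced subgraph on seeds ∪ direct
neighbors, including neighbor–neighbor edges (matching common PPI-tool
behavior and yielding richer intersections); a `seed_incident` mode keeps
only seed-touching edges for the narrower reading.  Unmapped seeds are
reported, never silently dropped.  Both constructions equal exhaustive
edge-scan oracles on random graphs (tested on 100 graphs up to 50 nodes).

Module detection is greedy modularity maximization (Clauset–Newman–Moore
via networkx) with deterministic ordering; module ids are assigned by
decreasing size with lexicographic tie-break, isolated nodes become
singletons, and an edgeless graph yields the all-singleton partition with
modularity 0.  The source study used an undisclosed internal clustering
tool, so any deterministic modularity method is a legitimate stand-in; on
planted partitions (3 modules × 20 nodes, p_within = 0.5,
p_between = 0.02) recovery is essentially perfect (mean ARI ≥ 0.99).

Over-representation uses the exact hypergeometric upper tail P[X ≥ k]
(observed overlap included), BH-adjusted across the collection, with query
and sets intersected with the universe first.  The universe defaults to
the quantified background (features surviving preprocessing) rather than
the whole genome — the standard guard against detection-bias inflation;
the enrichment background of the source analysis is unstated.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the mass spectrometry itself:

| parameter | default | meaning |
|---|---|---|
| baseline | Normal(25, 2) log2 units | MS-like intensity range; keeps censoring meaningful |
| n_per_group | 5 | channels per treatment, plus 1 pooled |
| de_fraction | 0.1 | fraction of features with planted effects |
| lfc_magnitude | 1.0 log2 units | planted |effect|, signs split 50/50 |
| noise_sd | 0.25 log2 units | per-channel Gaussian noise |
| censor_quantile | 0.05 | per-sample left-censoring threshold (MNAR) |
| mar_rate | 0.01 | independent random dropout |
| flag_rates | 0.01 each | reverse / contaminant / site-only |
| peptide counts | 1 + Poisson(3) | evidence filter behavior only |

The pooled channel is the per-feature mean of analytic channels plus
noise.  The per-channel variance and missingness rates of the original
study are unpublished; these defaults are stand-ins exposed in the config.

Planted effects are never assigned to artifact rows (decoy, contaminant,
site-only, or ≤ 1 peptide): a fold change planted on a row the filters must
remove is unobservable by construction, so a truth defined there would
measure the flag lottery rather than the pipeline.  Flags remain mutually
independent across the remaining features, and explicitly planted features
get their evidence guaranteed.  Losses that are genuine properties of the
method — planted features falling into the censored low-intensity tail,
and variance inflation from downshifted imputation — are deliberately left
in, which is why demo recall sits near 0.85 rather than 1.0.

PPI graphs are planted partitions: equal-size modules, intra-module edges
with probability p_within and confidence ~ Normal(conf_within, 2e−4)
clipped to [0,1], inter-module edges analogously.  Gene sets are one exact
set per planted module plus random decoys.  The label-free generator
shifts each sample by log2(loading_scale) to emulate loading differences,
which the insoluble pipeline divides back out.

What the generator does **not** emulate: reporter-ion interference and
ratio compression, peptide-to-protein roll-up, batch effects across
plexes, correlated missingness, heavy-tailed noise, and scale-free PPI
topology.  Passing tests therefore demonstrate correctness of the
statistical machinery under its own assumptions, not robustness to every
pathology of real MS data.

## End-to-end demo and problem sizes

The demo builds one 60-node/3-module graph (conf_within = 0.9995 so the
0.999 cutoff retains intra-module edges, conf_between = 0.8 so it removes
the rest); each module contributes five genes to each of the four seed
lists (total up/down at |log2FC| = 1, phospho up/down at |log2FC| = 2 on
all three sites), so the four first-order networks jointly cover the
modules and their intersection recovers the planted structure.  Tables are
2000 proteins / 1200 phosphosites / 800 insoluble proteins with 270 / 180 /
75 planted effects — sizes chosen so the scorecard's recall estimates have
Monte-Carlo sd ≈ 0.02 while the demo completes in seconds.  The acceptance
script uses 200 null replicates and 50 planted replicates of 2000-feature
experiments for the error-control and power estimates, 100 random graphs
for the network oracles, and 20 planted partitions for module recovery.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; identical seeds reproduce tables, networks,
artifacts and manifests bit-identically (manifests record sha256 checksums
per artifact).

## Known limitations

- Two-group designs only: no covariates, time-course modeling, or
  multi-factor contrasts.
- No protein-level phospho-occupancy correction; sites are tested as
  independent features.
- No live queries to interaction or enrichment services; users supply edge
  tables and GMT files.
- The moderated test assumes (approximately) normal log2 intensities after
  imputation; heavy contamination of a sample violates this upstream of
  the outlier guard.
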