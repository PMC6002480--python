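# Methods

## The question and the objects

In mixed natural forests, negative conspecific density dependence predicts
that the neighbourhood of a tree becomes more heterospecific as the tree
grows: crowded conspecific juveniles are thinned out, and the survivors end
up surrounded by other species. `treemingle` quantifies this with marked
point-pattern statistics on stem-mapped census plots — one record per stem
with position (x, y in metres), species label, and diameter at breast height
(dbh, cm) inside a rectangular observation window.

Two complementary summaries are used.

### Nearest-neighbour mingling index

For reference tree *i* with *k* nearest neighbours (default *k* = 4),

    M_i = (1/k) * sum_j 1(species_j != species_i)

over those neighbours, so M_i ∈ {0, 0.25, 0.5, 0.75, 1} for *k* = 4.
Because stems with no heterospecific neighbour are rare in the plots this
package emulates (under 5%), levels 0 and 0.25 are pooled, giving four
grouped levels. Community-level association between size and mingling is
assessed by (a) two-sided Wilcoxon rank-sum tests of dbh between every pair
of grouped levels, Holm-adjusted, rendered as a compact letter display, and
(b) a bivariate dbh × mingling-level density in which mingling is treated as
a discrete factor: one Gaussian kernel density of dbh per level, weighted by
the level's relative frequency, so the full array has unit mass. A
continuous two-dimensional kernel over a five-valued mark would be
ill-posed, which is why the factor treatment is used. The default bandwidth
is Silverman's rule on the pooled dbh sample — one common bandwidth keeps
level profiles comparable.

The rank-sum test uses the exact null distribution when both groups have at
most 20 observations and the pooled sample is tie-free, and the
tie-corrected normal approximation otherwise. Holm's correction was chosen
because it is assumption-free and conservative; the letter display derives
directly from the adjusted pairwise decisions (levels sharing a letter are
not significantly different).

### Cumulative mark mingling functions

The scale-dependent counterpart accumulates the heterospecific indicator
over all ordered tree pairs within distance *r*:

    K_m(r) = (1/l²)(1/A) Σ_i Σ_{j≠i} 1(m_i≠m_j) 1(d_ij ≤ r) w_ij
    k_m(r) = Σ 1(m_i≠m_j) 1(d_ij ≤ r) w_ij / Σ 1(d_ij ≤ r) w_ij

with intensity estimate l = n/A and translation edge-correction weights
w_ij = ab/((a−|Δx|)(b−|Δy|)) for a window of sides a × b. K_m mixes the
unmarked pattern with the mark correlation; the ratio form k_m(r) removes
the former and reads as the edge-corrected proportion of heterospecific
pairs within *r* — a value in [0, 1].

For a size class *d* (default: small 5–10 cm, medium 10–25 cm, large
> 25 cm, with the 10 cm boundary in medium and the 25 cm boundary in
medium), the reference index *i* runs over class-*d* trees while the
partner *j* ranges over **all** trees. The class curve can be normalised by
its expectation under a random arrangement of species,

    EM_d = Σ_i n_di (n − n_i) / (n_d (n − 1)),

so values below/above 1 read directly as less/more mingling than expected.
Size-class contrasts use the difference of the **non-normalised** curves,
Δk_v(r) = k_hi(r) − k_lo(r) ∈ [−1, 1]; positive values mean the larger
class has more heterospecific neighbourhoods at that scale.

Numerical conventions: the distance condition is the closed ball d ≤ r; the
grid excludes r = 0, so self-pairs never contribute and duplicate
coordinates enter at the first positive grid point; curve values are NaN
(not zero) wherever no admissible pair exists; the default grid (r ≤ 30 m
in 0.25 m steps) covers the scales at which tree interactions are typically
expressed while staying below the window quarter-side, which also
guarantees every pair displacement has a defined translation weight.

## Null models and envelopes

The null of *independent marking* — marks unrelated to locations — is
emulated by retaining every tree's (species, dbh) pair and redistributing
locations:

* **homogeneous Poisson**: uniform independent positions (conditioned on
  the observed count), removing all spatial structure;
* **heterogeneous Poisson**: per-species positions rejection-sampled from a
  species-specific intensity surface λ(x, y), removing small-scale
  interaction while preserving habitat-scale structure. λ is a
  moving-window estimate: counts in a 20 m-radius disc divided by the
  disc area clipped to the window (a uniform-disc kernel with local edge
  correction), evaluated on a 1 m grid and rescaled so the surface
  integrates exactly to the species count. The 20 m radius sits above
  typical interaction ranges, so structure below that scale is randomised.
  Relocation is conditional on the observed per-species counts — existing
  trees are redistributed, not re-drawn in number.

Envelopes are pointwise 2.5%/97.5% empirical quantiles over `nsim`
replicates (1000 by default, matching the reference experiment), with the
pointwise mean as the null-expectation curve. A master seed spawns one
substream per replicate, so runs are reproducible and the first *k*
replicates are identical for any `nsim ≥ k`. Pointwise bands carry the
usual multiple-testing caveat across r; no global rank-envelope correction
is applied (documented limitation).

## Synthetic data

Real mapped census plots for this analysis are not publicly deposited, so
the package ships two generators; their defaults are the study conditions
under which all statistical claims are tested.

**Dependent marking (two species).** Locations are homogeneous Poisson with
intensity 0.1 trees/m² on 100 × 100 m (≈ 1000 stems — a realistic 1-ha
density). A tree becomes species 1 ("common, small", mean dbh 20 cm) when
its second-nearest neighbour lies within r0 = 2.5 m, species 2 ("less
abundant, large", mean dbh 30 cm) otherwise — aggregating conspecifics.
dbh is normal per species, truncated below at the 5 cm census threshold;
the 5 cm standard deviation is a package choice that keeps species 1 mostly
at or below the 25 cm large-tree threshold and species 2 mostly above it,
which the construction requires. Finally every tree with dbh > 25 cm, in
ascending id order (later assignments overriding earlier ones — any fixed
order works and this one is reproducible), sets its nearest neighbour's
species to the opposite mark, creating heterospecific close neighbourhoods
around large trees. Ignoring edge effects, the species-2 fraction before
this last step has the closed form exp(−λπr0²)(1 + λπr0²) ≈ 0.416; the
simulator reproduces it to within the edge-effect bias (border trees see
inflated second-neighbour distances, raising the fraction by ≈ 0.01). The
point count is Poisson(λA) by default; an exact count can be requested via
`fixed_n`.

**Community emulator (multi-species).** Per species, a Thomas-type cluster
process: Poisson-many uniform parents (default 15/ha), offspring attached
to random parents with isotropic Gaussian displacements (default sd 5 m),
conditioned on the requested abundance, with truncated-normal dbh. Two
presets encode the composition contrast that drives null expectations of
Δk_v: `shared_size_community` (four species, one common dbh distribution —
null Δ expectation ≈ 0) and `rare_large_community` (three abundant
small-dbh species plus one rare large-dbh species — null Δ expectation
clearly positive, because large stems are mostly of the rare species whose
expected mingling is high). Note that even with a shared size distribution
a single realised community carries species-composition noise in EM_d of
order 0.01–0.02 at these abundances; "approximately zero" is meant at the
scale of the difference curves (±0.3), not exactly zero.

What the generators do **not** emulate: real plots have more species,
habitat heterogeneity correlated with topography, size-dependent thinning
histories, and measurement idiosyncrasies. Passing tests therefore validate
the estimators and the machinery, not ecological conclusions about any real
stand.

## Known limitations and open choices

* Every tree serves as a reference for M_i, including border trees whose
  true neighbours may stand outside the window; no nearest-neighbour edge
  correction is applied. This biases border M_i toward the plot interior's
  composition and is logged as a caveat.
* Distance ties in neighbour queries are broken by ascending tree id —
  deterministic and order-independent once ids are assigned.
* Envelopes are pointwise; excursion statements at "short range" scan
  r ≤ 8 m and are therefore mildly liberal under the null.
* The rectangular-window translation weight is the standard closed form;
  irregular windows are out of scope.
* Analysis problem sizes in the test-suite and the reproduction script
  (grids to 12–20 m at 0.5–1 m steps, 199 replicates for repeated runs,
  1000 for the single full run, 100–200 coverage trials) were chosen to
  give stable Monte-Carlo verdicts at plot-scale patterns; all are
  configurable.
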