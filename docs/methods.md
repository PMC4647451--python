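# Methods

## The model

The unit of the utilization analysis is the plant family.  A regional
reference set (a flora database extract, or a traditional-medicines
database) contributes `n` taxa for a family; the focal survey reports `x`
of them as medicinally used.  Treating each taxon's use status as an
exchangeable Bernoulli outcome with family-specific probability `p`, and
placing a uniform Beta(1, 1) prior on `p`, the posterior is
Beta(x + 1, n − x + 1).  The equal-tailed 95% credible interval — the 2.5%
("inferior") and 97.5% ("superior") posterior quantiles — is computed with
the regularized incomplete beta inverse (`scipy.stats.beta.ppf`).

The uniform prior is forced by the published bounds themselves: a family
with one taxon, one use report prints (0.158, 0.987) = (√0.025, √0.975),
the quantiles of Beta(2, 1), and the regional total (2258, 207) prints
(0.080, 0.104); both reproduce exactly under Beta(x+1, n−x+1) and under no
other standard prior.  Every printed interval across the six
province × reference panels (96 rows) reproduces at the published 3-decimal
precision, which also served as a self-check during digitization: the
concatenated "n x" digit strings of the printed tables were disambiguated
by recomputing the interval for each candidate split and accepting the
unique match.

Classification uses strict interval separation: overused iff
`family.inferior > total.superior`, underused iff
`family.superior < total.inferior`, neutral otherwise.  Equality therefore
yields neutral — a conservative, deterministic tie-break.  The margin is
`inferior − total.superior` (overused, positive) or
`superior − total.inferior` (underused, negative), always computed on
unrounded bounds (rounded-bound subtraction is off by 0.001 for several
published rows).  For neutral families the report carries
`max(inferior − total.superior, total.inferior − superior)`, a non-positive
distance-to-significance used for ranking near-misses; note that for a
family whose counts equal the totals this distance is `inferior − superior`,
not zero.  No multiple-testing correction is applied (none is applied in
the source analysis); reports carry the number of families tested so
family-wise error can be judged.

Totals are *inputs*, not derived sums: the published panels use
whole-dataset totals that differ from the sum over listed families (and
even differ by one between panels of the same database), so
`classify_utilization` takes an explicit total and `pooled_total` is only a
convenience for complete tables.

## Survey data model

One record per remedy report, identified by a herbarium voucher.
Multi-valued cells follow the grammar observed throughout the survey
table: `/` separates ailment codes, `|` separates remedy alternatives and
is aligned positionally across the part/preparation/route columns, `&`
joins co-used items within one alternative.  `explode_uses` produces one
event per (ailment × alternative); length-1 cells broadcast across
alternatives and genuinely incompatible cardinalities are an error naming
the voucher.  Explosion is lossless: the multiset of ailment codes over a
record's events equals its ailment list repeated once per alternative.

Taxon identity is case- and diacritic-insensitive, ignores authority
strings, and collapses infraspecific ranks to the binomial; genus-level
taxa are keyed as (genus, "sp.").  Family names pass through a synonym map
(shipped defaults: Labiatae/Labiate→Lamiaceae, Gramineae→Poaceae,
Guttiferae→Clusiaceae, Compositae→Asteraceae, Mimosaceae→Fabaceae,
Asclepiadaceae→Apocynaceae) that is idempotent and user-overridable.

Counting units are explicit everywhere the literature is ambiguous: the
ailment profile counts one per (record, ailment code); part, preparation
and route profiles count one per (record, alternative); both are
switchable to per-record counting.  Family tallies are offered per distinct
taxon (the unit of the utilization tables) and per report entry.

## The digitized survey table

`data/es_survey.tsv` is a digitization of the published East Sepik survey
table: 299 reports from four study areas (DK, BK, GW, MS).  The published
voucher column is internally unreliable (one voucher appears twice, and
several cross-references elsewhere in the publication contradict it), so
the digitization was validated globally instead: the pooled ailment
tallies (skin 73, respiratory 60, fever 39, gastrointestinal 36, malaria
29) and all four per-area top-five tallies stated in the running text
reproduce exactly from the table as aligned.  Two cells required curation,
both flagged in `es_survey.CHANGELOG`: the duplicated voucher is suffixed
"-2", and one of the two near-identical DK Zingiber officinale/malaria
records is assigned to GW, the only reassignment that makes the species
present in all four areas (as the running text states explicitly) while
preserving the pooled tallies and the GW respiratory count.  Irregular
code tokens ("S?", "-", "L or B", "R or H") are kept verbatim and surface
through `validate_codes` rather than being silently repaired.

One published figure is not reproducible: the "80 taxa (51 species-rank +
29 genus-rank) not shared between areas".  No consistent rule generates
the published membership — structurally identical cases (a genus with one
species-rank and one genus-rank taxon in different areas) appear on both
sides of it — and the candidate definitions give 151 (taxon in exactly one
area, the definition implemented), 144 (single-report taxa), 96
(species-rank only) or 83 (genus in one area).  The acceptance test for
this figure is left failing with this analysis rather than redefining the
statistic to fit.

## Synthetic data generator

`simulate_flora` draws family sizes from a truncated discrete power law
p(s) ∝ s^−α on [s_min, s_max]; defaults (α = 1.25, s ∈ [1, 250], 85
families) give a region of the same order as the East Sepik reference
flora: ≈2,000 taxa with a heavy tail (a couple of families above 100 taxa,
many singletons).  Individual families can be pinned to exact sizes for
power experiments.  `simulate_survey` includes each species independently
with probability clip(baseline × effect, 0, 1) — per species, not per
informant citation, because the utilization tables count distinct taxa —
and dresses included species in codes drawn from the packaged
vocabularies, so generated surveys validate cleanly.  The default baseline
0.09 matches the observed overall use fraction (207/2258).

Determinism: all randomness flows from `numpy.random.default_rng` seeded
from the config; replicate `i` of an experiment uses
`(1000003 · seed + i) mod 2³¹`.  The inclusion mask is drawn by a
dedicated stream, so `recovery_experiment` can skip materializing record
objects (`materialize="counts"`) and still produce classifications
identical to the full record pipeline — the equality is itself under test.

What the generator does *not* emulate: informant networks, spatially
structured plant availability, dialect-area effects, name-harmonization
noise between survey and reference set.  Passing recovery tests therefore
show the classifier behaves as designed under its own sampling
assumptions, not that real surveys satisfy those assumptions.

Measured operating characteristics under the default conditions (see
`analysis/05`): the per-family false-positive rate of the 95% rule on
fully neutral regions is a little under 5% — dominated by singleton
families whose one taxon happens to be reported, the same pattern visible
in the published over-utilization panels — and a planted 8×-effect family
of 120 taxa over a 5% baseline is recovered essentially always.

## Numerical and design notes

* Quantile accuracy is checked against an independent oracle: bisection
  inversion of the regularized incomplete beta computed by Gauss–Legendre
  integration of the polynomial density (exact for n ≤ 50), agreeing to
  1e-6 for all 0 ≤ x ≤ n ≤ 50.
* All rankings break ties lexicographically by code or family name;
  reports carry both 3-decimal display values (half-even) and
  full-precision columns.
* Degenerate inputs: x > n is an error naming the family (inconsistent
  datasets are flagged, not clamped); families absent from the reference
  set (n = 0) are reported as "unanalyzable" instead of being dropped.
* The published Poaceae margin (East Sepik flora panel) is inconsistent
  with the sign convention satisfied by every other underused row; the
  consistent convention is implemented and that row is excluded from the
  margin cross-check.
* Plots (per-area bar charts behind `--plot`) are conveniences; every
  contract in the package is about the numbers in the TSV outputs.
* Analysis problem sizes: the null-calibration and power experiments use
  300/200 replicates in `analysis/05` and 500/200 in the acceptance tests,
  enough for ±1–2% Monte-Carlo error on the reported rates.
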