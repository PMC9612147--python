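# Methods

## The problem and the model

The package targets intra-species genotyping of organisms whose standard
barcoding loci are invariant between strains. Its premise is that a small
circular organellar genome accumulates substitutions unevenly, so that one
short window (here 400 nt, a length convenient for Illumina-based
metabarcoding) can concentrate enough segregating sites to reproduce the
strain phylogeny of the whole molecule. The pipeline finds that window,
designs primers for it, and quantifies how much phylogenetic resolution
the window retains relative to the full genome.

All coordinates are 1-based and inclusive; an interval with end < start
wraps across the origin of a circular sequence. This convention makes the
span of an interval a–b equal to b − a + 1, so a 400-nt window prints as,
e.g., 5649–6048.

## SNV calling

Three input routes produce the same per-strain variant matrix:

* **Assembled genomes** (the primary route for the synthetic panels):
  position-wise comparison of equal-length strain genomes against the
  reference; columns where either base is ambiguous are skipped and
  tallied. Support is reported as 1.0.
* **Allele counts**: at each position the leading non-reference allele
  (ties broken alphabetically) is called iff coverage ≥ `min_coverage`
  (default 10) and its fraction of coverage is **strictly** greater than
  `support_threshold` (default 0.85). The strictness matters at the
  boundary: 85% support at threshold 0.85 is not a call, 86% is. The
  default minimum coverage is a conservative floor; at the >100×
  organellar coverages typical of the data this emulates it is
  immaterial. No strand, quality or significance filters are applied —
  only the support rule.
* **VCF-like tables**: validated row-by-row against the reference base;
  failing rows are collected in a rejection report rather than silently
  dropped.

The bundled read mapper places each read by its first k-mer (default
k = 21) with a unique exact hit on the doubled reference, forward or
reverse-complement, then counts bases ungapped. It is intended for
substitution-only synthetic reads; real data should be mapped with a
production aligner and summarised to the allele-count table.

## Window scan and marker selection

Windows start at 1, 1+step, … (defaults: window 400, step 100; the step is
a package choice — any value ≥ 1 is accepted). On a circular genome the
starts cover the whole circle and windows wrap; on a linear genome no
partial trailing window is emitted. Per window:

* **SNV count** — distinct segregating positions (a position variant in
  three strains counts once).
* **π** — mean over strain pairs of d_ij/L_ij where d_ij counts columns
  with two unambiguous, differing bases and L_ij counts columns with two
  unambiguous bases (pairwise deletion), scaled by 2/(n(n−1)). The scan
  computes this from per-pair difference tracks with cumulative sums, which
  is exactly equal to (and tested against) the direct per-window
  computation. Haplotypes come from the strain genomes, or are
  reconstructed from the variant matrix as reference-plus-alts, which is
  exact on substitution-only panels.

The marker window maximises SNV count; ties are broken by larger π, then
by smallest start with wrapping windows ranked last. If every window has
zero variants the pipeline stops with a "no informative region" error
(exit code 3).

## Primer design and specificity

Melting temperature uses the Wallace rule, Tm = 2(A+T) + 4(G+C), a
deterministic model adequate for the short (18–24 nt) primers enumerated
here; nearest-neighbor thermodynamics is deliberately out of scope. Default
constraints: length 18–24, GC 0.30–0.60, Tm 50–62 °C, pair ΔTm ≤ 5 °C,
homopolymer runs ≤ 5, amplicon span in [350, 400 + 2·24], amplicon covering
≥ 90% of the target window. The GC floor is 0.30 rather than the textbook
0.40 so that AT-rich organellar primers — including the published pair this
was calibrated against (GC 0.35 reverse primer) — are admissible. Pairs are
ranked by a penalty: 1.0·ΔTm + 10·(|GC_f−0.5| + |GC_r−0.5|) +
0.05·|span − window span| + 0.5 per non-G/C 3′ terminus; ties go to the
leftmost forward start, so ranking is deterministic.

In-silico PCR scans both strands of each template (circular templates are
extended across the origin and each amplicon reported once) for primer
binding sites with at most `max_mismatch` substitutions (default 3) and an
exactly matching 3′-terminal segment (default 3 nt), and reports every
properly oriented pair spanning ≤ 5,000 nt. Templates are classified
positive (a zero-mismatch pair), weak (only mismatched pairs — the
in-silico analogue of faint cross-species bands), or negative.

Marker-level specificity is coverage-weighted local-alignment identity:
matching columns of the best Smith–Waterman alignment (match +1, mismatch
−1, linear gap −2; deterministic traceback preferring diagonal, then up,
then left, from the first maximal cell) divided by the marker length, with
both strands searched. Dividing by marker length rather than alignment
length means a short perfect hit in a divergent genome still scores low.
The mild +1 match score keeps optimal local alignments from stretching
across heavily divergent sequence, so identity decays with divergence as
the screen requires.

## Trees, resolution, clades

Distances are p-distances with pairwise deletion; an optional JC69
transform −(3/4)·ln(1 − 4p/3) is available (undefined at p ≥ 0.75). Trees
are built with Saitou–Nei neighbor joining: join the pair minimising
Q_ij = (n−2)d_ij − r_i − r_j, branch lengths v_i = d_ij/2 +
(r_i − r_j)/(2(n−2)), with Q-ties broken by the lexicographically smallest
label pair (internal nodes carry the smallest leaf label beneath them).
Negative branch lengths are clamped to zero with the deficit moved to the
sister branch. Zero-length internal edges are collapsed to polytomies, so
an uninformative alignment yields a star tree rather than an arbitrarily
resolved one. NJ is exact on additive matrices, which the test suite
exploits as an oracle; maximum-likelihood inference is out of scope because
at intra-species distances (a handful of substitutions) topology is
entirely distance-driven.

Marker resolution is 1 − RF/(2(n−3)) for n ≥ 4, where RF is the
Robinson–Foulds bipartition distance (computed via dendropy) between the
marker-only and whole-genome NJ trees; with all variants inside the marker
the two distance matrices coincide and the score is exactly 1. A
variant-free marker gives a star tree and score 0.5 with an explicit
warning. Three taxa have a single unrooted topology and score 1 by
definition.

Clades are single-linkage clusters on p-distance: two sequences share a
clade iff connected by a chain of pairs at distance **strictly below** the
cutoff (default 0.005/site, i.e. two differences over a 400-nt marker
separate clades — chosen so that clades one diagnostic substitution apart
each remain distinct). Clades are numbered by their smallest member label.
Amplicons are typed to the clade of the nearest haplotype: equal-length
amplicons by p-distance in the marker frame, length-discordant ones by
local alignment with identity weighted over the amplicon length; exact
ties are reported "ambiguous" and nearest distances above 0.15
"unassigned — possible off-target".

## Synthetic data: what it emulates and what it does not

`simkit` reproduces the statistical structure of the study conditions, not
any demographic process:

* **Reference**: i.i.d. bases, default 35,000 nt at 24.3% GC (AT-rich,
  matching organellar composition), circular.
* **Strain panel**: 6 strains in 3 clades of 2. Clade-shared substitutions
  are drawn once per clade: inside the planted window (default 5649–6048,
  span 400) a zero-truncated Poisson count at 5×10⁻³ substitutions/site
  (≈ 2 per clade, ≈ 6 segregating sites in the window across the panel);
  elsewhere a plain Poisson at 1×10⁻⁵. The zero truncation makes every
  clade carry at least one diagnostic substitution — the clades being
  emulated are observably distinct entities, and a "clade" molecularly
  identical to the reference would misrepresent the condition being
  modelled rather than stress the pipeline. Positions are uniform without
  replacement, alternate alleles uniform over the three non-reference
  bases. Optional strain-private mutations default to zero. The background
  and planted rates are calibration choices of this package (no empirical
  per-site intra-species rate is available to set them).
* **Reads**: single-end, uniform starts on the circle (reads wrap),
  i.i.d. substitution errors, count = round(coverage·L/read length). No
  quality strings, GC bias, or pairing — none of which the pileup logic
  consumes.
* **Off-targets**: per-position Bernoulli substitution at the nominal
  divergence; a crude but sufficient stand-in for deeply divergent
  species in a specificity screen.
* **Amplicon survey**: named coastal regions each host a (possibly empty)
  set of clades; a site is positive iff its region hosts a clade; positive
  sites emit amplicons drawn uniformly from present clades' haplotypes
  with per-base error (default survey tests use 0 and 0.002/site).

Because the generator is substitution-only, passing tests demonstrate
correct behaviour on alignment-free, equal-length panels; they say nothing
about indels, rearrangements, chimeric amplicons, or mapping artefacts in
real data. Real panels with indels must be aligned externally and supplied
as an MSA-derived equal-length panel or a variant table.

## Numerical and scale choices

* Problem sizes in the test suite: full-scale recovery runs use 20
  independent 35-kb panels (the whole suite runs in well under a minute);
  oracle suites use 500 random π panels (≤ 5 taxa, ≤ 50 nt), 100 random
  6-leaf additive trees, and 200 random sequence pairs (≤ 12 nt) against
  exhaustive alignment enumeration.
* Window statistics and the alignment DP are exact integer/rational
  computations in floating point; no tolerances beyond 1e-9 (NJ branch
  lengths vs additive truth) and 1e-12 (tie detection in amplicon typing)
  are used.
* Degenerate inputs: all-ambiguous composition, fully ambiguous sequence
  pairs, zero-variant panels, empty amplicon files and empty clade sets
  raise typed errors or produce explicitly empty reports, as exercised in
  the tests.

## Known limitations

* The naive k-mer read placer drops multi-hit reads instead of resolving
  them; repetitive genomes would lose coverage (the target genomes are
  repeat-poor).
* In-silico PCR counts substitution mismatches only; primer–template
  bulges (indels) and thermodynamic duplex stability are not modelled.
* Clade delimitation by a fixed distance cutoff is a pragmatic
  operationalization; it is exposed as a parameter (`--clade-cutoff`)
  because no principled universal value exists.
* Bootstrap support on the intra-species trees is not computed.
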