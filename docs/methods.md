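# Methods

## Model

The Oligonucleotide Frequency Range (OFR) criterion treats a species as a
box in k-mer frequency space: for each of the 4^k oligonucleotides the
species occupies the interval between the minimum and maximum frequency
observed across its accessions.  Frequencies are computed on gap-free
sequence with a single-nucleotide sliding window and the nominal
denominator n−k+1 (n−1 for k=2, n−2 for k=3).  Two species are resolved
when at least one oligonucleotide's intervals are disjoint with a gap of at
least the threshold

    t = 1 / (a − k + 1),

with a the dataset-wide mean ungapped length.  t is the frequency weight of
one window at the average length, i.e. the smallest difference a single
substitution can produce; "separated by at least t" is read inclusively
(gap ≥ t).  Float comparisons against t use an absolute tolerance of
1e−12, far below one count unit at any realistic length.

Assumptions inherited by everything downstream:

* sequences belong to one orientation of one locus (no reverse-complement
  canonicalisation);
* a is meaningful for the whole dataset — a single t is shared by all
  pairs (a per-pair option exists on `resolution_matrix` callers via
  recomputation on subsets);
* at least two accessions per species are needed for a non-degenerate
  range; species below `min_accessions` (default 2) are reported as
  *not evaluable*, a distinct outcome from *unresolved*.

Ambiguity codes: any window containing a non-ACGT character contributes to
no count while the denominator stays n−k+1, keeping the printed
denominators literal.  The alternative (dividing by the number of clean
windows) is available as `denominator="valid"`.

## Scoring

`percent_resolution` offers two denominators.  *species* mode (default):
the share of evaluable species separated from **every** other evaluable
species — comparable with the per-species barcoding-gap criteria.  *pairs*
mode: the share of evaluable unordered pairs resolved.  Both are always
computable from the same matrix; reports include both where relevant.

## Comparator criteria

* **p-distance** — proportion of differing sites among pairwise-comparable
  sites (sites with a gap or ambiguity in either sequence excluded:
  pairwise deletion, the common default for uncorrected distances).  A
  species is resolved when min interspecific > max intraspecific
  (strict inequality).
* **Euclidean distance** — D = sqrt(Σ over all 4^k oligos (F1−F2)²)
  between accession profiles, no 1/N factor: any positive scalar rescales
  all distances equally and leaves the min-inter > max-intra criterion
  unchanged.  Same species criterion as p-distance, computed at accession
  level.
* **Diagnostic characters** — per alignment column, a state fixed in the
  focal species and absent from the comparison species is *pure*; present
  in some but not all focal accessions and absent from the comparison is
  *private*.  Columns containing any gap/ambiguity among the involved
  accessions are skipped, and gaps are never diagnostic states.  Pair
  resolution requires a pure character by default (`require=
  "pure_or_private"` relaxes this); the conservative default avoids
  crediting polymorphic evidence.

## Indel risk

t is only calibrated for sequences near the average length.  The minimal
risky indel length m solves Δ(L) ≥ margin, where

    Δ(L) = (L + k − 1) / (a − L − k + 1)

bounds the frequency shift of a single oligonucleotide after an indel of
length L (an indel touches at most L+k−1 windows and changes the window
count by L).  For a deletion threatening an overlapping pair (Type I) the
margin is |x| + t; for an insertion threatening a resolved pair (Type II)
it is x − t, with x the pair's extreme signed separation; a non-positive
insertion margin means m = 1.  Δ is a deliberately conservative worst-case
bound, isolated in `robustness.perturbation_bound` so a sharper bound can
be substituted without touching callers.  The dataset audit additionally
applies the length-asymmetry rule — D_s > D_l flags Type I, D_l > D_s
Type II, equality flags nothing — with D_l/D_s the (rounded) excess and
shortfall of the pair's extreme lengths against a.  The minimal-indel
diagnostic assumes equal lengths within a species; the audit only warns
when that fails.

## Mini-barcode scan

`trim_scan` removes alignment columns from one end in coarse blocks
(default 50) and, after the first drop below the running maximum
resolution, rewinds one coarse step and proceeds in fine steps (default
10) until the drop is located.  t is recomputed at every truncation
because a shrinks — the alternative (freezing the full-length t) would
keep an unrealistically strict threshold for short fragments.  Trimming is
by alignment columns rather than per-sequence nucleotides so the records
stay positionally comparable; the reported x-axis is the mean ungapped
retained length.  When nothing resolves at any length the "minimum length
with full resolution" is reported as the full length by convention.

Along a scan the number of discriminating oligonucleotides per resolved
pair generally shrinks with the retained length.  This holds exactly while
trimming removes signal-free sequence or removes signal; trimming that
removes *intraspecific noise* sites can narrow ranges and transiently
raise the count, which the hotspot fixture exhibits once the 3' scan cuts
into its variable region.

## Synthetic data

`generate_dataset` draws a uniform-random root sequence, one ancestor per
species, and i.i.d. accessions per species, with Jukes–Cantor-like
substitutions (each hit site moves to one of the three other bases
uniformly; sites independent; no rate heterogeneity).  The
parameterisation is chosen so the two dials have direct barcoding
meaning: `intra_div` is the expected accession-to-species-ancestor
divergence, and `inter_div` the expected accession-to-root divergence, so
the species-ancestor step mutates at `inter_div − intra_div`.
Consequences:

* expected intraspecific pairwise divergence ≈ 2·intra_div, interspecific
  ≈ 2·inter_div (minus coincident-hit terms;
  `expected_pairwise_divergence` gives the exact two-branch value);
* `inter_div == intra_div` collapses the species layer exactly: all
  accessions are exchangeable draws around the root and species labels are
  arbitrary — the natural null for false-resolution rates;
* `inter_div` may be a per-species vector for graded divergence, and
  substitutions can be confined to sub-intervals (`inter_region`,
  `intra_region`) to build mini-barcode fixtures with localised signal.

Optional indels (per-site rate, geometric lengths, insertion/deletion
50/50) break the shared coordinate system; such datasets are flagged
unaligned.  The truth record retains the root, every ancestor, and every
substitution/indel event.

Defaults (10 species × 5 accessions, 600 nt, intra 0.005, inter 0.05)
emulate a curated single-genus barcoding project: a COI-scale locus,
~1% within-species and ~10% between-species pairwise divergence.  What the
generator does **not** emulate: codon structure and selection, rate
heterogeneity along the locus (except via the region masks), coalescent
genealogies (incomplete lineage sorting, introgression), sequencing error,
and missing data.  Tests passing on these data therefore demonstrate the
algorithmic contracts and the qualitative regimes, not performance on any
particular real taxon.

## Numerical and design choices

* Percentages are printed with one decimal by the CLI; JSON artifacts keep
  full precision.
* `is_aligned` is inferred on reading (any gap present + equal gapped
  lengths); alignment-requiring operations accept any equal-length
  dataset, so ungapped simulated alignments work without a dummy gap.
* Sequences are upper-cased and U→T on ingest (public data mixes cases
  and RNA annotation).
* Ragged alignment ends are trimmed to the outermost columns covered by
  every record (`min_coverage` exposes laxer rules).
* The six-method comparison runs OFR/Euclidean criteria on the degapped
  view and p-distance/characters on the aligned view of the *same*
  records; the delta correlations use pair-level deltas (min interspecific
  − max intraspecific within the pair) on trinucleotide profiles by
  default.

## Problem sizes

The test suite and the acceptance script use desk-scale simulations:
50-replicate sweeps of the 10×5×600 benchmark, a 100-seed null, a
20-species graded-divergence dataset, a 6×4×600 hotspot fixture, and 10^4
single-substitution trials — together a few tens of seconds on one core.

## Known limitations

* OFRs depend on sampling: adding accessions can only widen ranges, so
  resolution is anti-monotone in sample size (this is a property of the
  method, verified by tests, not a defect of the implementation).
* The dinucleotide Euclidean criterion projects sequences onto 16
  composition dimensions and can conflate distinct substitution sets;
  in the benchmark regime it resolves fewer species than every other
  criterion.  The trinucleotide variant does not show this at these
  divergences.
* The minimal-indel bound Δ(L) is a worst case; real indels usually
  perturb less, so m is conservative (small).
* No query-against-reference classification: the method as implemented
  scores pairwise species resolution within a reference set.
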