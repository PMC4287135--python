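# Methods

This note documents the models implemented in `disevo`, the parameters that
matter, the design choices made where the design was genuinely open, and what
the synthetic validation does and does not show.

## Per-residue flexibility: the fold-index stand-in

The neural-network disorder predictors used in the comparative literature
(PONDR-FIT, PONDR-VLXT, PONDR-VSL2) are unpublished or web-only, so `disevo`
uses a fully specified fold-index stand-in and names it
"fold-index (charge–hydropathy) stand-in" in every output and manifest. For
residue i, over a centered window of `window` residues (default 51, a common
disorder-smoothing scale; shrunk symmetrically near the termini so the
half-width at position i is `min(window//2, i, L−1−i)`):

    F_i = 2.785·⟨H⟩_i − |⟨R⟩_i| − 1.151
    score_i = clamp(0.5 − F_i, 0, 1)

* ⟨H⟩: mean Kyte–Doolittle hydropathy mapped to [0, 1] by (v + 4.5)/9 — the
  standard CH-plot normalization.
* ⟨R⟩: mean net charge per residue; K and R count +1, D and E count −1,
  histidine and everything else are neutral. Termini are ignored.
* 'X' (unknown residue) carries zero charge and neutral hydropathy 0.5.

Residues with score > 0.5 are called disordered. The stand-in preserves the
downstream logic of the published workflow (0.5 threshold, CDF curves,
per-domain means) with a deterministic computation; it is *not* a
re-implementation of any PONDR network, and absolute disorder percentages
from the literature (e.g. the 41%/61% figures for the human proteins) are
not expected to be reproduced by it.

## Whole-sequence CH-CDF classification

* **CH distance.** On the charge–hydropathy plane, R = |#(K,R) − #(D,E)|/L
  and H = mean normalized hydropathy over the whole sequence. The boundary
  line is R_b = 2.785·H − 1.151 and dCH = R − R_b (vertical distance;
  whether the original analyses used vertical or perpendicular distance is
  not documented, and only the sign enters the quadrant logic). Positive dCH
  = charge excess, the disorder-prone side.
* **CDF distance.** CDF(t) = fraction of residues with score ≤ t, a
  right-continuous step function, evaluated at 7 equally spaced thresholds
  0.1 … 0.7. dCDF = mean over thresholds of CDF(t_i) − boundary_i. Positive
  = order-prone.
* **Boundary calibration.** The published CDF boundary belongs to a specific
  predictor and is not tabulated, so the boundary for the stand-in is
  rebuilt: at each threshold it is the midpoint of the mean CDF curves of an
  ordered-composition and a disordered-composition reference set, made
  nondecreasing by a cumulative maximum. The shipped default
  (`data/cdf_boundary.tsv`, version 1) was calibrated on 200 + 200 synthetic
  length-300 sequences drawn from the default compositions (seeds
  20140101/20140102, window 51). `calibrate_cdf_boundary` rebuilds it for
  any other predictor configuration.
* **Quadrants.** Q1: dCH ≥ 0 & dCDF ≥ 0 (charged but possibly structured);
  Q2: dCH < 0 & dCDF ≥ 0 (structure-prone); Q3: dCH < 0 & dCDF < 0;
  Q4: dCH ≥ 0 & dCDF < 0 (both disorder-prone). Zero is assigned to the
  ≥ 0 side by convention.

## Alignment engine

Pairwise and profile alignment share one affine-gap Gotoh DP so that a
two-sequence progressive MSA scores exactly like the pairwise optimum.

* Gap run of length k costs `gap_open + (k−1)·gap_extend`; defaults
  open 10, extend 0.1 (the classic CLUSTALW protein settings).
* Matrices come from Biopython's `substitution_matrices`; "default PAM" is
  read as PAM250 for the MSA, BLOSUM62 is the default for homolog scoring.
  Gap symbols score 0 in profile columns.
* Traceback ties are broken deterministically: match/mismatch is preferred
  over a gap in the first input, which is preferred over a gap in the second
  (tolerance 1e−9 on score equality).
* Profile–profile scores are the *average* sum-of-pairs substitution score
  over cross-profile residue pairs (counts normalized by profile sizes).

The progressive MSA builds its guide tree by NJ on pairwise 1 − identity
distances and merges profiles in postorder. It omits sequence weighting and
iterative refinement on purpose — it is a desk-scale approximation of
CLUSTALW, adequate for the rate statistics downstream, not a competitor to
modern aligners.

## Homolog filtering

Database search heuristics are replaced by exact global alignment: the
self-score filter keeps candidates with score ≥ `fraction` (default 0.10) of
the query–query score — a scale-free rule, so the heuristic-vs-exact scoring
difference largely cancels. Redundancy clustering is greedy longest-first
(ties by id): each record joins the first cluster whose representative it
matches at ≥ `identity_threshold` (default 0.90), else founds one. Identity
is matches / alignment length *including* gap columns — stricter and
deterministic. The representative is the longest member (the founder, given
the ordering).

## Neighbor joining and bootstrap

Standard Saitou–Nei NJ on p-distances (mismatch fraction over columns with
no gap in either row; a pair with zero comparable columns is an error naming
the pair). The Q-criterion minimizer is chosen with ties broken by the
smallest index pair; a negative branch length is clamped to zero with the
deficit moved to its sister so the pair's path length is preserved. The tree
is stored rooted at the final trifurcation but is an unrooted tree; splits
are canonicalized relative to the alphabetically first leaf.

Bootstrap resamples alignment columns with replacement, rebuilds the NJ tree
per replicate, and reports for each internal edge the fraction of replicates
containing its bipartition. Fully seeded (`numpy.random.default_rng`);
identical seeds give byte-identical Newick output. The CLI default is 100
replicates for interactive use; 2000 is the publication-scale setting.

## Per-domain substitution rates

Domains are annotated once on a reference sequence (1-based inclusive on
disk, 0-based half-open internally) and projected to the minimal alignment
column interval covering the reference residues. Sites are alignment columns
of the projected region, so insertions relative to the reference widen L.

Two group-comparison semantics are implemented because the verbal procedure
("compared with the amino acid sequence in the first group") is ambiguous:

* **pairwise** (default): S_i = number of ordered cross-group pairs whose
  symbols differ at column i. Then ΣS_i/(M·N·L) is a genuine [0, 1] mismatch
  fraction and symmetric in the groups. This is the only reading under which
  the M·N·L normalization is a rate.
* **any-match**: S_i = number of second-group sequences whose symbol matches
  no first-group symbol at column i, normalized by N·L.

Matching rules: 'X' mismatches everything, including another 'X'
(conservative, deterministic). Gap policy `mismatch` (default) treats
gap-vs-residue as a substitution — indels are evolutionary events in this
workflow — and gap-vs-gap as a match; `exclude` drops gap-containing
comparisons from the counts (the M·N·L denominator is kept, making excluded
rates conservative lower bounds).

## Conserved gene neighborhood

"Window of two million bases" is read as a total 2 Mb span (±1 Mb around the
center gene's midpoint), matching the "surrounding 2 Mb" convention of
synteny plots; pass a different `window_bp` for the ±2 Mb reading. Gene
position is the span midpoint (strand-free), window membership is a closed
interval, and gene identity is case-insensitive symbol equality — the
orthology declaration is the user's neighborhood table. CGN = C_X/M_HS, so
score > 0.5 ⇔ more than half the reference neighbors are conserved, by
construction.

## Synthetic data generator

The generator emulates the *statistical* structure the pipeline assumes — it
makes no attempt to imitate real DBC1/CCAR1 sequences.

* **Compositions** (`data/compositions.yaml`, version 1): the ordered class
  is enriched in I, L, V, F, W, Y, M (mean normalized hydropathy ≈ 0.63,
  near-zero net charge), the disordered class in E, K, S, P, Q, G (≈ 0.28,
  balanced but abundant charge). These mirror the hydropathy/charge contrast
  that fold-index-style predictors exploit, with a wide margin on both sides
  of the CH boundary.
* **Architectures**: `dbc1_like_architecture()` alternates ordered domains
  (S1-Like, LZ, Nudix, EF-Hand) with disordered linkers/tails (430 residues
  total); `rate_benchmark_architecture()` is a two-region 150+150 layout for
  rate recovery.
* **Evolution**: along each branch of a Newick species tree, every site of a
  region substitutes with probability `rate × branch length` (capped at 1);
  the replacement is drawn from the region-class composition *conditioned on
  differing from the current residue*. This conditioning makes the planted
  per-site probability identifiable as the expected parent–child mismatch
  fraction; an unconditioned draw would silently deflate recovered rates by
  the composition's self-collision mass. Indels are Poisson per branch
  (geometric lengths) and confined to disordered regions by default so
  ordered-domain boundaries stay projectable, matching the conserved-domain
  picture; `indels_anywhere` lifts this.
* **Rate-recovery benchmark** (`two_group_star_spec`): a star tree whose
  reference group sits at divergence 0 and whose diverged group has
  independent unit-length branches. Under this design the expected
  cross-group mismatch probability per site *equals* the planted rate, so
  recovery within ±0.05 is a sharp test (with 20 leaves/group and 150-column
  regions the Monte-Carlo standard error is ≈ 0.01). Because the benchmark
  runs indel-free, its leaves are columnwise aligned by construction and
  `AlignedFamily.from_ungapped` is used; the MSA path is exercised
  separately (scoring-consistency checks and end-to-end tests with indels).
* **Neighborhoods**: the counterpart window shares exactly
  `round(f·n_genes)` symbols with the reference window, positions jittered
  uniformly inside the window, so the planted fraction is recovered exactly.

What passing these tests shows: the statistics are computed correctly and
recover planted truth under the generator's assumptions (i.i.d. composition
within regions, site-independent substitutions, clean group structure). What
they do not show: robustness to real-data features the generator omits —
rate heterogeneity across sites, realistic substitution matrices (WAG/LG),
selection, alignment error on deep divergences, or orthology mistakes in
gene symbols.

## Numerical and degenerate-input conventions

* Score-equality tolerance in alignment traceback 1e−9; all rate and CGN
  comparisons in tests are exact or at explicitly stated tolerances.
* NJ requires ≥ 2 taxa; 3 taxa yield the unique unrooted star; distance
  updates are clamped at 0.
* Empty FASTA is a format error; an illegal residue names the record and
  1-based position; overlapping domains name both domains; an empty
  calibration class, even profile window, or empty reference window are
  parameter errors. CLI exit codes: 1 for input errors, 2 for parameter
  errors.
* A region fully deleted by simulation raises an error advising a new seed
  rather than silently returning a truncated family.

## Validation problem sizes

The shipped validation (`scripts/acceptance.py`, mirrored by the acceptance
test module) uses: 200 random alignments (3–10 sequences/group, ≤ 50
columns) for oracle equivalence; 10 simulator seeds at 20 leaves/group for
rate recovery; 5 planted fractions at 40 genes for CGN; 50 random 8-taxon
additive matrices and a 6-taxon homoplasy-free alignment (200 bootstrap
replicates) for NJ; 100 + 100 length-300 sequences per draw for CH-CDF
separation; 100 architecture replicates for the profile contrast; and 100
random pairs plus all ≈ 7 × 10³ pairs of length-≤4 strings over a 3-letter
alphabet for alignment scoring. These sizes give sharp expectations (exact
equality or Monte-Carlo error well inside the stated tolerances) while
keeping the whole suite to a few seconds.
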