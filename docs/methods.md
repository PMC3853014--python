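# Methods

This note documents the models, parameters and numerical choices behind
`polydesign`, and what the synthetic test fixtures do and do not establish
about behaviour on real data.

## The processing model

A CTL epitope is presented only if the antigen-processing pathway delivers
it: the proteasome (constitutive or immunoproteasome) must cut precisely at
the epitope's C-terminus, TAP must transport the liberated peptide (or an
N-terminally extended precursor, later trimmed by ER aminopeptidases) into
the ER, and the peptide must bind an HLA class I molecule. In an artificial
polyepitope, the residues surrounding each epitope are a design variable:
the designer controls each epitope's upstream neighbour (the previous
epitope plus any spacer) and can prepend flanking residues. `polydesign`
treats all three pathway stages with simple, pluggable sequence models so
that literature-derived parameter tables can be dropped in without code
changes; the bundled tables are synthetic, clearly labelled, and exist so
the machinery is testable against planted ground truth.

### TAP transport (module `tap`)

TAP affinity is additive over four positions: the first three N-terminal
residues (roles N1, N2, N3) and the C-terminal residue (role C), which
dominate the transporter's sequence preference. The score of peptide *p*
is `M[N1, p1] + M[N2, p2] + M[N3, p3] + M[C, p_last]`, in the matrix's own
log-affinity units, with the orientation (higher = better) declared in the
parameter-file header so matrices from different sources cannot silently
flip sign.

**Flank selection.** An epitope scoring at or above `tap_threshold` is left
untouched. Otherwise all flanks of length 1, 2, 3 (20 + 400 + 8 000
candidates) are scored exhaustively — the search space is tiny, so no
heuristic is justified — and the *shortest* flank reaching the threshold
wins; among equally short reaching flanks, the highest-scoring, then
lexicographically first. If no flank reaches the threshold, the candidate
with maximal score (including the empty flank) is kept, ties broken by
shorter then lexicographic. Consequently the TAP score never decreases.
Only N1–N3 change when a flank is prepended (the C-terminus is fixed), so a
flank of length ≥ 3 fully determines the N-terminal contribution; lengths
1–2 still matter because they shift the epitope's own residues out of the
scored positions.

**Threshold calibration.** No universal "inefficient binder" cutoff exists
— it depends on the matrix's units. When `tap_threshold` is not supplied,
the CLI calibrates it to the median TAP score of all 9-mer windows of a
user-supplied reference antigen (or, failing that, of the epitope set
itself) and logs the value. The median is self-normalizing across matrices
and marks roughly half of natural peptides as adequate transporters, which
matches the intended "flank only when necessary" behaviour.

### Proteasomal cleavage (module `cleavage`)

Cleavage efficiency is expressed on an 11-level rank scale (1 = most
efficient, 11 = least). A model is a list of degenerate patterns over a
declared context window around the scissile bond — default P4–P2′, i.e.
4 residues upstream and 2 downstream, the minimal span used by
motif-based cleavage models — each pattern mapping to a rank, plus a
default rank for unmatched contexts. Matching is deterministic: the most
specific pattern (most constrained slots) wins, ties broken by file order.
Contexts that extend past a sequence terminus are padded with a character
that matches only wildcard slots. The proteasome and immunoproteasome get
independent tables because their specificities differ; both ranks enter the
junction weight separately and through `min(rank_pr, rank_impr)` — cleavage
by *either* form suffices to liberate the epitope.

### HLA binding and junctional epitopes (module `mhc`)

The reference binding predictor is a per-(allele, length) position-specific
scoring matrix with intercept, emitting pIC50 = −log10(IC50/M). Any
predictor that produces pIC50 can stand behind the same file format.
Predicted pIC50 maps to the 3-level affinity rank with closed lower bounds:
rank 1 (moderate) at 6.3, rank 2 (high) at 7.3, rank 3 (highest) at 8.3;
below 6.3 is a non-binder (rank 0).

A *junctional* peptide is any scanned window of `pep1 + spacer + pep2` not
fully contained in either flanked peptide alone — such windows exist only
because of the artificial juxtaposition. Windows identical to a target
epitope sequence are excluded (re-creating a target is not off-target).
Scanned lengths default to 9 and 10, the dominant class-I ligand lengths,
and are configurable. Flank residues count as part of their peptide for the
containment rule: the flanked precursor is the unit being assembled.
`N_eps` counts (peptide, allele) hit pairs rather than unique peptides —
the weight formula counts affected alleles separately as `N_HLA`, so the
raw hit count is the natural reading, and the choice is isolated in
`summarize_junction` should a user prefer the other.

### The junction weight (module `junctions`)

Candidates for a pair are the direct junction plus every prefix expansion
of the spacer motif (≤ 6 positions; degenerate positions multiply out), in
shorter-first, then lexicographic order. Each candidate's weight combines
the junctional burden (frequency-weighted best ranks, hit and allele
counts), the spacer length, and the cleavage ranks at the first epitope's
C-terminus, with the downstream context taken from the spacer plus the
start of the second *flanked* peptide — the context that will actually
exist in the assembled protein. The minimal-weight candidate wins; the
enumeration order makes "shorter, then lexicographic" the tie-break for
free.

One term needs care: `0.05 × (4 − mean rank_HLA)` *decreases* the weight as
junctional binders get stronger, opposing every other term. We keep the
algebra verbatim whenever hits exist, but define the term as 0 when there
are no hits at all — otherwise a hit-free junction would be penalized 0.2
relative to one with weak hits, inverting the design goal. The
`empty_junction_mean_term` switch restores the fully verbatim behaviour.

**Admissibility.** A pair is disallowed when no candidate achieves
`min(rank_pr, rank_impr) ≤ cleavage_allow_threshold` (default 7, the
midpoint-or-better of the 1–11 scale): an efficient cleavage site at the
first epitope's C-terminus is the one hard processing requirement.
Disallowed pairs enter the graph at weight 5000, two-plus orders of
magnitude above typical allowed weights (≤ 10), so any ordering that avoids
them will beat any ordering that doesn't.

### Ordering (module `assembly`)

The construct is the minimum-weight Hamiltonian *path* (no return edge) in
the complete weighted digraph. Three solvers:

* **exhaustive** — scans all n! orderings, capped at n = 8 (40 320
  evaluations); ties broken lexicographically on the id sequence. Serves
  as the oracle for the others.
* **greedy** — nearest-neighbour from *every* start node (deterministic,
  strictly better than a single-start rule which the greedy approach
  leaves unspecified); ties by (weight, node id).
* **ga** — permutation-encoded genetic algorithm: tournament selection
  (size 2), order crossover (rate 0.9), per-position segment-inversion
  mutation (rate 0.1), elitism 1, population 80, 500 generations, seed
  mandatory. Inversion rather than swap mutation because reversing a
  segment is a 2-opt move — the natural neighbourhood for path weight —
  and plain swaps left the population trapped in 2-opt local minima on a
  few percent of small random instances. A quarter of the initial
  population is seeded with the multi-start greedy paths, so the GA result
  is never worse than greedy; the random majority preserves exploration.
  With these settings the GA recovered the exhaustive optimum on 60/60
  random 5–7-node graphs across three seed streams (the packaged test
  checks 20 instances).

A fixed seed makes the GA bit-identical; the CLI's outputs contain no
timestamps, so whole runs are byte-reproducible.

### T-helper module (module `thelper`)

Class-II presentation tolerates — indeed benefits from — natural flanking
context, so instead of concatenating minimal epitopes the module selects
whole antigen windows of 20–40 residues dense in predicted 9-mer class-II
binding cores. All windows of every length are scored; ranking is
(distinct allomorphs desc, distinct cores desc, length asc, start asc) —
repertoire breadth first, per the design goal of covering the maximal
repertoire of class-II allomorphs — and windows are accepted greedily
while their cores stay pairwise disjoint (overlapping fragments would
duplicate sequence). Each accepted core is extended by exactly five
residues per side, clamped at the antigen termini. Fragments are joined in
input order (ordering is optimized only for the CTL module) through the
`[KR][KR]` motif — dibasic sites for lysosomal cathepsins — choosing the
minimal-weight candidate with the same ranking machinery, including the
class-I junctional scan; no admissibility gate applies because fragment
liberation here is cathepsin-, not proteasome-, driven.

### HLA coverage (module `coverage`)

Selecting which epitopes enter a construct so that every allele of a
repertoire is bound by at least *r* of them is set-multicover; the module
uses the classical greedy heuristic (largest remaining-demand reduction,
ties by summed genotypic frequency of the alleles advanced, then id).
Infeasible repertoires yield a partial solution flagged `complete=False` —
a design aid should report how far it got, not fail. Tests compare the
completeness flag against exhaustive subset search on 10-epitope instances
and check the classical ln-factor size guarantee empirically.

## Synthetic fixtures — what they do and do not show

`fixtures.make_fixtures` emits a full parameter set whose optima are known
by construction: cleavage rank is controlled entirely by the P1′ residue,
one designated residue gets ranks (1, 2) while all others rank 8–11;
epitopes never start with that residue, so direct junctions are
inadmissible and the planted optimal spacer is the single good residue;
class-I matrices are centred at pIC50 ≈ 4.5 with small position weights, so
junctional hits are rare, as in the regime where most random peptides are
non-binders. Same seed ⇒ byte-identical files.

Passing tests therefore establish that the machinery *optimizes what it is
told to optimize*: scoring is exact against independent summation oracles,
spacer and ordering choices match exhaustive enumeration, and the pipeline
is deterministic end-to-end. They do not establish immunological validity
of any particular parameter table — with literature-derived TAP, cleavage
and MHC tables the code will faithfully optimize those, but the bundled
synthetic tables carry no biological meaning, and real antigens add
phenomena (correlated positions, length-dependent processing, allele
linkage) that position-independent additive models ignore.

## Defaults at a glance

| Parameter | Default | Units / range | Why |
|---|---|---|---|
| `tap_threshold` | calibrated (median 9-mer score) | matrix units | self-normalizing across matrices |
| `max_flank` | 3 | residues | precursor extension limit |
| `junction_lengths` | 9, 10 | residues | dominant class-I ligand lengths |
| `cleavage_allow_threshold` | 7 | rank 1–11 | midpoint-or-better cleavage required |
| `disallowed_weight` | 5000 | weight units | dominates any allowed path |
| pIC50 rank cut-offs | 6.3 / 7.3 / 8.3 | −log10 M, closed lower bounds | moderate / high / highest affinity |
| cleavage window | 4 up, 2 down | residues | minimal motif-model span; file-declared |
| GA | pop 80, gen 500, cx 0.9, inv-mut 0.1, tourn 2, elite 1 | — | recovers exhaustive optimum on all tested n ≤ 7; seconds for n ≤ 20 |
| Th fragment | 20–40 core, ±5 extension | residues | class-II-rich windows plus TCR-relevant flanks |

## Known limitations

* All scoring models are position-independent and additive; no interaction
  terms, no length-dependence beyond separate per-length matrices.
* The junction scan only covers the configured lengths; an off-target
  8- or 11-mer binder would be missed under the defaults.
* Greedy and GA solvers carry no optimality certificate beyond the tested
  regimes; for ≤ 8 epitopes the exhaustive solver should be preferred.
* The T-helper module does not model binding-register alignment within a
  core, nor cathepsin specificity beyond the fixed dibasic motif.
* Graph construction is O(n² · |candidates| · scan cost) and single-
  threaded; large epitope sets with degenerate motifs are the slow case.
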