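# Methods

## Definition grammar

KEGG module DEFINITION strings are parsed by a recursive-descent parser
with the conventional precedence: comma (OR) binds loosest, whitespace
(AND, i.e. consecutive reaction steps) next, and `+`/`-` (complex
subunit / non-essential component) tightest; parentheses override. `--`
is a gap — a reaction known to occur but with no catalogued gene. The
parser emits a normal form (nested same-kind AND/OR flattened, singleton
nodes collapsed), so whitespace-only differences in the input cannot
change the tree, and `parse(serialize(T)) == T` holds for every valid
tree — the round-trip law the test suite checks on randomized trees and
on the shipped example definitions.

Semantics chosen where the grammar is conventional rather than formally
specified:

* **Optional components** (`-X`, whether a whole step or a complex
  subunit) are omitted entirely from paths: they contribute to neither
  the denominator nor the numerator of completeness. Counting them would
  penalise genomes that lack dispensable genes.
* **Gaps** (`--`) contribute one permanently unsatisfiable step. This is
  the conservative reading: an undefined reaction caps attainable
  completeness below 100% rather than inflating it.
* **Complexes** (`A+B`) are one step, satisfied only when every
  non-optional subunit is present — binary, not fractional. This keeps
  the step count of a path well defined. For sensitivity analysis a
  `genes` count mode is provided in which each subunit of a complex is
  counted individually; presence calls in the default mode use steps.

## Completeness evaluation

Completeness is the best fraction of satisfied steps over all alternative
paths through the module. Because the number of paths is the product of
OR branch counts, exhaustive enumeration can explode; and because the
objective is a *ratio*, the locally best OR branch (highest satisfied /
total among the branch's own steps) is not in general the globally best
one once sibling steps are added in. The evaluator therefore reduces
each subtree to the Pareto frontier of achievable `(satisfied, total)`
integer pairs — union at OR nodes, Minkowski sum at AND nodes, one-step
collapse at complexes — pruning any pair that another pair weakly
dominates (at least as many satisfied, no more total). Pruning is sound
because `(s + S) / (t + T)` is increasing in `s` and decreasing in `t`
for any non-negative context `(S, T)`; frontier size is bounded by the
subtree's step count, so evaluation is polynomial. At the root the best
ratio is taken in exact rational arithmetic (`fractions.Fraction`); a
witness path is carried along, with ties broken toward fewer total steps
and then the lexicographically smallest path so the reported best path is
deterministic. The test suite verifies exact agreement with brute-force
path enumeration on hundreds of random trees, including constructions
where a greedy per-branch choice gives the wrong answer.

Degenerate case: a module whose best path has zero scorable steps (all
components optional) reports completeness 0 with an empty witness path.

## Presence threshold

The conventional "67%" criterion is implemented as the exact fraction
2/3 with a `>=` comparison and a 1e-9 epsilon guard, so a genome with 2
of 3 steps (completeness 0.666…) is called present — the behaviour the
rounded percentage is shorthand for — while avoiding float-boundary
ambiguity for users who pass `--threshold 0.6667`. The threshold is
configurable in (0, 1].

## Annotations, filtering, quality

Annotations are read from anvi'o-style TSV exports (gene id, contig,
source, accession, function, e-value) joined to a contig→bin map; genes
on unmapped contigs are kept under the reserved id `UNBINNED` so nothing
is silently dropped. E-value filtering is strict (`e < threshold`) per
source, mirroring the `<1e-100` marker-screen convention; **no e-value
filter is applied to module detection by default**, since pathway-level
screens conventionally accept the annotator's own acceptance thresholds —
filters are opt-in per source.

MAG quality bands: high requires completion > 90 and redundancy < 10;
medium requires completion in [42, 90] and redundancy in [0, 11], with
the high rule applied first. The published band edges overlap
(redundancy 10–11), but only for completion > 90, which the high rule
cannot claim (its redundancy bound is strict) and the medium rule cannot
reach (completion ≤ 90) — so the bands are disjoint, which the tests
verify exhaustively on a half-unit grid.

## Gene suites and the nitrogen-fixation screen

Suites use the ANY-gene rule: a MAG is positive when any annotation
matches any pattern. EC wildcards match field-wise (`1.4.*` matches
`1.4.1.2`, never `1.14.13.25`), with the wildcard allowed only as the
final field. The shipped `data/suites.tsv` carries the three
ammonification-hydrolase EC families verbatim; the DOM transporter suite
memberships are **synthetic placeholders** (representative transporter
KOs) intended to be replaced by a user-supplied file — the engine, not
the membership list, is the contribution here.

The nif screen requires both K02588 (nifH) and K02586 (nifD) as
KOfam-source hits with e < 1e-100 in the same MAG (a same-contig strict
mode is available). COG1348 hits are surfaced in an advisory list but
never count as evidence, because that COG family also contains
light-independent protochlorophyllide reductases — high-similarity
homologs from pigment biosynthesis that are the classic nifH
false-positive. Accessory genes (COG2710, COG0347, COG0535; unpadded
"COG 347"-style labels are accepted and canonicalised) are reported per
nifH-bearing contig with gene-order distances.

## Synthetic communities

The generator writes the exact TSV formats the pipeline consumes, with
planted ground truth per MAG: for each (module, target fraction, path
index) it plants the full accession sets of ⌈f·total⌉ randomly chosen
non-gap steps of the designated path (reporting the realised fraction
when the target is not exactly representable); suite genes instantiate
patterns (EC wildcards get random concrete fields); a diazotroph plant
adds both nitrogenase markers plus accessory genes on the nifH contig;
the homolog trap adds COG1348 without the KOs. Distractors draw from
reserved accession pools (K9xxxx, COG9xxx) disjoint from everything
planted, and the generator asserts that disjointness.

Ground-truth completeness is computed at generation time by exhaustive
path enumeration with naive subset counting — a different route from the
frontier evaluator — so recovery tests compare two independent
computations. E-values are drawn log-uniformly: planted hits on
[1e-180, 1e-20], nitrogenase markers and the trap on [1e-180, 1e-110]
(below the strict screen by construction), decoys on [1e-90, 1e-5].
These windows exist to exercise thresholds and routing; they are not a
model of real HMM score distributions. Likewise the generator starts at
the annotation table: it does not emulate assembly chimeras, binning
contamination, missed gene calls, or annotation transfer errors, so
passing recovery tests demonstrates the correctness of the scoring
logic, not robustness to upstream noise. Host/tissue metadata mimic the
macrophyte study design (blade/rhizome/sediment/bulb; blades assigned to
the water-column oxygen class) purely to exercise the matrix grouping.

One known edge: if a user-supplied module itself contains the
nitrogenase marker KOs, planting it can make a MAG pass the nif screen
whenever the drawn e-values fall below 1e-100; the generator's own
fixtures use a disjoint accession range, so their ground truth is exact.

## Matrix and determinism

The metabolism matrix orders columns by (oxygen class, host, tissue,
MAG id) and rows by (benefit group, feature kind, name); both orders are
pure functions of the metadata, so reruns are byte-identical — checked
end to end. Benefit-group assignment is configuration
(`data/groups.tsv`), not inference. Missing (feature, MAG) pairs are
filled FALSE with a warning rather than an error, since partial result
tables are common in practice.

## Problem sizes

Randomised checks use 1,000 trees for grammar round-trips, 500 trees
(≤12 leaves) for evaluator-vs-enumeration agreement, 1,000 single-gene
additions for monotonicity, and a 50-seed community sweep (3 modules ×
3 MAGs per seed) for planted recovery — sizes at which the brute-force
oracles stay exact while covering all grammar features many times over.

## Limitations

* Presence/absence only: no abundance weighting or copy-number logic.
* DEFINITION strings only: no module hierarchies, signature modules, or
  REACTION cross-references.
* Whether the historical "67%" tools counted steps or raw genes is not
  documented; both modes are provided, steps being the default because a
  network algorithm over KEGG definitions naturally scores reaction
  steps.
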