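# Methods

This note records the linguistic and statistical conventions the package
implements, in enough detail to reproduce or audit any output.

## 1. Orthographic model

**Normalization.** Responses are lowercased, stripped, and internal runs of
whitespace collapse to a single space. A blank response raises
`InvalidResponseError`; any character outside the Portuguese letter set
(including digits and punctuation) raises `NonAlphabeticError`, which the
classifier converts to `OTHER`.

**Grapheme units.** Segmentation is maximal-munch over the digraph set
`rr ss ch lh nh qu gu sc sç xc xs`, with three context restrictions: `sc`,
`xc` and `gu` act as digraphs only before a front vowel (`e`, `i`, accented
or not) — so `escola` is `e·s·c·o·l·a` but `conseguiu` contains `gu` — while
`qu` is always a digraph. Token boundaries (spaces) are stored separately
from units so that multiword targets align on letters, not on spaces.

**Grapheme-to-phoneme reading.** One symbol per non-silent unit:

- coda sibilants neutralize to the archiphoneme `/S/`, nasal codas to `/N/`;
- word-initial `h` is silent; `ç` reads `s`; tilde vowels are single
  nasal symbols (`aN`, `oN`);
- final unstressed `e`/`o` raise to `i`/`u`; coda `l` vocalizes to `w`;
  unstressed `i`/`u`/`o` directly after a vowel read as glides `j`/`w`;
- `x` reads `X` (/ʃ/) unless the lexicon marks the word as reading `z`
  (`exame`, `exemplo`);
- `Z`=/ʒ/, `X`=/ʃ/, `L`=/ʎ/, `J`=/ɲ/, `R` strong rhotic, `r` tap.

Stress comes from the lexicon (syllable spans plus stress index); a response
with no lexicon entry uses a heuristic (accent mark wins; else paroxytone
when the word ends in `a/e/o` optionally followed by `s` or `m`; else
oxytone).

## 2. Alignment

A Damerau-style dynamic program over grapheme units with costs: match 0,
substitution 1, insertion/deletion 1, adjacent transposition of distinct
units 1. A substitution costs **0.5 when it is sound-preserving**, which is
defined operationally: the classifier cascade would label it arbitrary
(`IPG_1`/`IPG_2`/`AAW`). Ties break by preferring more transpositions, then
fewer "unrelated" substitutions (no shared base letter, sound, homorganic
pairing or grapheme family), then a fixed traceback priority that yields a
leftmost-normalized script. Similarity is `1 − cost/max(|t|,|r|)`, clamped
to `[0, 1]`.

Token boundaries are compared by mapping each space through the unit
alignment: a target space with no response counterpart is a `join`
(hyposegmentation), a response space with no target counterpart a `split`
(hypersegmentation).

Invariants (tested): replaying a script over the target units reproduces the
response units exactly, and `matches + subs + dels + 2·transpositions =
|target units|` (symmetrically for the response).

## 3. Classification

Order of decision:

1. normalized equality → correct, no labels;
2. `OTHER` gates: non-alphabetic content; a fixed lexicalized-intrusion list
   (`almoção`, `temum`, `futball`); alignment similarity < 0.5. `OTHER` is
   exclusive and suppresses all other labels;
3. per-edit labels: transpositions → `ASS`; deletions → `OIL` (except the
   silent initial `h`, which is lexically opaque → `IPG_2`); insertions →
   `OIL`; substitutions go through a 17-step precedence cascade (accent-only
   difference → `AAW`; nasalization tilde, morphological slots, contextual
   rules such as `gu/qu` before front vowels, `r/rr`, nasal codas, final
   vowel raising in paroxytones, past-tense final `u` → `IPG_1`; lexically
   opaque sound-preserving choices such as intervocalic `s/z`, sibilant
   spellings, final nasal letters, pretonic `e/i` and `o/u`, final semivowel
   letters in non-verbs → `IPG_2`; anything that changes the reading →
   `RPG`);
4. migration pairing: a deletion (or the letter released by reducing a
   digraph) paired with an insertion of an equivalent letter elsewhere
   (identical letters, semivowels `l/u/o`, nasals `m/n`, sibilants) is a
   displacement → both edits collapse into `ASS`;
5. boundary `join`/`split` ops add `USW` **in addition to** per-edit labels.

## 4. Statistics and reporting

- **Per-word 2×2 tables** (correct/incorrect × group, n = 30 + 30): Pearson
  chi-square **without** continuity correction when at most 20% of expected
  cell counts are below 5, two-sided Fisher exact otherwise. Words with no
  error in either group have no test (degenerate table).
- **Mann–Whitney U**: exact null distribution when the pooled sample is ≤ 20
  and tie-free, asymptotic otherwise. **Normality**: Lilliefors-corrected KS
  by default.
- **Rounding**: means half-up to 1 decimal; percentage shares half-up to 2
  decimals; p-values half-up to 3 decimals, printed `<0.001` only when the
  rounded value falls below 0.001 (so a true p of 0.0007 prints `0.001`).
  The overall share of the 60-word list written incorrectly is **truncated**,
  not rounded, to 2 decimals (28.3/60 → 47.16%).

These conventions were chosen because together they reproduce every
published per-word p-value (58/58 at 3 decimals) and all published grade
shares/means from the embedded counts; the test suite freezes that
agreement.

## 5. Synthetic corpora

Per-word error probabilities come from the embedded per-word incorrect
counts (`count/30` per group); the per-group category mix comes from the
embedded distinct-form counts. Each error realizes one category-consistent
operator: `RPG` homorganic swaps (p/b, t/d, f/v, c/g, x/j — s/z is excluded
because sibilant swaps are sound-preserving and belong to `IPG_2`), `OIL`
single-unit deletion or `i`-insertion, `ASS` adjacent transposition, `USW`
join/split at a syllable boundary, `AAW` accent stripping, `IPG_1`/`IPG_2`
rule-table violations enumerated per word, and `OTHER` drawn from the fixed
lexical list only (no gibberish generator). Every operator validates its
output by re-segmentation, so single-error corruptions round-trip through
the classifier (tested at 100% over the full operator inventory).

Because categories differ in how many words they can apply to (insertions
fit all 60 words, accent errors only 5), a naive per-word draw would distort
the global category mix. Sampling weights are therefore **calibrated** by
iterative proportional fitting over the word-by-category applicability
matrix, weighted by per-word error rates, so the expected drawn mix equals
the profile mix. A second operator is added with probability
`multi_error_rate` (default 0.25, applied only to words with ≥ 5 units and
at positions ≥ 2 units away from the first edit).

All generation is deterministic given the profile and a seed.

## 6. Annotated fixtures and known ambiguities

The corpus module embeds ~260 expert-annotated misspelled forms with their
category labels. Thirteen records are flagged `ambiguous`: their published
labels conflict with the published classification rules (for example,
decompositions where a substitution-plus-insertion reading and the printed
single-category reading disagree). Containment tests run on the unambiguous
subset; the flagged records are retained verbatim with their source
rationale for audit. Two further anomalies are preserved as printed and
documented in the fixture docstrings: one count annotated with an impossible
percentage (stored from its count column), and a grade-5 mean whose printed
rounding is inconsistent with the convention used everywhere else.
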