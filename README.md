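# dswspell

Semiological classification of Brazilian Portuguese spelling errors on a
60-word dictation list, with group-comparison statistics and a
seed-deterministic corpus simulator.

Given a dictation target and a child's written response, `dswspell` aligns
the two at the grapheme-unit level (digraphs such as `rr`, `ss`, `ch`, `nh`,
`qu`, `gu` count as one unit), labels every edit with a category from a
two-class taxonomy, and aggregates the labels into the group-level statistics
used in studies of developmental dyslexia (GD = group with dyslexia, GWD =
group without).

## Taxonomy

| Class | Category | Meaning |
|---|---|---|
| Natural spelling | `RPG` | grapheme substitution that changes the reading (e.g. homorganic swaps p/b, t/d, f/v, c/g) |
| Natural spelling | `OIL` | omission or insertion of a letter |
| Natural spelling | `ASS` | syllable-structure alteration: adjacent transposition or displacement of an equivalent letter |
| Natural spelling | `USW` | unconventional word segmentation: hyposegmentation (`derepente`) or hypersegmentation (`em baixo` for `embaixo`) |
| Arbitrary spelling | `IPG_1` | sound-preserving substitution violating a contextual or morphological rule (`gerra` for `guerra`) |
| Arbitrary spelling | `IPG_2` | sound-preserving substitution where the choice is lexically opaque (`caza` for `casa`) |
| Arbitrary spelling | `AAW` | accentuation alteration (`tambem` for `também`) |
| — | `OTHER` | unrecognizable or lexicalized intrusion; exclusive, suppresses all other labels |

A single response can carry several labels (e.g. an omission plus an
arbitrary substitution). Responses whose alignment similarity falls below a
configurable threshold (default 0.5), contain non-letters, or match a fixed
lexical list are labeled `OTHER`.

## Quick start

```python
import dswspell

word = dswspell.word_by_form("guerra")
c = dswspell.classify(word, "gerra")
c.labels          # ('IPG_1',)
c.similarity      # 0.875

# published-count statistics (per-word 2x2 tests, grade summaries)
result = dswspell.run(counts_only=True)
result.group_stats["GD"]["mean_incorrect"]   # 28.3

# simulate a synthetic corpus and analyze it end to end
cfg = dswspell.PipelineConfig(simulate=True, seed=42, output_dir="out")
result = dswspell.run(cfg)
```

Command line:

```bash
dswspell classify guerra gerra        # labels + edit script as JSON
dswspell stats                        # statistics from the embedded counts
dswspell simulate -o sim.csv --seed 1 # synthetic response table
dswspell aggregate sim.csv -o out/    # classify + summarize a table
dswspell report -o report/            # counts-only report
dswspell self-test                    # internal consistency checks
dswspell export-fixtures fixtures/    # embedded tables as CSV
```

## Layout

- `dswspell.orthography` — normalization, grapheme segmentation,
  context-sensitive grapheme-to-phoneme reading for Brazilian Portuguese.
- `dswspell.alignment` — Damerau-style dynamic program over grapheme units;
  sound-preserving substitutions cost 0.5, all other edits 1.
- `dswspell.classifier` — the per-edit labeling cascade and `OTHER` gates.
- `dswspell.corpus` — the 60-word lexicon, curated examples, annotated
  misspelled-form fixtures and published per-word/grade counts.
- `dswspell.analysis` — Fisher exact / chi-square / Mann–Whitney /
  Lilliefors wrappers plus the reporting conventions (half-up rounding,
  truncated percentages, p-value formatting).
- `dswspell.synthetic_data` — category-consistent corruption operators and a
  calibrated corpus simulator.
- `dswspell.pipeline` — end-to-end runs; `dswspell.cli` — the CLI.

See `docs/methods.md` for the conventions and design decisions in detail.

## Tests

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The suite cross-checks the statistics against hand-written enumeration
oracles (hypergeometric Fisher, rank-assignment Mann–Whitney), verifies
label containment on ~260 annotated misspelled forms, and round-trips every
corruption the simulator can emit back through the classifier.
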