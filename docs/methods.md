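# Methods

## The residue model

The package's unit of analysis is the fatty-acid residue: a chain
summarised as carbons:double-bonds (C:D), with the attachment chemistry
(acyl ester, `O-` ether, `P-` vinyl-ether/plasmalogen) retained as
metadata only. Two residues are identical for aggregation purposes iff
their C:D labels are equal. This mirrors how residue-level results are
reported in practice — a `P-22:1` chain is reported as 22:1 — and means
ether/plasmalogen status never fragments the output rows. Positional and
stereochemical detail (double-bond locants such as 9Z,12Z, sn-position)
is deliberately outside the model: a residue carries counts, not
structure. Oxidized, branched and hydroxy-fatty-acid nomenclature is out
of scope.

## Identifier grammar

An identifier is one or more *alternatives* joined by `/` at
parenthesis-nesting depth zero. Splitting only at depth zero is the rule
that separates the isobar separator (top level) from the chain separator
(inside `(...)`): `PG(P-22:1/18:1)/PG(O-22:2/18:1)` is two alternatives
of two chains each, not four. Unbalanced parentheses are a hard error for
the single identifier and a skip-and-log event in table mode.

Each alternative is either:

- `CLASS(chain/chain/...)` — chains also split on `_`, a common vendor
  variant that never appears at top level;
- `CLASS C:D` (generic dialect only) — a sum composition: the identifier
  gives only the total carbons and double bonds of all chains, recorded
  as a single residue flagged `sum_composition`;
- a bare chain token or a natural-language name (generic dialect only).

Chain tokens accept `O-`/`P-` link prefixes and the sphingoid
hydroxylation prefixes `d`/`t`, which are stripped to the bare C:D
(`SM(d18:1/24:0)` yields 18:1 and 24:0). The token `0:0` marks an empty
sn-position in lyso-species and yields no residue. The `refmet` dialect
accepts only the `CLASS(...)` form; everything it parses, `generic`
parses identically, so `refmet` is a strict subset by construction.

## Ambiguity weighting

The ambiguity index k is the number of alternatives. Every chain
occurrence across all alternatives carries weight 1/k; occurrences of the
same label are merged only at aggregation time, so a residue present in
both alternatives of a k = 2 isobar accumulates weight 1 while
alternative-specific residues accumulate ½. The same rule applies
uniformly for k ≥ 3. With `drop_ambiguous`, any k > 1 lipid contributes
nothing, which is algebraically identical to filtering the input to
k = 1 rows first (a tested invariant). Whether the link type should ever
enter the output identity was considered and rejected: reported residues
omit it, so it stays metadata.

## Natural-language nomenclature

Decoding is lexicon-driven with two routes that must agree wherever both
apply:

- **Trivial names** ("linolenic" → 18:3) live in a tab-separated data
  file bundled with the package (`data/lexicon.tsv`, ~50 entries,
  overridable via `--lexicon`); coverage gaps are data patches, not code
  changes.
- **Systematic names** decompose into a Greek carbon root (etha=2 …
  triaconta=30, with icosa/eicosa and henicosa/heneicosa spelling
  variants) plus an unsaturation suffix (anoic=0 … hexaenoic=6). The
  elided vowel in saturated names (octadec-anoic vs octadeca-trienoic) is
  handled by accepting the root with or without its final "a". The root
  table covers every chain length 2–30, chosen because 30 carbons is also
  the default analysis cutoff (see below).

Names are lowercased, whitespace-collapsed, and leading locants are
dropped before lookup; the trailing word "acid" is optional.

Ester names ("linoleyl palmitate") decode as two components: the "-ate"
acid maps through ate→ic / oate→oic transforms, the "-yl" alcohol
through yl→ic / yl→oic / yl→anoic transforms, each then resolved like a
free acid; output is the two residues sorted by label. One deliberate
choice: the shipped lexicon follows standard fatty-alcohol chemistry, so
"linoleyl" is the 18:2 alcohol and "linoleyl palmitate" yields 16:0 and
18:2 (the monounsaturated reading would correspond to "oleyl
palmitate"). Count-level behavior — exactly two residues, exactly one
16:0 — does not depend on that assignment.

## Table conversion

Input tables have identifiers in the first column, one header row, and
one sample per remaining column. Processing order: (1) drop every column
that is not numeric throughout — a column counts as numeric if every
non-missing cell parses as a decimal number, so numbers stored as text
survive and empty strings count as missing; (2) parse each row's
identifier, skipping and counting unparseable rows (a whole-dataset run
must not die on one vendor quirk; only a run where *every* row fails is
an error); (3) accumulate `weight × abundance` per residue label and
sample. Missing cells contribute nothing — absent, not zero — preserving
the distinction sparse vendor exports make. Duplicate identifiers are
processed independently and sum into the same rows (summation, not
averaging, keeps the semantics additive). Output rows are sorted by
(carbons, double_bonds) so runs are diffable; units are unchanged from
input.

The carbon cutoff (`max_carbons`, inclusive at the bound) exists because
sum compositions and low-resolution species produce totals such as 42:2
that are not single physiological chains; C-30 is the conventional
choice, since the longest unambiguously named fatty acids are C-24
(lignoceric acid and its unsaturated relatives). The cutoff applies to
the residue's carbon count, sum-composition totals included.

## Summaries

- **Saturation split**: saturated means exactly zero double bonds; the
  two outputs are an exact disjoint partition of the rows.
- **Abundance split**: a residue is "abundant" when its grand mean over
  all samples exceeds the threshold (0.5 in the input's units is the
  conventional choice for pmol/μg data). The grand mean — rather than a
  per-group mean — was chosen for symmetry across designs; the threshold
  and the table of samples are both parameters, so per-group splits are
  a slice away.
- **Percent change vs baseline**: pairing is explicit — a design file
  maps each treatment sample to the sample that is its own baseline —
  because positional pairing is fragile. A zero baseline yields a missing
  value, never infinity. Percent change is scale-invariant by
  construction (a tested property).

## Synthetic lipidomes

The generator emits identifier tables covering the grammar end to end:
plain 1–3-chain classes (PC, PE, PG, PI, PS, DG, TG, CE, FA), sphingoid
`d`-prefixed SM/Cer species, `O-`/`P-` prefixes, two-way mass isobars,
space-form sum compositions and natural-language names. Isobar pairs are
chemically honest: a plasmalogen chain P-C:D has the same mass as the
ether chain O-C:D+1, exactly the pair assays fail to resolve. Defaults —
50 lipids, 6 samples, 20% ambiguous, 15% sum compositions, 10% common
names, chains C12–C26 with 0–6 double bonds — emulate a modest
plasma-style panel. Abundances are log-normal (location −1.0, scale 1.5
on the log scale), reflecting the very wide dynamic range of real lipid
amounts and straddling the 0.5-unit abundant/less-abundant threshold.

The ground-truth residue table is written **during generation** by a
brute-force allocator that walks the generated chain structures and adds
`abundance / n_alternatives` per occurrence. It shares no code with the
parser or the table converter — the trivial-name rows even use values
embedded in the generator rather than the lexicon — so it is an
independent oracle. What passing oracle tests shows: the parser and
aggregator implement the 1/k allocation exactly on every shape the
grammar produces. What it does not show: robustness to annotation
conventions outside the grammar (adducts, oxidized species, free-text
comments), which in real tables surface as counted, skipped rows rather
than wrong numbers.

## Numerical and I/O choices

- Aggregation is plain float64 accumulation; oracle agreement is checked
  at 1e-9 absolute per cell (addition-order differences only).
- Input delimiter sniffing is restricted to comma/tab/semicolon and
  fails loudly when undecidable — silent misparsing is worse than an
  error. Decimal commas are handled by an explicit flag, never
  auto-detected.
- Spreadsheet input is `.xlsx`/`.xlsm` (openpyxl); legacy `.xls` is not
  supported — export to text or `.xlsx` first.
- Output is tab-separated by default; write→read round-trips exactly.
- Test and acceptance runs use small problem sizes (tens of lipids, a
  handful of samples, hundreds of seeds) because the allocation arithmetic
  is size-independent; the properties checked do not sharpen with larger
  tables.

## Known limitations

- The lexicon ships ~50 trivial names; rarer trivial names need a data
  patch or a custom `--lexicon` file.
- Class tokens are not validated against a lipid-class ontology; the
  parser trusts the chain tokens.
- Three-or-more-way isobars use the same uniform 1/k rule; no evidence
  weighting between alternatives is attempted.
- No normalization, imputation, batch correction, or inferential
  statistics — the output table is meant to feed whatever statistical
  environment the study already uses.
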