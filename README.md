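# lipresidue

Extract individual fatty-acid residues from complex lipid identifiers and
turn whole lipidomic abundance tables into residue × sample tables.

A finished lipidomic dataset names each analyte with a textual identifier
— RefMet-style shorthand such as `PC(16:0/18:1)`, sum compositions such as
`SM 42:2`, or natural-language names such as "linolenic acid" or
"linoleyl palmitate". The fatty-acid moieties attached to those backbones
(each summarised as carbons:double-bonds, e.g. 18:2) are shuttled between
lipid classes by lipid metabolism, so aggregating a dataset by *residue*
rather than by molecular species often reveals patterns a per-analyte view
hides. `lipresidue` is for anyone holding a processed lipidomics table who
wants that residue-level view without touching raw mass-spectrometry data.

## The method

Each identifier parses into one or more *alternative* chain
decompositions. When an assay cannot distinguish mass isobars, vendors
join the alternatives with a top-level `/`:

```
PG(P-22:1/18:1)/PG(O-22:2/18:1)
```

This lipid is either a plasmalogen (`P-`) with chains 22:1 and 18:1 or an
ether lipid (`O-`) with chains 22:2 and 18:1. The parser returns all four
residue occurrences together with an **ambiguity index** k = number of
alternatives (here k = 2; unambiguous identifiers have k = 1). When
counting residues, or allocating abundances, every occurrence is weighted
1/k: the 18:1 residue, present in both alternatives, receives weight
2 × ½ = 1, while 22:1 and 22:2 each receive ½ — one full residue is
correctly assigned and the irresolvable pair shares an equal chance.
Alternatively, all ambiguous isobars can be discarded outright
(`drop_ambiguous`), keeping only k = 1 identifications.

For a table with analytes in rows and samples in columns, the converter
parses each row's identifier and adds `weight × abundance` into the
residue's output row, per sample; units pass through unchanged.
Sum-composition identifiers contribute their total (e.g. 42:2) as a
single residue, which is why a carbon cutoff (commonly C-30) is useful
downstream. Helper summaries split residues by saturation (zero vs
nonzero double bonds), by abundance around a threshold (e.g. 0.5 pmol/μg),
and express treated samples as percent change against their own paired
baseline, `100 × (x_treat − x_base) / x_base`.

## Worked example

```python
import pandas as pd
from lipresidue import make_residues_table

table = pd.DataFrame(
    {"S1": [10.0, 2.0, 4.0, 1.0], "S2": [1.0, 4.0, 8.0, 0.5]},
    index=["FA(18:3)", "PC(16:0/18:1)",
           "PG(P-22:1/18:1)/PG(O-22:2/18:1)", "SM 42:2"],
)
res = make_residues_table(table, dialect="generic")
print(res.to_csv(sep="\t"))
```

prints

```
residue	S1	S2
16:0	2.0	4.0
18:1	6.0	12.0
18:3	10.0	1.0
22:1	2.0	4.0
22:2	2.0	4.0
42:2	1.0	0.5
```

Reading S1: the free fatty acid passes its 10.0 through to 18:3; the PC
contributes 2.0 to each of 16:0 and 18:1; the two-way isobar splits its
4.0 as 4.0 to 18:1 (both alternatives contain it) and 2.0 each to 22:1
and 22:2; the unresolved sphingomyelin lands as the artefactual total
42:2. Note 18:1 = 2.0 (PC) + 4.0 (isobar) = 6.0.

The same run from a shell:

```
lipresidue extract lipids.tsv -o residues.tsv --generic
lipresidue extract lipids.tsv -o residues.tsv --drop-ambiguous --max-carbons 30
lipresidue simulate --seed 7 --n-lipids 50 -o sim/
```

`extract` reads delimited text or `.xlsx`, drops any column that is not
numeric throughout, writes tab-separated output, and reports rows read,
rows skipped as unparseable (with their names) and columns dropped.
`simulate` writes a synthetic lipidome with a known ground-truth residue
table, useful for validating a pipeline end to end.

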