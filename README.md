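# pase

Functional-impact scoring of amino acid substitutions from physicochemical
property changes and alignment conservation.

When resequencing turns up a missense variant — say `W45S`, tryptophan 45
replaced by serine — the first triage question is whether the change is
likely to matter for protein function. Most predictors answer from
evolutionary conservation alone, which breaks down when few homologs are
available. `pase` scores the substitution itself: how far apart the two
residues sit in a space of physicochemical properties, optionally combined
with a simple conservation score so both lines of evidence count.

## Scores

**PASE** (physicochemical score). Each residue is a point in a
7-dimensional space of AAindex property vectors covering hydrophobicity,
steric bulk, electrostatics, polarity and secondary-structure propensity.
The score of a substitution *o → s* is the Euclidean distance

P = sqrt( Σᵢ₌₁⁷ (aaₒᵢ − aaₛᵢ)² ) / D_max

where *aaₒᵢ* and *aaₛᵢ* are the i-th property values of the original and
substituted residue and *D_max* is the largest distance over all 190
residue pairs (glycine–tryptophan with the packaged table), so P ∈ [0, 1]:
0 is neutral, 1 the most dissimilar swap possible.

**MSAC** (conservation score). From a multiple sequence alignment of N
homologs, the conservation of residue *a* at a site is

C = r · (1 − 0.95ᴺ)

with *r* the fraction of rows carrying *a* there. The 1 − 0.95ᴺ factor is
the probability that N random equal-frequency sequences show a given
residue at a site at all; it discounts shallow alignments (a single
sequence scores at most 0.05).

**PASEC** (combined score). S = P · C — high only when the substitution is
both physicochemically drastic and at a conserved site.

## Worked example

The four benchmark substitutions — two cataract-associated variants in
human connexin 50 (Cx50) and the two porcine PRKAG3 variants behind the
dominant RN muscle-glycogen phenotype — scored with the packaged table and
the per-site conservation values observed for those proteins:

```python
from pase import (load_packaged_table, normalize, parse_substitution,
                  pase_score, combine, format_score)

space = normalize(load_packaged_table())
for token, c in [("W45S", 0.93), ("G46V", 0.93), ("I199V", 0.85), ("R200Q", 0.93)]:
    sub = parse_substitution(token)
    p = pase_score(sub, space)
    s = combine(float(format_score(p)), c)
    print(f"{token:>6}  PASE={format_score(p)}  MSAC={c:.2f}  PASEC={format_score(s)}")
```

```
  W45S  PASE=0.80  MSAC=0.93  PASEC=0.74
  G46V  PASE=0.56  MSAC=0.93  PASEC=0.52
 I199V  PASE=0.14  MSAC=0.85  PASEC=0.12
 R200Q  PASE=0.54  MSAC=0.93  PASEC=0.50
```

Reading: W45S swaps the bulky aromatic tryptophan for tiny polar serine
(PASE 0.80) at a conserved site — a strong functional candidate (PASEC
0.74), consistent with its disease association. I199V is a conservative
branched-chain swap (PASE 0.14); despite sitting at a conserved site its
combined score stays low (0.12), matching its mild phenotype.

## Command line

`pase score` runs the full flow on files; `simulate` builds a synthetic
query/alignment/substitution fixture with exactly controlled conservation:

```bash
pase simulate -n 10 -L 30 -r 0.8 --count 5 --seed 3 -o fixture
pase score fixture/query.fasta fixture/substitutions.txt \
    --msa fixture/msa.fasta -o report.tsv
cat report.tsv
```

```
# pase 1.0.0
# config 2a67454d8c24 scheme=raw-global-max gap_policy=all-rows
# query query length=30 n_substitutions=5 msa_rows=10
id	position	ref	alt	PASE	MSAC	PASEC	flags
Q15M	15	Q	M	0.44	0.32	0.14	
A19E	19	A	E	0.59	0.32	0.19	
H25G	25	H	G	0.66	0.32	0.21	
H26M	26	H	M	0.45	0.32	0.14	
D29T	29	D	T	0.54	0.32	0.17	
```

Every site here was generated at conservation r = 0.8 over 10 sequences,
so MSAC is 0.8 · (1 − 0.95¹⁰) = 0.32 throughout, and each PASEC entry is
the rowwise product of its two factors. `pase matrix` emits the full
20×20 substitution score matrix; `pase conserve` scores an alignment's
reference row site by site. Positions are 1-based on the ungapped query;
omit `--msa` and the report carries PASE only.

## Scope

The package consumes finished alignments (aligned FASTA or Clustal) and
homolog hit tables (TSV: species, evalue, sequence — filtered to the best
hit per species at E ≤ 0.01). Running the homology search and the aligner
themselves, and mapping nucleotide variants to protein coordinates, are
out of scope. See `docs/methods.md` for the model details, parameter
choices and limitations.
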