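# sluptools

Design and quality-control toolkit for targeted DNA libraries built on
single-stranded, dU-containing PCR-derived templates (the SLUPT approach to
multi-site mutagenesis).  It is aimed at protein engineers who concentrate
genetic diversity at chosen residues — recombinase active-site loops, scFv
paratope positions — using degenerate codon mixtures carried by
5′-phosphorylated donor primers, and who then verify the resulting library
by deep sequencing.

The package covers the four computational stages of that workflow:

1. **Degenerate codon selection (MSCS).**  Each codon position can carry any
   of the 15 IUPAC base mixtures, so there are 15³ = 3375 candidate codon
   mixtures.  Given a request — amino acids `a` with weights
   `w_a ∈ [−1, 1]` — every mixture's expansion is translated and scored:

       score = Σ_{a requested, m_a ≥ 1} w_a
               − p_missing · Σ_{a requested, m_a = 0, w_a > 0} w_a
               − p_extra · (extra codon mass ⁄ codon count)
               − p_stop · (number of stop codons)

   where `m_a` is the number of concrete codons encoding `a`.  Mixtures are
   ranked and reported with their encoded/missing/extra amino acids.
2. **Library design.**  A `LibrarySpec` (coding-strand template + ordered,
   non-overlapping mutation sites) yields exact codon-level diversity
   (`Π sites` expansions), protein-level diversity (`Π sites` distinct amino
   acids), combinatorial variant counts `C(L, n)·k^n`, and the expected
   equimolar base fractions at every position.
3. **Donor primers.**  Coding-sense oligos with template-exact flanks grown
   from 15 nt per side until the Wallace-rule Tm of the flanks (mutated core
   excluded) reaches 55 °C; overlap detection and minimum partitioning of
   overlapping primers into separate sub-libraries (greedy interval
   coloring, optimal for interval graphs).
4. **Sequencing QC.**  A CIGAR-walking pileup over plain-text SAM gives
   per-position A/C/G/T fractions and depth; mutated regions are summarized
   against the spec (template-encoded vs primer-encoded vs unexpected
   bases); the per-base error rate is the mean unexpected-base fraction over
   non-mutated positions after end trimming.  A seeded read simulator with
   exact ground truth makes the whole QC stage testable without external
   data.

## Worked example

Select a codon mixture encoding A, T, F, W and C with weights
1.0, 1.0, 0.5, 1.0 and 0.2:

```bash
$ slupt mscs --aa A,T,F,W,C --weights 1,1,0.5,1,0.2 --top 3
5/5 Encoded: A3 T3 F2 C2 W1 Missing:0 Extra: S5 G3 V3 I2 L1 M1 R1 Codons: 27 Code: dbb
5/5 Encoded: A2 T2 F1 W1 C1 Missing:0 Extra: S3 G2 V2 I1 L1 M1 R1 Codons: 18 Code: dbk
5/5 Encoded: A2 T2 F1 W1 C1 Missing:0 Extra: S3 G2 V2 I1 L1 M1 R1 Codons: 18 Code: dbs
```

The second line reads: the mixture `dbk` (A/G/T, C/G/T, G/T) expands to 18
codons; all five requested amino acids are encoded (A and T twice each), no
requested amino acid is missing, and seven unrequested amino acids ride
along.  A more compact alternative, `dsg` (6 codons), encodes A, T and W
exactly once each but misses F and C:

```bash
$ slupt expand dsg | tail -1
# 6 codons, profile: A1 G1 R1 S1 T1 W1
```

Diversity accounting for a five-site library using the mixtures RRK, VNA,
VNA, DSC and VDS (a recombinase-style design):

```python
>>> from sluptools import codon_diversity, protein_diversity
>>> from sluptools.synthetic import cre_like_spec
>>> spec = cre_like_spec(seed=7)
>>> codon_diversity(spec)
124416
>>> protein_diversity(spec)
55055
```

124 416 distinct DNA sequences encode 55 055 distinct proteins
(7·11·11·5·13 distinct amino acids across the five sites).

End-to-end QC on simulated reads:

```bash
slupt simulate library.yaml --n-reads 10000 --error-rate 0.002 --seed 1 --out-dir sim/
slupt qc regions sim/reads.sam library.yaml
slupt qc error-rate sim/reads.sam library.yaml   # mean unexpected-base fraction ≈ 0.002
```

The library spec is YAML/JSON:

```yaml
template_file: template.fasta
frame_offset: 0
sites:
  - {start: 60, reference: AAA, replacement: RRK, label: site1}
  - {start: 111, reference: CTG, replacement: VNA, label: site2}
```

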