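# cppr

Design and analysis toolkit for **consensus pentatricopeptide-repeat (cPPR)
proteins** — synthetic repeat proteins that bind single-stranded DNA and RNA
one nucleotide per repeat, programmably.

A PPR repeat is a 35-amino-acid helix–hairpin–helix; tandem repeats stack
into a solenoid whose concave face reads a nucleic-acid strand. The base
bound by each repeat is set by the amino acids at repeat-local positions 5
and 35:

| position 5 | position 35 | base |
|:-:|:-:|:-:|
| T | N | A |
| N | S | C |
| T | D | G |
| N | D | T / U |

The same code applies to ssDNA and RNA, which makes cPPRs a route to
sequence-specific ssDNA reagents — for example 10-repeat designs against the
telomeric repeat `TTAGGG` that occlude telomerase substrates.

The package provides, for people designing or characterising such proteins:

- **`cppr.ppr_code`** — the recognition code as a bidirectional, config-driven
  table.
- **`cppr.scaffold`** — forward design (target → protein: `MGNS` N-cap, one
  35-aa consensus repeat per base, `VTYTTLISGLGKAG` solvating helix), reverse
  engineering (protein → predicted target), and the
  `global = cap + 35·(repeat−1) + local` residue-coordinate arithmetic.
- **`cppr.target_scan`** — mismatch-tolerant binding-site scanning (wildcard
  `N` matches anything), telomeric-primer annotation (5′ spacer vs 3′
  telomeric phase), and a G-quadruplex consensus flag.
- **`cppr.bindnseq`** — Bind-n-Seq analysis: anchored flank trimming with an
  exact insert-length filter, per-position base frequencies with information
  content in bits, and discriminative k-mer enrichment scored by a one-sided
  hypergeometric exact test with Bonferroni E-values.
- **`cppr.synthetic_data`** — matching synthetic libraries: a uniform random
  insert pool and an `ε^m` selection model (an insert with *m* mismatches to
  the design target survives the pull-down with probability `ε^m`).
- **`cppr.structure_metrics`** — PDB-based observables: per-class heavy-atom
  counts, distance-based hydrogen-bond detection, the inter-repeat
  Arg16/Glu18/Glu19 and Lys28/Glu26 b-helix network, rearrangement counts
  between apo and bound states, and superhelix extent (max pairwise Cα–Cα
  distance).

## Worked example

```python
>>> from cppr import build_design, scan_sequence, annotate_telomeric_primer
>>> d = build_design("TTAGGGTTAG", name="telo1")
>>> ["".join(p) for p in d.repeats]
['ND', 'ND', 'TN', 'TD', 'TD', 'TD', 'ND', 'ND', 'TN', 'TD']
>>> len(d.protein)                      # 4-aa cap + 10x35 repeats + 14-aa helix
368
>>> d.protein[159]                      # Arg16 of repeat 5 = residue 160
'R'
>>> scan_sequence(d, "GGTTAGGGTTAG", max_mismatch=0)
[ScanHit(offset=2, mismatches=0, matched_window='TTAGGGTTAG', strand='+')]
>>> ann = annotate_telomeric_primer("CTAGACCTGTCATCATTAGGGTTAGGGTTAGGG")
>>> ann.spacer_len, ann.telo_len
(15, 18)
```

The design reads its target 5′→3′ with repeat 1 at the N terminus: thymines
get the (N, D) pair, adenines (T, N), guanines (T, D). The scan locates the
10-nt site at offset 2 of the 12-nt probe, and the 33-nt extension-assay
primer splits into a 15-nt non-telomeric spacer plus 18 nt in phase with
`TTAGGG`.

A full in-silico Bind-n-Seq run (simulate → trim → enrich) is two calls:

```python
>>> from cppr import simulate_bindnseq, trim_and_filter, kmer_enrichment
>>> sel, bg = simulate_bindnseq("TTAGGGTTAG", n=20_000, epsilon=0.3, seed=42)
>>> inserts, _ = trim_and_filter(str(r.seq) for r in sel)
>>> controls, _ = trim_and_filter(str(r.seq) for r in bg)
>>> kmer_enrichment(inserts, controls, k=10)[0].kmer
'TTAGGGTTAG'
```

The designed target comes out as the top-ranked 10-mer, and the predicted
base exceeds the 0.25 background frequency at every one of the 10 positions.

A `cppr` console command wraps the same functions
(`cppr design`, `cppr scan`, `cppr annotate-primer`, `cppr bindnseq
simulate/analyze`, `cppr struct hbonds/junctions/compare/length`).

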