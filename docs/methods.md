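# Methods

## The recognition code and its scope

The toolkit treats base recognition by a consensus PPR repeat as a pure
lookup: the amino-acid pair at repeat-local positions 5 and 35 determines
the bound base, with the canonical four entries (T,N)→A, (N,S)→C, (T,D)→G,
(N,D)→T/U. Three modelling choices follow:

- **U ≡ T.** The same pairs bind RNA and ssDNA, so the code does not
  distinguish uracil from thymine; everything internal uses T and RNA
  display is a rendering concern. The code is identity-only: it does not
  encode the (real) affinity asymmetry by which poly(T) ssDNA binds far more
  weakly than poly(U) RNA.
- **Wildcard fallback.** A residue pair absent from the table maps to `N`
  rather than raising, so natural PPR arrays with non-canonical pairs can be
  reverse-engineered and their predictions scanned; `N` matches every base
  and never counts as a mismatch.
- **The table is data.** It ships as a TSV config and can be replaced or
  extended without code changes; loading rejects a table in which one pair
  maps to two bases or a base has no pair.

## Scaffold assembly and residue arithmetic

A design is `MGNS` + one 35-aa consensus repeat per target base + the
`VTYTTLISGLGKAG` solvating helix. Repeat 1 (N-terminal) reads the 5′-most
base. The default consensus repeat is
`VVTYTTLISGLGKAGRLEEALELFEEMKEKGIKPD`-style with the two specificity slots
variable; it is validated on load against the structurally constrained
positions (Val2, Lys13, Arg16, Glu18, Glu19, Glu25, Glu26, Lys28). Its
positions 2–15 equal the solvating helix — the helix is the a-helix of a
would-be next repeat, which is the internal consistency check behind the
default template. The template is likewise user-replaceable config.

Residue numbering is arithmetic: `global = cap_len + 35·(repeat−1) + local`.
This reproduces the standard annotation anchors (Arg16 of repeat 5 = residue
160, Lys28 of repeat 4 = 137, Glu19 of repeat 9 = 303 with a 4-residue cap).
Note one published figure legend labels the repeat-local position of
Glu170/Glu205/Glu240 as 29; the arithmetic (which fits every other anchor)
places those residues at local position 26, and this package follows the
arithmetic rather than silently renumbering.

Reverse engineering (`parse_design`) requires the length to decompose as
cap + 35·R + helix and tolerates up to 20% mismatches per repeat at
non-variable template positions (default; configurable), so drifted or
natural repeats still parse; the specificity slots are always read verbatim.
Codon-level gene design is out of scope.

## Scanning

Scanning is exhaustive Hamming matching of the design's specificity string
over every window, 0-based half-open coordinates, ties broken by offset.
ssDNA has no strand, so reverse-complement scanning is opt-in for dsDNA
inputs. Per-position weights are supported (terminal positions of a target
contribute least to affinity) but default to uniform since no quantitative
weights are established. Telomeric-primer annotation takes the longest 3′
suffix in phase with the tiled repeat unit; a trailing coincidence shorter
than one full unit (e.g. a lone `A`) is not called telomeric, which is what
makes a pure-spacer primer annotate as 0 nt telomeric. The G-quadruplex
flag is the standard consensus (four runs of ≥3 G, loops of 1–7 nt) and is
a motif heuristic, not a folding prediction.

## Bind-n-Seq analysis

Trimming is anchored: the 5′ flank must match at the read start and the 3′
flank at the read end, each within `max_flank_mismatch` substitutions
(default 1 per flank, the anchored equivalent of adapter trimming with two
adapters); trimmed inserts must be exactly the construct's insert length
(default 10 nt). All rejections are tallied, never raised.

Enrichment replaces regular-expression motif elicitation with exact k-mer
counting: every k-mer occurring in the selected pool is tested against its
background occurrence count with a one-sided hypergeometric exact test on
the 2×2 occurrence table, and the E-value is the p-value times the number
of distinct k-mers tested (Bonferroni). This is deliberately simpler than a
heuristic motif search: the claim being tested — that the designed target
is the most enriched k-mer and the predicted base dominates every position —
does not need one. Results are ordered by p ascending, ties by selected
count descending then lexicographic. Position matrices report per-position
frequencies and information content `2 + Σ_b f_b log2 f_b` bits (0 =
uniform, 2 = fixed); `logo_matrix()` gives the information-scaled
frequencies a logo plotter consumes.

## Synthetic libraries

The generator emulates the printed library construct
(`CTTTATCCAGCCCTCAC` + N₁₀ + `CTATAGTGTCACCTAAATC`) with uniform i.i.d.
inserts, and a selection step in which an insert with *m* mismatches to the
design target survives with probability `ε^m`. This is the simplest
monotone model consistent with binding degrading over a 1/3/5-mismatch
probe series; it fits no real affinities. Sequencing errors are
substitution-only (indels would only complicate anchored trimming without
adding test value); qualities are constant placeholders. PCR bias and
duplicates are not modelled.

Defaults: `ε = 0.3`, 20,000 reads per pool, seed 42. The depth is a free
choice (no published depth exists for this assay); 20,000 reads give the
exact target an expected count of ≈30 in the selected pool — comfortably
detectable yet far from degenerate. Under `ε^m` selection the retained-pool
distribution factorises per position: the predicted base appears with
probability `1/(1+3ε)` (≈0.53 at ε=0.3) and each other base with
`ε/(1+3ε)`, which is what the parameter-recovery tests check against.
Because Bernoulli `ε^m` thinning keeps only ≈0.06% of a uniform pool, the
pipeline reaches a fixed selected depth by streaming candidate inserts
through the same retention model in batches until the requested number
survive; `select_library` itself remains the pure thinning operation. All
randomness flows from one seed through spawned substreams, so runs are
bit-reproducible.

What passing these tests shows: the analysis correctly inverts the
generative model it assumes (anchored construct, independent per-base
selection, substitution noise). What it does not show: robustness to PCR
jackpots, ligation bias, indels, or secondary-structure-driven selection in
real libraries.

## Structural metrics

Coordinates are parsed with gemmi; alternate locations resolve to the
highest occupancy (ties: alphabetically first label), after which
(chain, residue, atom name) is unique. Residues classify as
protein/DNA/RNA/water/other by standard residue-name sets with gemmi's
tabulated residues as fallback; atom counts are heavy atoms only.

Hydrogen bonds are heavy-atom N/O–N/O contacts between different residues
within a cutoff, with contacts under 2.2 Å discarded as covalent-range. No
angle term is applied because the models of interest carry no hydrogens.
The default cutoff is 3.5 Å, configurable to 4.0 Å — some genuine but long
bonds (threonine–adenine contacts at 3.6–3.9 Å) only register at the wider
setting, and whether the junction-rearrangement count is cutoff-sensitive
on deposited models is an empirical question left to the user's cutoff
choice.

The inter-repeat network evaluates, per junction j (between repeats j and
j+1): Arg16(j+1)–Glu19(j+1), Arg16(j+1)–Glu18(j) and Lys28(j)–Glu26(j+1),
using side-chain donor/acceptor atoms only (NE/NH1/NH2, NZ, OE1/OE2).
Residue numbers come from the cap+35·(r−1)+local arithmetic, so the model
numbering must match the design numbering. A junction with missing
residues is flagged indeterminate, reported, and excluded from the
rearrangement count, which tallies junctions whose Arg16–Glu19 bond is
present in the apo model and lost in the bound one.

Superhelix length is defined as the maximum pairwise Cα–Cα distance — the
measurement convention is recorded in output because "length" of a curved
solenoid is not otherwise well defined, and alternative conventions
(axis arc length, terminal-residue distance) can differ by a few Å.

The test suite exercises these metrics on synthetic solenoid models built
to a specified geometry (a 10-repeat skeleton whose junction bonds sit at
2.9 Å, with three glutamates displaced in the bound state and Cα extents of
104 Å and 64 Å). Passing shows the machinery measures what it is defined to
measure; validating against deposited coordinate files requires fetching
them (a `fetch_pdb` helper is provided) and is not part of the offline
suite.

## Numerical and degenerate-input choices

- Exact-test tails come from `scipy.stats.hypergeom.sf` and are validated
  in the tests against a `math.comb` enumeration on all tables with pooled
  totals ≤ 12.
- Empty scan queries shorter than the design warn and return no hits rather
  than raising; empty insert collections and mixed-length inserts raise.
- Seeds: every stochastic function takes a seed or Generator; derived
  streams are spawned, never reused.
- Problem sizes in the default suite (20,000-read pools, 30-nt round-trip
  targets, ≤160-atom brute-force hydrogen-bond oracles) were chosen as the
  smallest sizes at which the statistical checks are far from their
  decision boundaries.
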