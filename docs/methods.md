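# Methods

This note documents the models, algorithms, defaults, and numerical choices
behind `upomine`, and what its synthetic-data tests do and do not establish
about real proteomes.

## Sequence model and coordinates

Sequences are peptides over the 20 canonical residues plus `X`. On input,
letters outside that alphabet (ambiguity codes B/Z/J, the rare U/O, gaps,
internal stops) map to `X` and a single terminal `*` is stripped; the mapping
is idempotent. Real fungal gene models contain `X` runs, and discarding such
records would silently bias a screen, so ambiguity is tolerated and
propagated instead: an `X` in a sequence matches only wildcard positions of a
motif (never a specific residue class), and molecular weights computed over
`X`-containing sequences count 110 Da per unknown residue and carry an
`uncertain` flag.

All coordinates in reports and results are 1-based inclusive, matching the
residue numbering used in the structural literature for AaeUPO (Cys36,
Arg189, Glu196). The single exception is the optional BED-like motif export,
which uses 0-based half-open intervals as that format requires.

## Motif registry

Motifs are fixed-length exact residue-class patterns: a literal letter, a
class `[ABC]`, or the wildcard `X`. There are deliberately no quantifiers
and no probabilistic models — the grammar this package implements is defined
by exact patterns, and a scanner whose behavior is exactly checkable against
a naive sliding window is worth more here than extra sensitivity.

The default registry contains:

- the previously known catalytic core: `PCP`, the distal tripeptides
  `EGD` (UPO) and `EHD` (CPO), and the `EAD`/`ETD` distal variants observed
  in UPO-like CPO sequences;
- sixteen newly reported conserved motifs: `S[IL]G` and `SXXRXD` (present in
  essentially all UPOs; SXXRXD is absent in MroUPO, hence independently
  relaxable), the NHG variant family, and thirteen subfamily signatures.

Signature sets per subfamily:

| Subfamily | Signatures |
|---|---|
| I  | NHG variant `[SN]HG`, `FXD`, Cys-Cys rule, `HXXF` |
| II | `NHG`, `RGN`, `IDG`, `TXXXXXXR`, `VPPLPG`, `HXXF` |
| III| `NHG`, `G[ML]G` |
| IV | `NH[GN]`/`NYG`, `CDA`, `FXXXDG`, `GAAXXXYE`, `HXXF` |
| V  | `NHG`, `EDXXH`, `GXG` |

Two registry conventions deserve explanation. First, the NHG family is kept
as a *single* motif whose acceptable variant differs per subfamily, because
the variants overlap (`NHG` satisfies both `[SN]HG` and `NH[GN]`) and
treating them as independent motifs would double-count shared evidence.
Second, the Subfamily-I disulfide evidence has no local sequence pattern; it
is carried as a rule — at least two cysteines outside the PCP motif — and
flagged `weak-cys-evidence` wherever it contributes to a call. Conflicting
subfamily attributions that exist for `RGN` and `G[ML]G` are resolved in
favor of the signature table and noted in the registry entries' `note`
fields rather than silently dropped.

The registry is editable: `save_registry`/`load_registry` round-trip it
through YAML, and every pipeline entry point accepts a registry path.

## Core grammar

`find_core_grammar` searches for an ordered chain of motif hits:

- **UPO_core**: `PCP < S[IL]G < EGD < SXXRXD < R < E` with exactly six
  residues between the stabilizer arginine and the catalytic glutamate.
- **UPO_like_CPO**: the same chain with distal `EGD`/`EAD`/`ETD` and spacing
  6 or 7 (tried only after UPO_core fails, so the canonical EGD + 6
  combination is never mislabeled).
- **CPO_core**: `PCP < EHD < E`; no stabilizer position is defined.

Each chain element must start strictly after the previous element ends.
When several stabilizer/glutamate pairs are possible the left-most pair
satisfying the spacing constraint is chosen (ordered by arginine position,
then glutamate position) — deterministic, and consistent with the one
experimentally characterized exemplar. Overlapping motif hits are all
reported; multiplicity is never penalized. Sequences shorter than 60
residues (configurable) are classified `none` without scanning, as they
cannot host the full anatomy.

`aromatic_context` counts F/Y/W within ±15 residues of the distal motif
midpoint. It is a sequence-level descriptor of the aromatic lining of the
substrate channel and is reported as an annotation only — it is not a
structural check, makes no claim of equivalence to one, and never filters
candidates.

## Homology screen

The screen is pairwise Smith–Waterman local alignment (BLOSUM62, gap open
11, extend 1 — the community default, configurable) with Karlin–Altschul
statistics:

```
E = K · m · n · exp(−λ·S)
```

where `m` is the query length and `n` the summed residue count of the
proteome. For the default scheme the gapped parameters are the standard
empirical values (λ = 0.267, K = 0.041). For custom *ungapped* schemes,
`calibrate_lambda` solves `Σ pᵢpⱼ exp(λ sᵢⱼ) = 1` by bracketed root-finding
to 1e-12; a scheme without an empirical K falls back to a conservative
K = 0.1 and should be calibrated by the user for serious use.

A BLAST-style edge-effect length adjustment was evaluated and rejected: at
the sequence lengths this package typically screens (~80–500 residues) the
fixed-point collapses the effective lengths and inflates acceptance roughly
tenfold. The plain formula empirically yields ≈1–3 accepted random decoys
per 100 searches at the 0.01 inclusion threshold — consistent with the
threshold's interpretation — and keeps E exactly linear in both lengths.

Two-tier thresholds: hits with E ≤ 10 are reported, hits with E ≤ 0.01 are
accepted into the funnel. Both are exposed as `--evalue` / `--inclusion`.

## Clustering

**Greedy identity clustering** follows the cd-hit algorithm: sort by length
descending (ties by id), join the first existing cluster whose
representative shares ≥ 90% identity, else found a new cluster. Identity is
identical aligned positions divided by the *shorter* sequence's length, on
the optimal local alignment. The word-length-5 prefilter skips only pairs
sharing no 5-mer at all; at a 90% cut-off such pairs cannot reach the
threshold, so the partition is provably unchanged (asserted in tests by
running with and without the filter).

**MCL** operates on the bit-score similarity graph of the greedy
representatives plus the seed (query): add self-loops (weight = maximum
incident edge weight; 1 for isolated nodes), column-normalize, then
alternate expansion (matrix squaring) and inflation (elementwise power 1.4,
renormalize), pruning entries below 1e-8, until the maximum column change
falls below 1e-6 or 100 iterations (non-convergence returns the current
interpretation with a logged warning). Clusters are the weakly connected
components of the positive entries of the converged matrix. The matrix is
built over sorted node ids, so input order never affects the partition.
Self-loop weight, pruning, and tolerance are package choices (the MCL
stage's upstream description fixes only the inflation value); all are
exposed as configuration. Edge weights default to bit scores with
−log₁₀E available behind a flag.

Only the cluster containing the seed is retained, and retained
representatives are expanded back to their greedy-cluster members before the
grammar stage, so redundancy removal never costs recall.

## Classification

For each grammar-positive sequence the full registry is scanned; the
subfamily score is `matched signatures / total signatures`, and the arg-max
subfamily is assigned when the score is ≥ 0.5 **and** at least two
signatures matched (a single 3-mer is too weak to carry a call). Ties and
sub-threshold scores yield `unassigned` with all five scores reported. The
0.5/2 rule is this package's operationalization of "shared signature
motifs" — the underlying taxonomy was defined jointly by phylogeny and
motif content without a numeric rule — and both constants are configurable.

CPO-grammar sequences bypass signature scoring: the Pog superfamily is a
phylogenetic clade, not a motif class, so placement is by tree proximity.
A neighbor-joining tree is built over the candidates plus anchor sequences;
a candidate is Pog when its nearest anchor by path length is a Pog exemplar,
else classic CPO. Exact ties go to Pog with a `tie` flag — conservative
toward the superfamily, which is the hypothesis-generating label. Without
anchors the call is deferred with a `needs-tree` flag.

Molecular weights are average (isotope-abundance) masses: the sum of
anhydrous residue masses plus one water, via Biopython's tables. The
Group-I/II threshold of 35 kDa is the midpoint of the two reported group
averages (29 and 44 kDa); no cut-off is defined by the groups themselves,
so the midpoint is the least informative choice.

## Trees

`protein_distance` is the Kimura-corrected distance
`d = −ln(1 − p − 0.2 p²)` with `p` the fraction of differing residue pairs
over the gap-free aligned columns of the optimal local alignment; `p ≥ 0.85`
is outside the correction's domain and is capped at 5.0 with a logged
warning. Neighbor joining (scikit-bio's implementation, negative branch
estimates clamped to zero) is exact on additive matrices — the property the
test suite leans on. The two-taxon case is the single edge with the distance
split evenly. Newick output uses 6 significant digits and quotes labels
containing spaces or metacharacters. This stage exists to support anchor
placement and sanity checks; it does not attempt model-based phylogenetics,
bootstrap support, or rooting beyond an optional midpoint display.

## Synthetic data

The generator emulates the statistical situation the pipeline faces —
a few grammar-conformant targets hidden among unrelated proteins — under
fixed default conditions:

- 30 planted UPO sequences, six per subfamily, among 500 uniform-background
  decoys of 200–500 residues;
- one master UPO template of 270 residues on the AaeUPO coordinate anatomy
  (PCP≈35, S[IL]G≈60, distal≈122, SXXRXD≈130, Arg≈189, spacing 6), each
  anchor jittered by ±10 positions per generation so position-hardcoding
  bugs are caught; the master doubles as the screening query;
- per-subfamily founders derived from the master at 20% divergence plus the
  subfamily's signature block; members as 3% substitution clouds around
  their founder (strain-level divergence, keeping clouds above the 90%
  clustering cut-off while founders stay well below it);
- optional CPO-grammar sequences: two anchors derived from the master at
  45% divergence with EGD swapped to EHD and the UPO support motifs
  scrubbed, plus members within a 12-substitution budget of their anchor.

Construction guarantees are enforced, not hoped for: planted sequences are
re-scanned and any registry hit outside the planted intervals is mutated
away (wildcard fills are chosen to avoid spawning other registry motifs
inside a planted instance; structurally unavoidable overlaps such as the
GXG match inside every G[ML]G are kept — they can never complete a rival
signature set). Stray cysteines outside planted intervals are removed so the
disulfide rule remains exclusive to Subfamily-I plants. Decoys are resampled
until they carry no complete core grammar. Every planted sequence is
verified against its intended grammar class before emission, and the truth
table labels every emitted id exactly once. All sampling is integer-based,
so a seed fixes the output bit-for-bit.

**What passing synthetic tests shows — and does not.** The generator
produces substitution-only homolog clouds with uniform background, no
indels, no compositional bias, no domain architecture, and no phylogenetic
signal beyond the template hierarchy. Perfect recall and zero false
positives under these conditions validate the *pipeline logic* (thresholds
compose correctly, no stage loses a true positive, the grammar and scoring
do what they claim); they do not estimate sensitivity or specificity on real
proteomes, where gene-model truncations, indels in motif neighborhoods, and
biased composition all occur. The E-value calibration check is similarly a
consistency check of the extreme-value model on shuffled sequences, not a
benchmark against a profile-HMM search.

## Problem sizes and determinism

The test and acceptance workloads are sized for a single CPU: the full
mining study runs 530 sequences against one query (~seconds); oracle sweeps
use 400–1000 random sequences for the scanner, several hundred short pairs
for alignment, 60 small graphs for MCL, and 200 additive matrices (n ≤ 8)
for NJ; the E-value simulation runs 500 searches of an 80-residue query
against 40 shuffled decoys. Every stochastic component takes an explicit
seed; pipeline reruns with identical config and inputs produce byte-identical
reports (timestamps are deliberately excluded from outputs).

## Known limitations

- Exact-pattern motifs cannot express indel tolerance; a single insertion
  inside SXXRXD hides the motif (the relaxation flags exist for exactly the
  one known natural case, MroUPO).
- The screen is pairwise, not profile-based: remote homologs that a
  profile-HMM would recover can fall below the inclusion threshold.
- Karlin–Altschul constants are empirical for the default scheme only;
  custom gapped schemes need user calibration.
- Pog/classic-CPO placement inherits NJ's sensitivity to non-additive
  distances; with very distant anchors the placement should be read as a
  hypothesis, not a verdict.
- The aromatic-context count is a crude stand-in for a structural
  binding-cavity analysis and is reported for triage only.
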