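# upomine

Mining fungal proteomes for **unspecific peroxygenases (UPOs, EC 1.11.2.1)**
and classifying them against the conserved motif grammar of heme-thiolate
peroxidases.

UPOs are secreted fungal enzymes that transfer peroxide-borne oxygen onto an
unusually broad range of substrates, which makes them attractive industrial
oxyfunctionalization biocatalysts. They share a proximal cysteine heme ligand
with chloroperoxidases (CPOs) but differ in their distal-side machinery.
`upomine` is for sequence analysts who want to screen translated proteomes
(peptide FASTA) for UPO candidates and sort them into subfamilies without any
web services or structure prediction: everything runs locally from the motif
grammar, pairwise alignment statistics, and a light distance-based tree.

## The grammar and the taxonomy

A candidate passes the **UPO core grammar** when it carries, in order,

```
PCP  <  S[IL]G  <  EGD  <  SXXRXD  <  R ——6 residues—— E
```

— the Pro-Cys-Pro proximal heme ligand (Cys36 in AaeUPO numbering), the
S[IL]G and SXXRXD support motifs, the distal Glu-Gly-Asp tripeptide, and the
Arg/Glu acid-base catalyst pair with exactly six intervening residues
(Arg189/Glu196 in AaeUPO). CPOs instead satisfy `PCP < EHD < E` (His-mediated
distal side, no arginine stabilizer). Sequences with an EAD/ETD distal
variant and/or a seven-residue pair spacing receive the intermediate
`UPO_like_CPO` verdict.

Grammar-positive sequences are then scored against per-subfamily signature
motif sets (subfamilies I–V; e.g. `EDXXH` + `GXG` for Subfamily V,
`G[ML]G` for Subfamily III): the score is the fraction of a subfamily's
signatures present, and the arg-max subfamily is assigned at score ≥ 0.5 with
at least two motifs matched. CPO-grammar sequences are placed as the mixed
peroxidase-peroxygenase (**Pog**) superfamily or classic CPOs by
neighbor-joining proximity to user-supplied anchor sequences (an MroUPO
homolog and a classic CPO such as LfuCPO). Each sequence also gets a mass
class — Group-I (short UPOs, ≈29 kDa average) below 35 kDa, Group-II
(long UPOs, ≈44 kDa) above.

The mining funnel mirrors classic genome-mining practice:

1. **Homology screen** — Smith–Waterman local alignment against the query
   under BLOSUM62 (gap 11/1) with Karlin–Altschul E-values; reporting
   threshold E ≤ 10, inclusion threshold E ≤ 0.01 (≈1 random false positive
   per 100 searches).
2. **Greedy identity clustering** — cd-hit-style incremental clustering at a
   90% identity cut-off with a word length of 5.
3. **Markov clustering (MCL)** at inflation 1.4 over the bit-score similarity
   graph, retaining only the cluster containing the seed/query.
4. **Grammar filter + classification** as above.

## Worked example

Generate a synthetic proteome with planted UPO/CPO sequences among decoys,
then mine it:

```bash
upomine simulate --out sim --seed 42 --decoys 100 --per-subfamily 2 \
        --pog-like 1 --classic-like 1
# 112 sequences written to sim
upomine mine sim/proteome.fasta --query sim/query.fasta --out run \
        --anchors sim/anchors.fasta --pog-anchor anchor_pog --cpo-anchor anchor_cpo
# run written to run
cat run/run_log.tsv
```

```
config_hash     73986768d08b
input_sequences 112
screen_accepted 12
greedy_clusters 7
mcl_retained    12
grammar_passed  12
```

All 12 planted targets survive the funnel and none of the 100 decoys do.
`run/classification.tsv` holds the final calls (excerpt):

```
record_id          grammar_class  family       group    weight_kda  score  evidence
upo_V_0            UPO_core       V            Group-I  32.18       1.000  NHG_family,EDXXH,GXG
upo_III_0          UPO_core       III          Group-I  32.78       1.000  NHG_family,G[ML]G
upo_I_0            UPO_core       I            Group-I  32.77       1.000  NHG_family,FXD,CYS_CYS,HXXF
cpo_pog_0          CPO_core       Pog          Group-I  32.58       0.000
cpo_classic_cpo_0  CPO_core       classic_CPO  Group-I  32.24       0.000
```

Each row shows the grammar verdict, the subfamily (or tree-placed
Pog/classic-CPO label), the Group-I/II mass class with the computed
molecular weight in kDa, the matched-signature score, and the motif evidence
behind the call. `sim/truth.tsv` carries the generator's ground truth, so
recovery is directly checkable. `upomine classify`, `annotate-motifs` and
`tree` expose the later stages for pre-selected candidate sets.

## Scope notes

Proteomes are consumed as translated peptide FASTA only. Motifs are exact
residue-class patterns (no PSSMs/HMMs). The tree stage is distance-based
(Kimura-corrected NJ) and exists for relative anchor placement, not for
publication-grade phylogenetics; see `docs/methods.md` for the full model
description, parameter defaults, and limitations.
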