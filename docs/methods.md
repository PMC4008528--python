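# Methods

This note documents the models, parameters and design choices behind
`comcensus`, and what the synthetic validation does and does not establish.

## Profile HMMs

**Architecture.** One node per seed-alignment match column (match columns =
gap fraction strictly < 0.5, pinned by a boundary test). Each node `k` has a
match state (emitting), an insert state `I_k` (emitting; `I_0` precedes the
first node) and a silent delete state; transitions from each of
`{M_k, I_k, D_k}` go to `{M_{k+1}, I_k, D_{k+1}}`, with node `M` exiting to
End. Emissions and transitions are maximum-likelihood counts from the seed
alignment with +1 Laplace pseudocounts. Laplace pseudocounts (rather than
Dirichlet mixtures) keep every parameter reproducible by a hand count and
make the exhaustive-enumeration oracle exact; the census needs rank
separation between family members and decoys, not matcher-exact scores.
The background distribution is the seed alignment's residue frequencies
mixed 1:1 with uniform 1/20.

**Scoring.** Glocal mode: global in the model, local in the sequence. Free
flank states absorb any prefix/suffix at background odds (odds contribution
exactly 1), so a short ComX model can hit inside a longer mispredicted ORF.
The reported score is `log2 P(seq|model)/P(seq|background)`; forward sums
over all (entry, path, exit) combinations, Viterbi maximizes. The forward
recursion runs in probability space with per-position rescaling; the silent
delete chain is resolved blockwise via cumulative products (block 64 keeps
the running product inside float64 range). Scores whose residual path mass
underflows (~ below −1000 bits) saturate at a finite floor; such scores are
orders of magnitude outside any acceptance region. Non-standard residues
(X, B, Z, ...) emit at background odds, i.e. contribute 0 bits.

**Calibration and E-values.** `(μ, λ)` of a Gumbel are fitted by maximum
likelihood to forward bit-scores of `n_null = 500` i.i.d. sequences of
Robinson-Robinson composition with length equal to the model length. The
E-value is the Gumbel tail `E = N·exp(−λ(s−μ))` with `N` = number of
proteins scanned in the current run, recorded on every hit. This is a
deliberate simplification of matcher-internal calibration (which uses
exponential tails for forward); at the survey's operating point (E ≈ 0.1,
true hits hundreds of bits above the null) the difference is immaterial.
The 0.1 threshold is applied per sequence.

## Census rules

Acceptance of a hit requires all of: E < 0.1; protein length inside the
role's range (ComQ 286-309, ComX 52-73, ComA 196-245 aa — the ranges of the
reference families — and ComP 700-800, wide enough for the frame-extension
variants); a tryptophan in the C-terminal 10 residues for ComX (the
permissive bound of the signal-tryptophan window); both the
histidine-kinase and ATP-binding sub-domain recognizers below E < 0.1 for
ComP; and Viterbi match-state coverage ≥ 60% of the model, which
operationalizes the manual "alignment coverage" check. Rejected hits go to
a JSONL audit log naming the failed criterion. Transmembrane-helix counts
(Kyte-Doolittle, 19-residue windows, mean > 1.6, runs closer than 5
residues merged) are annotation only — receptors lacking the membrane
domain exist in both clades, so no hard filter.

Loci are maximal same-contig, same-strand chains of accepted hits with
consecutive gaps ≤ 600 bp and ≤ 1 intervening annotated gene, whose roles
follow comQ-comX-comP-comA along the strand (coordinate-reversed on −).
"Adjacent" is not quantified in the survey literature; 600 bp / 1 gene
passes every generated geometry (including the annotated unusual comX
sitting between comQ and comP) while excluding the dispersed decoys, and
both are configuration keys. Chains with ≥ 2 roles but not all four are
kept as `incomplete`; chains holding exactly comQ, comP, comA trigger an
ORF search of the comQ-comP span on both strands for a start-codon ORF
(ATG/GTG/TTG) of ComX length with the C-terminal tryptophan — longest wins,
ties to the leftmost start; a same-strand find is labeled
`hypothetical_comX`, an opposite-strand find `antisense_comX`.

Overlap typing is pure coordinate arithmetic on the consecutive pairs
(QX, XP, PA): `{} → A`, `{QX} → B`, `{QX,XP} → C`, `{PA} → D`,
`{XP,PA} → E`, anything else `other`; lengths are reported in bp and as
`bp // 3` aa. The A-E letter legend is reconstructed from the clade
narrative (B/C in the *B. subtilis*-like clade, D/E in the other); the
mapping is a single table in `classify_overlap` should it need revisiting.

## Synthetic data: what it emulates

**Evolution model.** Site-independent Poisson substitutions with uniform
replacement among the 19 alternatives — the 20-state Jukes-Cantor analogue,
chosen because it has the closed-form expected p-distance
`(19/20)(1−exp(−(20/19)d))` used as the generator's own oracle. Leaves sit
`divergence_within` (default 0.1) from their clade ancestor; clade
ancestors sit `divergence_between` (default 0.5) apart.

**Study conditions.** Two multipliers shape the within-clade branch:
`family_divergence_scale` (ComQ 1.8, ComX 2.5, ComP 1.0, ComA 0.5) and
`clade_divergence_scale` (non-bsub-like 1.6). They were set once from the
closed form so that the per-family π values fall in the region of the
reported survey table and reproduce its two directional claims — the
second clade more diverse for every protein, and
ComX > ComQ > ComP > ComA within each clade — while leaving every family
detectable by its recognizer. ComX additionally carries a hypervariable
C-terminal quarter (site rates 2.5 vs 0.6, normalized to mean 1) with the
signal tryptophan hard-masked, mirroring the concentration of its
variability at the C terminus.

**Overlap construction.** A k-residue frame extension is realized as a
`3k+1` bp overlap. A `3k` bp overlap would put both genes in the same
frame, and two well-formed overlapping CDSs cannot share a frame (the
upstream stop would be an internal in-frame codon of the downstream gene),
so `3k+1` is the smallest realizable geometry consistent with the reported
extension lengths; the census reports it back as `bp // 3 = k` aa. Types
use the reported extensions: B = comQ C-extension of 13-18 aa (sampled per
locus), C adds a 14-aa comP N-extension, D = 21-aa comP C-extension into
comA, E = 3-aa comP N-extension into comX plus the PA overlap. Overlap
nucleotides are constructed codon-first: synonymous choices in the carrier
gene place the required stop/start of the second frame and keep it
stop-free; where no synonymous assignment exists a single residue is
relaxed, and ground truth always records the realized proteins. Every
constructed block is verified by re-translation before it is emitted.

**Unusual loci** (non-bsub clade only, probability `p_unusual = 0.1`) use
the no-overlap geometry with a random 73-aa protein (tryptophan at −6) in
the comX slot, annotated on the same or the opposite strand. Length 73 —
the top of the ComX range — guarantees no spurious intergenic ORF can
out-rank the planted one in the rescue search.

**Decoys** (4 per genome) cycle through a full-length ComP-family kinase, a
ComA-family regulator, a ComQ-family transferase and a random-composition
protein, each appended with > 700 bp clearance so they can never satisfy
the adjacency rule; the family decoys deliberately *do* pass the hit
filters, exercising the two-role floor of locus assembly.

**What passing does not show.** The generator has no indels, rearrangements,
codon bias, annotation errors, or horizontal transfer; contigs are single
and complete. Perfect sensitivity/specificity on this data validates the
pipeline's logic (filters, assembly, typing, rescue) — not its performance
on noisy draft genomes, where annotation quality and alignment would
dominate.

## Diversity

π uses pairwise deletion by default (columns gapped in either member of a
pair are skipped, per-pair); `gap_mode="complete"` drops every gapped
column first. The standard error comes from a seeded 500-replicate site
bootstrap rather than an analytic variance. Conservation profiles average
BLOSUM62 similarities over all ordered row pairs per column (a gap against
anything scores the matrix minimum) and smooth with a moving window of 4 —
the classic positional-similarity plot.

## Trees and statistics

**Neighbor joining** (Saitou-Nei) on pairwise p-distances replaces the
progressive-alignment guide trees used historically: it is the standard
distance method with a checkable exactness property (tree-additive inputs
are reconstructed exactly, verified on random additive trees up to 12
taxa). Q-matrix ties break on the smallest index pair; negative branch
lengths are clamped to 0 with the excess moved to the sister branch. UPGMA
is available as a config alternative. Bootstrap supports come from column
resampling (default 1000 replicates; fewer in tests for runtime) with
bipartition counting on a shared taxon namespace.

**Clade assignment** treats each clade as the smallest clan (bipartition
side of the unrooted tree) containing all of that clade's anchors and none
of the other's — equivalent to MRCAs after rooting between the anchor
sets. With anchors spanning a clade the assignment recovers it exactly;
with sparse anchors it returns a contained subgroup and never crosses into
the other clade. Non-separable anchors raise an error.

**P-test.** Minimum state changes by Hartigan's bottom-up pass (exact on
multifurcations, reduces to Fitch on binary trees; verified against
brute-force enumeration). The default null shuffles trait labels across
leaves on the fixed tree — exchangeability-equivalent to the "random
phylogenies" formulation and simpler; `null="random_tree"` instead regrows
a random topology per replicate for sensitivity analysis. p-values use the
add-one convention and are never exactly 0.

**F-test.** `F = (θ_T − θ_W)/θ_T`, with θ_T the mean over all pairwise
distances and θ_W the mean over within-group pairs pooled across groups
(groups smaller than 2 are excluded with a warning); significance by
permuting group labels, default 10000 permutations.

**Calibration and power conditions.** Type-I error is checked over 200 null
simulations (P-test: random trees of 40 leaves, four balanced shuffled
states — enough support points that the discreteness of the parsimony
statistic does not make the test overly conservative; F-test: 20 i.i.d.
random proteins in two groups of 10) against the binomial 95% CI of the
nominal 0.05. Power uses 100 simulations of two 16-leaf clades
(within-branch 0.18, between 0.5) with overlap types confined to clades —
B dominant and C rare (85/15) in one, D dominant and E rare in the other,
mirroring the reported dominance pattern — requiring rejection at α = 0.01;
permutations are reduced to 999 for runtime (the add-one p-value floor,
1/1000, still resolves α = 0.01).

## Problem sizes and numerics

The validation census runs 50 genomes per clade plus 10 decoy-only genomes
(~780 proteins); recognizer calibration uses 500 null sequences per model;
bootstrap checks use 200 replicates on 24 taxa; the NJ exactness suite uses
100 random trees; parsimony exactness 500 (tests) / 200 (acceptance script)
random cases. These sizes were chosen as the smallest at which every
property is a stable, reproducible check rather than a coin flip. All
randomness flows from a single seed through spawned generators;
`simulate()` is byte-deterministic, and the determinism check hashes every
emitted file across two independent runs.

Numerical tie-breaks worth knowing: NJ argmin takes the first (row-major)
minimum; locus assembly is leftmost-start greedy; the ORF rescue prefers
longer ORFs, then leftmost starts; π with no comparable sites in a pair is
an error at the matrix level and a missing value at the pair level.
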