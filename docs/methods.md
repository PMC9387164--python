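# Methods

## Retention indices

`chem_profile` implements the Kováts retention index as linear interpolation
of retention time between the two bracketing n-alkanes,

RI = 100·(Z + (Z′ − Z) · (t_X − t_Z) / (t_Z′ − t_Z)),

generalized to ladders whose carbon numbers are not consecutive (Z′ is the
next ladder carbon, not necessarily Z + 1); for consecutive alkanes this is
the classical 100·Z + 100·(t_X − t_Z)/(t_{Z+1} − t_Z). The formula is an
interpolation, so retention times outside the ladder span raise an error
rather than extrapolating — a silent extrapolation would produce indices
with no physical meaning. At a ladder member's retention time the index is
exactly 100·Z (the interpolant vanishes identically, no floating-point
tolerance needed).

Component identity is the normalized (name, CAS) pair: published GC-MS
tables legitimately list the same compound name twice with different CAS
numbers (isomers), and both rows must contribute separately to the weight
cascade. A table that repeats the *same* (name, CAS) pair is rejected; such
rows occur in the wild and must be disambiguated or merged upstream, because
silently merging them would double-count content. Contents are accepted on
the 0–100 percent scale as printed in GC reports; a `content_scale=fraction`
switch converts 0–1 inputs. Oral bioavailability is never imputed — a
component without OB is an error at weighting time, not a default.

## Weight coefficients

With OB ∈ [0, 1] and content I ≥ 0 (percent):

- A = OB · I per component row,
- B(t) = Σ A over components with a (component, target) edge,
- C(p) = Σ B over the pathway's targets that have a B score.

Properties relied on downstream and enforced by tests: the cascade is linear
in both OB and I; a component contributes its full A to every target it
hits (no splitting); duplicate edges from merged prediction databases count
once (repeated database hits are evidence redundancy, not dosage); targets
without edges are absent from B rather than zero-filled. C is a raw sum with
no pathway-size correction — large pathways can accumulate large C simply by
containing many scored targets. This is a deliberate fidelity-to-method
choice, and the reason C is used for *re-ranking within* an enrichment
result rather than as a standalone statistic.

## DEG selection and intersection

DEGs are selected by `fdr < fdr_max` (strict) and `|log2FC| ≥ lfc_min`
(inclusive) with both boundaries configurable, defaults `fdr_max = 0.05`,
`lfc_min = 1`. Published criteria frequently disagree between a methods
section and a results section (≥ 2 vs > 1 is a typical discrepancy), which
is exactly why the boundary semantics here are explicit configuration and
every applied threshold is logged. Genes with log2FC = 0 that pass both cuts
are excluded (they are neither up- nor down-regulated) with a warning, so
`n_up + n_down = |selected|` always holds. The DE statistics themselves
(counts → log2FC/FDR) are upstream of this package.

The key-target set is the plain three-way intersection of component
targets, disease genes and DEGs, after trimming/upper-casing symbols. No
alias or ortholog mapping is attempted; inputs must share one symbol
convention.

## Enrichment and re-ranking

Over-representation uses the upper-tail hypergeometric test,
p = P(X ≥ k), X ~ Hypergeom(N, K, n), equivalent to one-sided Fisher's
exact — the standard ORA test. The universe defaults to all genes appearing
in the GMT (the annotation universe) and is configurable; query and pathway
genes are restricted to it. BH-FDR is applied across exactly the pathways
tested, one family per collection (run GO-BP and KEGG as separate GMT files
to mirror separate correction families). SciPy provides both the
hypergeometric survival function and the BH routine; the test suite checks
them against exhaustive subset enumeration (all universes N ≤ 12) and an
independent step-up implementation.

Re-ranking sorts the same result rows by descending C. It is a pure
permutation: p-values, overlap counts and FDR values are untouched, and
`rank_delta = unweighted_rank − weighted_rank` (positive = promoted).
Tie-breaks are deterministic — unweighted: ascending p, then descending k,
then pathway id; weighted: descending C, then ascending p, then pathway id —
so equal weights reproduce the unweighted order exactly and outputs are
byte-stable. Whether to combine C with p was an open design point; C alone
(with p as tie-break only) was chosen as the most direct reading of
"re-rank by weight coefficient", and because any p/C blend would need an
arbitrary mixing parameter.

## Networks

PPI combined scores arrive in two dialects, 0–1000 integers or normalized
0–1; the reader auto-detects (any score > 1 implies the 0–1000 scale) with
an explicit override. The confidence filter is strictly greater-than, so
0.900 fails a 0.9 threshold — the literal reading of a "highest confidence
(>0.9)" setting. Undirected pairs are canonicalized lexicographically;
reversed duplicates keep the higher score with a warning. The tripartite
network contains component–target edges (weight A) only for key targets,
target–pathway edges (weight B), and optional PPI edges among key targets;
isolated nodes can be dropped ("free proteins hidden"). Centrality and hub
metrics are intentionally not computed — construction, filtering and
SIF/GraphML export only. SIF carries no weights (format limitation);
GraphML preserves node kinds and edge weights.

## Synthetic data: what it emulates, what it does not

`synthetic_data.generate` emits every pipeline input from a single
`numpy.random.default_rng(seed)` instance (no global state; identical
configs give byte-identical files). Defaults state the emulated world:

| parameter | default | rationale |
|---|---|---|
| n_components | 20 | typical size of a GC-MS component table |
| content_concentration | 0.5 | symmetric Dirichlet; yields one dominant component (~30%) |
| ob_range | (0.2, 0.9) | realistic OB spread for volatile terpenoids; never tabulated in practice |
| n_targets / universe | 60 / 500 | small predicted-target set inside a desk-scale gene universe |
| n_key_targets | 26 | key-gene count typical of these studies |
| frac_de | 0.1 | fraction of the universe passing default DEG thresholds |
| planted_de_shift | 2.0 | signal genes get &#124;log2FC&#124; ≥ 2, FDR < 0.04 |
| n_pathways / sizes | 25 / 10–40 | one planted + 4 decoys + background |
| planted_weight_boost | 4.0 | planted targets wired to the top-(boost) components by A |

The planted pathway holds 6 key targets wired to the highest-A components;
decoy pathways hold larger key-target overlaps (better unweighted p) whose
targets carry only baseline edges. When `planted_weight_boost > 1` the
generator deterministically adds further top components to the planted
targets until the planted C strictly exceeds every rival — the guarantee is
constructive, not tuned; with boost = 1 no guarantee is made and the
manifest simply records the realized C ordering. The manifest's A/B/C values
come from an independent brute-force triple loop kept separate from the
pipeline's weighting code.

The DE model is deliberately naive (null: log2FC ~ N(0, 0.3), FDR ~
U(0.05, 1); signal: shifted log2FC, FDR ~ U(0, 0.04)): it tests threshold
mechanics, not DE inference. Consequently a green end-to-end test
establishes that filtering, intersection, weighting, enrichment and
re-ranking compose correctly and that planted weight signal is recovered —
it does **not** establish that real expression data, real target
predictions, or real pathway annotations would produce any particular
ranking, nor anything about the correlated noise, annotation bias and
p-value miscalibration of real studies.

## Numerical choices and limitations

- All ranking tie-breaks are lexicographic on pathway id last, so every
  output is reproducible to the byte on fixed inputs.
- Weight equality in tests uses exact arithmetic where the math is exact
  (ladder-member RI, A = OB·I) and 1e-9..1e-12 relative tolerance where
  accumulation order may differ.
- The hypergeometric p is computed via the survival function at k − 1;
  k = 0 gives p = 1 exactly.
- Known limitations: no pathway-size normalization of C; no gene-alias
  mapping; SIF round-trips lose edge weights; the pipeline treats DEG lists,
  target predictions and disease gene lists as authoritative inputs and does
  not adjudicate conflicts between them.
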