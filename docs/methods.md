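# Methods

## The screen

`pgscreen` looks for orthologous gene groups (OGs) in a bacterial pangenome
whose member sequences co-vary with a binary strain phenotype. The phenotype
here is induced cytokine production (IL-10 or IL-12, pg/mL) measured in
duplicate per strain: the per-strain level is the mean of the two replicates,
and strains at or above the median level of their species form the "active"
group, the rest the "silent" group. Each (species, cytokine) pair defines its
own median and its own bipartition.

For each OG with at least `min_per_group` (default 2) members in *each*
group, the screen computes:

1. **Overall distance matrix.** Pairwise p-distances (fraction of differing
   residues over gap-free columns, pairwise deletion) between the member
   amino-acid sequences, members in lexicographic strain order. Equal-length
   members are taken as aligned; ragged members are globally aligned
   pairwise (match +1, mismatch −1, gap −2, deterministic traceback).
2. **Row embedding.** Strain *i* is represented by row *i* of the overall
   N×N matrix. All three centroids (active, silent, overall) then live in
   the same N-dimensional space, and the exact decomposition
   TSS = BGSS + WGSS holds. (Computing centroids on group submatrices would
   mix incompatible dimensions; `embedding="mds"` offers classical MDS
   coordinates as an alternative reading.)
3. **Cluster validity between phenotype groups.**
   BGSS = Σᵢ nᵢ‖Cᵢ − C‖², WGSS = Σᵢ Σ_{X∈Cᵢ} ‖X − Cᵢ‖², and the
   Calinski–Harabasz index CH = (BGSS/(K−1)) / (WGSS/(n−K)) with K = 2.
4. **Sequence-distribution factor.** seq_dist_factor =
   N_overall / zero_value_count_overall, where zeros are counted over the
   full matrix *including* the diagonal — the factor is exactly 1 when all
   members are distinct and shrinks toward N/N² when members collapse onto
   few identical sequences. It down-weights OGs that would separate
   trivially because most members are identical.
5. **PG index** = CH × seq_dist_factor.

The top 2% of OGs by PG index (count = ⌈0.02·M⌉, floor 1) are re-clustered
with K = 2 k-means on the same row embedding, the CH index is recalculated
with the k-means labels (no seq_dist_factor), and candidates are ranked by
recalculated CH. Candidate lists from the IL-10 and IL-12 comparisons are
intersected at top-k (default 3). Kruskal–Wallis and pairwise two-sided
rank-sum tests with Bonferroni correction compare PG-index distributions
between labeled collections.

Independently of sequence divergence, the **marker screen** flags OGs by
presence pattern alone: present in ≥80% of active strains and ≤50% of
silent strains (both boundaries inclusive).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_per_group` | 2 | members required in each phenotype group (two finite centroids) |
| `top_fraction` | 0.02 | PG-index fraction advanced to re-clustering |
| `top_k_overlap` | 3 | depth of the cross-cytokine intersection |
| `kmeans_restarts` | 10 | k-means++ restarts, best inertia kept |
| `marker_active_threshold` | 0.80 | minimum active presence fraction |
| `marker_silent_threshold` | 0.50 | maximum silent presence fraction |

The classification switches `strict_gt` (active strictly above the median)
and `pooled_median` (one pooled median per species instead of one per
cytokine) implement the two alternative readings of the grouping rule;
the defaults are ≥ and per-cytokine.

## Numerical choices

- **Perfect separation.** WGSS = 0 with BGSS > 0 yields a +inf CH sentinel
  that ranks above every finite score (ties broken by BGSS, then og_id);
  BGSS = 0 yields CH = 0. No epsilon is imposed, since any epsilon would be
  an arbitrary scale. Caveat: the sentinel requires WGSS to vanish *exactly*;
  when a group's rows are identical, floating-point rounding of the group
  mean can leave WGSS ≈ 1e−30 and a finite ≈ 1e30 CH instead. Rankings are
  unaffected.
- **Ties.** Top-fraction selection orders by PG desc, CH desc, BGSS desc,
  family size desc, og_id asc; the score table by PG desc, og_id asc;
  k-means restarts keep the first-best inertia.
- **Degenerate inputs.** All-tied phenotypes make one group empty; the split
  is flagged degenerate and the screen refuses it. Families with < 3 members
  have an undefined recalculated CH and are excluded from candidate ranking.
  All-identical members give recalculated CH = 0, flagged "unplottable".
  A sequence pair sharing no gap-free column gets distance 1 with a warning.
- **k-means.** k-means++ seeding from a seeded generator, Lloyd iterations
  to exact assignment convergence (cap 300), empty clusters repaired by
  reassigning the point farthest from its centroid. Each top-fraction
  candidate gets its own RNG stream spawned from the screen seed, so results
  are independent of processing order.
- **Rank tests.** Kruskal–Wallis uses the tie-corrected H with the
  chi-square approximation; all-identical data return (H=0, p=1). Rank-sum
  p-values use the exact null for small tie-free samples and the normal
  approximation with tie and continuity corrections otherwise; Bonferroni
  multiplies by the number of pairs and caps at 1.
- **Classical MDS.** Torgerson double centering, symmetric eigendecomposition,
  negative eigenvalues truncated to zero, each axis oriented so its
  largest-magnitude loading is positive (deterministic output).

## The synthetic data generator

`pgscreen.simulate` emits a complete, re-readable input set (Roary-dialect
presence table, per-OG FASTA, phenotype CSV) plus a ground-truth record. It
emulates the regime the screen assumes: 30 strains of one species; lognormal
cytokine means (μ = ln 3, σ = 0.8 — right-skewed with a median of a few
pg/mL, the scale of typical strain panels) with duplicates at ±≤5%; a
pangenome of 120 core and 77 accessory null families (background per-site
diversity 0.02, accessory presence probability 0.5); one planted signal
family whose members descend from two ancestors at p-distance 0.15, each
strain drawing the ancestor matching its phenotype group except for a 10%
allele/phenotype disagreement rate (mimicking silent strains observed inside
active sequence clusters); and two marker families present in exactly
⌈0.9·n_active⌉ active and ⌊0.3·n_silent⌋ silent strains. Every family uses
its own RNG stream spawned from the master seed, so enlarging the pangenome
never perturbs existing families.

What it does **not** emulate: indels (all families are emitted pre-aligned),
selection, recombination, shared phylogeny between families (alleles are
generated conditionally on the phenotype group, not down a tree), assembly
or annotation artifacts, and paralogy. Passing recovery tests therefore show
the statistic and the screening machinery behave as designed when the
model's assumption — a phenotype-aligned allele split — literally holds;
they do not certify performance on real pangenomes, where phenotype-linked
variation is confounded with phylogenetic structure.

## Problem sizes used in the test and acceptance runs

The bundled checks run the screen on 200-family, 30-strain pangenomes of
length-300 proteins (20 seeds for the recovery rate), 1,000-case random
ensembles for the algebraic identities and invariances, and 100-case
ensembles for the CH-oracle and MDS-recovery comparisons. These sizes give
sub-minute wall time while keeping every estimate comfortably away from its
pass boundary.

## Known limitations

- The row embedding makes CH depend on family size N (each strain is an
  N-vector); comparisons of PG indices across OGs with very different
  membership should be interpreted with care — the screen only *ranks*.
- p-distance saturates for highly diverged alleles and ignores substitution
  heterogeneity; model-based distances are out of scope.
- The pairwise aligner is O(L²) per pair and intended for the fallback case,
  not for large unaligned families; supply an MSA for those.
- The marker screen uses raw presence fractions with no uncertainty: near
  the 0.8/0.5 boundaries single strains flip the call.
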