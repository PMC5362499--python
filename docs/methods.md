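# Methods

## Model and procedure

`lncsubpath` treats a pathway as an undirected simple gene graph G = (V, E)
and asks which connected region of G is most dysregulated between two sample
groups *jointly* at three levels: the genes themselves, the gene–gene
interactions, and the risk lncRNAs associated with the genes.

**Risk lncRNAs.** Expression is non-negative abundance (FPKM-like). All
differential statistics work on log2(x + pseudocount); fold changes are
ratios of linear-scale group means with the same pseudocount. A lncRNA is a
risk lncRNA when its BH-adjusted t-test P < `fdr_cut` and its fold change is
strictly > `fc_hi` or strictly < `fc_lo`. The t-test on logged values is the
single built-in test for every input type; count-model alternatives for raw
RNA-seq counts are deliberately out of scope. Thresholds are strict
inequalities, so a fold change of exactly 1.5 does not qualify.

**Node weights.** For pathway gene v with associated risk lncRNAs L1…Lm:

    w_v = α·|log2FC_v| + (1−α)·Σ_j d_vLj·|log2FC_Lj|
    d_vLj = 1 + |r_case(v,Lj) − r_control(v,Lj)|   ∈ [1, 3]

Correlations are Pearson, per group, on the logged scale. α (default 0.5)
balances the gene's own dysregulation against the lncRNA layer; α = 1 makes
the lncRNA layer provably inert. Prizes are normalised within one pathway as
b_v = β·(w_v − w_min)/w_max with β = 15. Dividing by the maximum rather than
the range is intentional — it is the normalisation this method defines — but
because the alternative reading is plausible, `range_normalize=True` divides
by (w_max − w_min) instead. If all raw weights are equal (including all
zero), every prize is 0.

**Edge weights.** w_e = 1 − |r_case − r_control|, so an *unchanged*
interaction has maximal weight; costs c_e = (w_e − w_emin)/w_emax (same
normalisation convention and switch). A pathway gene missing from the
expression matrix keeps its node with w_v = 0 and neutral (w_e = 1) incident
edges, preserving topology. A group with fewer than 3 samples yields
correlation 0 with a warning.

**Region search (PCST).** The region is the connected subgraph minimising
Σ_{e∈E'} c_e − Σ_{v∈V'} b_v. Components of at most `exact_threshold` nodes
(default 4) are solved by exhaustive enumeration of connected induced node
subsets, each scored by its minimum spanning tree under c_e. Larger
components use a deterministic heuristic: (a) strong pruning (bottom-up
optimal-subtree dynamic programming) of the component MST from every root,
and (b) greedy growth from the highest-prize seeds with one- and two-step
lookahead followed by MST + strong pruning; the better candidate wins. The
heuristic matches the exhaustive oracle on all 200 seeded random instances
(6–15 nodes, prizes U[0,15], costs U[0,1]) in the test suite. Ties break by
(objective, fewer nodes, lexicographic ids) so results are reproducible. Only
tree edges enter the objective; significance scoring uses the region's full
induced edge set. A pathway with no strictly profitable region yields "no
region". Multiple node-disjoint regions per pathway are produced by
iteratively re-solving after removing found regions (`max_regions`).

**Significance.** Observed scores are means of *raw* quantities over the
region: S_node = mean w_v, S_edge = mean (1 − w_e) = mean |Δcorrelation|.
Scoring edges by differentiality rather than by raw edge weight makes
"larger = more dysregulated" hold at both levels, so a single right tail is
correct; this deliberately deviates from scoring edges by w_e itself, whose
right tail would reward *unchanged* regions. Null scores are means of
size-matched draws without replacement from background pools: for nodes, the
raw weights of every expressed PCG associated with at least one risk lncRNA;
for edges, the differentialities of all edges of all pathways in the run
(hence a run is defined over a pathway collection). P = #(S_rand ≥ S_obs)/R
with R = 1000 by default; the ≥ tail is the default and `strict_tail`
restores the strictly-greater count. P has resolution exactly 1/R and a
reported 0 means "< 1/R"; `add_one` computes (count+1)/(R+1) for users who
need nonzero P. If the pool is smaller than the region, sampling is with
replacement (warned). The joint P is the product p_node·p_edge — note the
product of two uniforms is *not* uniform (CDF t·(1 − ln t)), so the joint is
anticonservative in isolation; in practice the risk-lncRNA gate (below)
controls the false-positive rate. Joint P values are BH-adjusted across all
tested regions (Bonferroni optional) and the final report keeps regions with
at least one associated risk lncRNA, sorted by adjusted then joint P.
Permutation streams are seeded per (seed, pathway, region, level), so a
pathway's node-level P does not depend on which other pathways are in the
run, while edge-level P legitimately does (global edge pool).

**Key lncRNAs.** Region-associated lncRNAs are ranked by
IS = γ·|log2FC_L| + (1−γ)·Σ_j d_LGj·D_Gj, where D_Gj is the degree of gene
Gj inside the region's induced subgraph and γ = 0.3; ties break by larger
|log2FC|, then id. The core set seeds with the top-IS lncRNA and walks down
the ranking, admitting a candidate only when it strictly increases the
fraction q of region genes covered by the core set (union coverage), and
stops once q ≥ pert (default 0.8). Rejected candidates are discarded
permanently (single pass, as the selection rule reads). A missing
lncRNA–gene correlation contributes d = 1 (no shift).

## Association network construction

Two evidence layers, merged by set union on (lncRNA, PCG) with provenance
'both' for duplicates (co-expression sign retained):

* **Co-expression**, per dataset: features need coefficient of variation
  ≥ 0.3 *and* a CV in the top 75% of all features (ties kept; zero-mean
  features dropped). All lncRNA×PCG Pearson correlations get Fisher-z
  two-sided P values (z = atanh r·√(n−3)), Bonferroni-corrected by the
  number of tested pairs in that dataset; retained pairs need adjusted
  P < 0.01 and a correlation in the global top or bottom `extreme_frac`
  (0.1%) of that dataset's pair correlations. The global percentile (rather
  than per-gene) reading matches "of all co-expression pairs". A pair enters
  the network when the same sign is retained in ≥ 3 datasets; support is
  that count (if both signs somehow reach support, the larger wins, ties
  drop the pair).
* **ceRNA**: for each lncRNA, candidate mRNAs sharing ≥ 1 miRNA are kept when
  the shared-miRNA hypergeometric upper tail P(X > m) < 0.05 and their
  Jaccard coefficient ranks in the top 20% of that lncRNA's candidates
  (count = ceil(0.2·n_candidates), so a single candidate always ranks). The
  strictly-greater tail is the printed form of this test; `inclusive=True`
  gives P(X ≥ m). Jaccard of two empty sets is 0 by convention.

Pre-built networks load directly from edge-list TSV — the practical default,
since assembling the co-expression layer needs many expression datasets.

## Pathway graphs

KGML documents flatten to undirected simple graphs: every gene of one entry
connects to every gene of a related entry (direction and subtype dropped;
`maplink` relations skipped; group entries expand to their component gene
entries — a choice, since grouped-complex handling is generally
unspecified), and two enzyme entries connect when one reaction's product
compound is another's substrate. Documents yielding no gene–gene structure
raise a dedicated error so callers can exclude them; disease-pathway
exclusion is an id blocklist concern left to the caller, and no gene-id
mapping is bundled.

## Simulation engine

Each dataset: 150 PCGs + 50 lncRNAs, two equal groups, multivariate normal
on log2 scale with baseline mean 5 and unit variance; expression is emitted
as 2^z. The first PCGs carry the bundled topologies (20-gene linear chain;
a 46-gene ERBB-signalling-style fixture — a documented synthetic stand-in
following the published KEGG ERBB structure, since the originally used node
list is not available; it is the single source of truth for all
simulations). Pathway edges and lncRNA–PCG associations carry baseline
correlation ρ0 = 0.6. lncRNAs attach to pathway genes by a seeded random
bipartite graph with mean degree 2. ρ0, variances, means and degree are
config keys; the values are fixed here as realistic defaults because the
original parameterisation is not published.

Planted signal: a **connected** region — grown as a random breadth-first
tree of ⌈p·|V|⌉ nodes of the chosen topology, or the explicitly supplied
region node sets — receives a case-group mean shift of log2(n) (also applied
to the lncRNAs associated with region nodes), and ⌈p·|E|⌉ edges drawn from
the region's induced edges (plus the altered lncRNAs' associations into the
region) have their case-group correlation lowered to ρ0 − e. Connected
planting matters: scattering altered nodes arbitrarily would make the
planted object not a subpathway at all. With p = 0 the two groups share mean
and covariance exactly. Indefinite matrices produced by the planted
structure are repaired by eigenvalue clipping at 1e-4 plus diagonal
renormalisation (one eigendecomposition; chosen over iterative
nearest-correlation refinement because the repair runs inside replicate
loops and the clipped matrix is within sampling noise of it).

Null presets: `choi` uses compound-symmetry blocks (ρ0) over each pathway's
genes; `goel` draws a random factor-model correlation block per pathway per
replicate. Both satisfy μ1 = μ2, Σ1 = Σ2 exactly.

Studies (all seeded, reproducible bitwise):

* **Sensitivity** — per (n, e, p, N) cell, the fraction of replicates whose
  identified region in the planted topology reaches joint P < 0.01 / 0.05.
* **FPR** — fraction of null replicates whose best reported region reaches
  joint P < alpha (0.01). Under the null the risk-lncRNA gate (FDR *and*
  1.5-fold change with ~125 samples per group) almost never opens, which is
  the method's actual false-positive control: the anticonservative joint P
  is rarely even computed.
* **Recall** — per planted region, mean over replicates of
  |identified nodes ∩ region|/|region|, with identified nodes the union of
  the pathway's reported regions (`max_regions=3` to cover the three ERBB
  regions).

What the generator does *not* emulate: count noise and library-size effects,
heavy-tailed abundance distributions, correlated background genes,
annotation errors in the association network, and overlapping pathway
membership. Passing simulations therefore validate the machinery and its
statistical calibration under the stated MVN model, not performance on real
RNA-seq data.

## Default problem sizes

Test-suite and acceptance-script studies run at desk scale chosen as the
package's own defaults: FPR 100 replicates × 4 conditions at 500
permutations; recall 20 replicates; sensitivity 3×3×3 grid × 30 replicates
at 200 permutations; PCST oracle comparison 200 instances of 6–15 nodes.

## Known limitations

* The t-test is used for all inputs including raw RNA-seq abundances.
* The PCST heuristic has no optimality guarantee beyond the tested regime.
* The joint P is anticonservative by construction (see above); interpret it
  through the BH-adjusted column and the permutation resolution 1/R.
* Signed (activating/repressing) lncRNA regulation and directed pathway
  semantics are not modelled.
* The prize scale β = 15 against costs ≤ 1 makes region growth permissive on
  small dense graphs; on the 20-node fixtures identified regions often
  extend beyond the planted stretch (recall-oriented rather than
  precision-oriented behaviour).
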