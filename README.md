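# lncsubpath

`lncsubpath` identifies **dysregulated subpathway regions associated with risk
lncRNAs**. Given matched lncRNA and mRNA expression matrices for two sample
groups (e.g. tumour vs normal), KEGG-style pathway topologies, and a global
lncRNA–protein-coding-gene (PCG) association network, it locates connected
pathway regions whose genes, gene–gene interactions and associated lncRNAs are
jointly dysregulated, scores each region by permutation, and names the key
lncRNAs that drive it. It is aimed at researchers who have a set of
disease-dysregulated lncRNAs and want pathway-level functional context for
them.

## Method

1. **Risk lncRNAs.** lncRNAs differentially expressed between the groups
   (two-sample t-test on log2(x + pseudocount), BH-adjusted P < 0.25, and
   linear fold change > 1.5 or < 2/3).
2. **Node and edge weights.** For each pathway gene *v* with associated risk
   lncRNAs *L1…Lm*:

       w_v = α·|log2FC_v| + (1−α)·Σ_j d_vLj·|log2FC_Lj|,   d = 1 + |r_case − r_control|

   normalised within the pathway to prizes b_v = β·(w_v − w_min)/w_max
   (α = 0.5, β = 15). Each edge gets w_e = 1 − |r_case − r_control|, cost
   c_e = (w_e − w_emin)/w_emax, so unchanged interactions are expensive and
   rewired ones cheap.
3. **Region search.** A prize-collecting Steiner tree (PCST) solver finds the
   connected subgraph minimising Σ c_e − Σ b_v (exhaustive enumeration on
   small components, a deterministic grow-and-prune heuristic on larger ones,
   verified against the exhaustive oracle).
4. **Significance.** Node- and edge-level permutation P values compare the
   region's mean raw weight/differentiality against background pools (all
   risk-lncRNA-associated PCGs; all edges of all pathways); the joint P is
   their product, BH-adjusted across regions.
5. **Key lncRNAs.** Region-associated lncRNAs are ranked by importance
   IS = γ·|log2FC_L| + (1−γ)·Σ_j d_LGj·D_Gj (γ = 0.3, D = region degree) and
   a minimal core set covering ≥ 80% of associated region genes is selected
   greedily.

A built-in simulation engine generates matched lncRNA/mRNA datasets with
planted node fold changes and edge correlation shifts over two bundled
topologies (a 20-gene linear chain and an ERBB-signalling-style fixture), and
drives three studies: sensitivity across a (n, e, p) grid, false-positive
rate on null data, and planted-region recall.

## Worked example

```python
import lncsubpath as L

pathways = list(L.fixture_pathways().values())          # linear + ERBB fixtures
scenario = L.SimulationScenario(topology="linear", n=4.0, e=0.5, p=0.5,
                                N=300, seed=11)
pair, network, truth = L.simulate_dataset(scenario, pathways)
results, log = L.run(pair, pathways, network,
                     L.RunConfig(permutations=500, seed=2))
best = results[0]
print(best.region_id, len(best.nodes), best.p_node, best.p_edge, best.p_adjusted)
print(best.key_lncrnas)
```

prints

```
linear_1 19 0.232 0.0 0.0
('lnc008', 'lnc043', 'lnc036', 'lnc050', 'lnc027', 'lnc041', 'lnc011', 'lnc028', 'lnc016', 'lnc047')
```

i.e. a 19-gene region containing the planted dysregulated stretch (g08–g17 in
this seed) is reported with edge-level permutation P below resolution
(< 1/500, shown as 0.0), adjusted joint P < 0.05, and a core lncRNA set that
covers ≥ 80% of the region's associated genes.

The same pipeline is exposed on the command line:

```
lncsubpath run --lnc lnc.tsv --pcg pcg.tsv --groups groups.tsv \
               --net network.tsv --pathways pathways.tsv --perms 1000 --seed 7
lncsubpath overlap --universe 214 --a 32 --b 18 --k 11   # -> 2.43778e-06
```

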