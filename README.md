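# asthmanet

Network analysis of paired stimulation transcriptomics for two clinical
groups — the kind of design where PBMCs from control and asthmatic
children are profiled before and after tetanus-toxoid stimulation, and
the question is not *which genes move* (they move identically in both
groups) but *how the regulatory wiring differs*. The package is aimed
at computational immunologists and systems biologists who want the full
chain — co-expression modules, message-passing regulatory networks,
per-TF regulatory-shift statistics, and an epigenomic binding-proximity
test — as tested, composable library code with a synthetic benchmark
generator that carries ground truth for every stage.

## What it computes

1. **Perturbed gene set.** Median-of-ratios normalization,
   log2(x/sf + 1), then a paired t-test on per-subject TT − NS
   differences per group with BH correction; the union of genes at
   q < 0.05 in either group enters the network analysis.
2. **Signed co-expression modules.** Adjacency
   a_ij = ((1 + cor(x_i, x_j))/2)^12, topological overlap
   TOM_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij), average-linkage
   tree cut (minimum module size 30, eigengene merge height 0.15).
   Module eigengenes (first principal components) are tested with mixed
   two-way ANOVA for stimulation and group × stimulation effects, and
   module connectivity is compared between groups via eigengene Pearson
   correlations with per-group FDR.
3. **Regulatory networks.** A motif prior (promoter hits at ≥ 80% of a
   PWM's min–max score range over [TSS − 1000, TSS + 200)), a TF–TF
   interaction prior, and per group × condition co-expression are fused
   by message passing (Tanimoto responsibility/availability updates,
   α = 0.1) into four TF × gene edge-weight networks on a z-score
   scale.
4. **Regulatory shift.** Per TF and module, the median of
   z_asthma − z_control over the TF's targets in the module; TFs
   cluster on these patterns by k-means with the cluster count chosen
   by maximum mean silhouette over k = 2..10.
5. **DMR binding proximity.** Per DMR, each bound TF's hit positions
   are smoothed with a 21-bp/5-sd Gaussian kernel into a sum-to-one
   profile; pairwise L1 distances, elimination of near-duplicate
   profiles (distance < 0.1), then the mean silhouette of TF community
   labels is compared against 10,000 label permutations,
   p = #(null > observed)/10,000.

The synthetic generator (`asthmanet.simulate`) produces
negative-binomial counts with latent-factor modules whose inter-module
correlation signs differ between groups, promoters and DMRs with
planted consensus motif occurrences, a community-structured TF–TF
prior, and constructed case/control networks with planted shift
patterns — every downstream stage has a ground-truth-bearing fixture.

## Worked example

The numbered scripts under `analysis/` run a desk-scale study (1,200
module genes + 2,400 background genes, 30 + 19 subjects, 20 TFs, ten
500-bp DMRs) end to end, staging data under `scratch/analysis/` and
writing summaries under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_coexpression_modules.py
...
python analysis/07_dmr_proximity.py
```

`03_coexpression_modules.py` prints, for the default seed:

```
               quantity     value
       modules_detected    4.0000
        genes_clustered 1182.0000
       genes_unassigned   47.0000
recovery_ari_vs_planted    0.9987
```

— the four planted modules are recovered essentially exactly (adjusted
Rand index 0.999), every module shows a significant stimulation effect
(p < 10⁻⁴) and none shows a group × stimulation interaction, matching
the planted design. `07_dmr_proximity.py` ends with

```
10 of 10 DMRs significant at p < 0.001 under the planted communities
```

— TFs from the same regulatory community bind in proximal zones, so the
observed silhouette exceeds all 10,000 permuted-label silhouettes in
every DMR. The same run also reports the fitted-network route, where
community recovery is weak at this sample size (see
`docs/methods.md`, Known limitations).

The whole pipeline is also available as a CLI with per-stage
subcommands and a manifest-writing `run-all`:

```bash
asthmanet run-all --outdir out --seed 7
asthmanet dmr-test --outdir out          # rerun one stage in place
```

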