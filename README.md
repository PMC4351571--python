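# clichunter

Detection of **3D hotspots of recurrent retroviral insertions** by
overlaying insertional-mutagenesis (IM) screen data with Hi-C chromatin
contact maps.

Retroviral IM screens mark candidate cancer genes as clusters of
insertions recurring across independent tumours.  Enhancers in the viral
LTRs can, however, act on genes far away on the linear genome through
chromatin looping, so insertions targeting one gene may be split across
several linearly distal but spatially proximal loci — diluting the signal
of classical common-insertion-site (CIS) analysis and misassigning target
genes.  `clichunter` finds pairs of insertion clusters (ICs) whose mutual
Hi-C contact significantly exceeds the contact expected at their genomic
distance: **co-localized insertion clusters (CLICs)**.

The pipeline, for bias-corrected intra-chromosomal contact maps H and an
insertion table (chrom, position, sample):

1. **Rank normalization** — every contact h_ij is replaced by its
   average-tie rank among contacts at a similar genomic distance (the k-th
   superdiagonal H^d, extended with neighbouring superdiagonals to a pool
   of at least L values), scaled into (0, 1].  No distributional
   assumptions; invariant under monotone transforms of the raw scores.
2. **Compartments** — PC1 of the correlation matrix of the normalized map
   splits bins into open/closed chromatin; insertion counts correlate with
   the open compartment.
3. **IC calling** — insertions are smoothed with a Gaussian kernel
   (2σ = 80 kb); ICs are density peaks with bin-aligned extents, split at
   the genome-wide median peak height into high- and low-scoring sets.
4. **CLIC detection** — for every intra-chromosomal pair of high-scoring
   ICs, the n×m bridging scores (positive distribution) are tested
   one-tailed against all scores at matching genomic distance (negative
   distribution, ≥ L values) with a Wilcoxon rank-sum test; Holm's
   step-down controls the family-wise error rate at level α.
5. **Downstream** — mutual exclusion of insertions between CLIC loci
   (mean-Manhattan distance), Fisher-exact enrichment of gene sets and
   TFBS carriers, and expression association scores T^A / T^AB with
   spatial association sign(T^A)(T^AB − T^A).

A synthetic-data module generates contact maps (power-law decay × plaid
compartments × log-normal noise), insertion cohorts (uniform background +
selected clusters, optionally with planted contact boosts and mutual
exclusivity) and expression matrices with planted trans effects, so the
whole pipeline is testable with known ground truth.

## Worked example

```python
from clichunter import (
    SimulationConfig, ClusterSpec, ClicPairSpec, RunConfig, run_pipeline,
)

sim = SimulationConfig(
    n_bins=400,                      # 16 Mb chromosome at 40 kb bins
    compartment_contrast=1.0,
    n_samples=100,
    background_rate=1.0,             # background insertions / sample
    cluster_specs=(
        ClusterSpec(center_bin=80, width_bp=160_000, expected_hits=30),
        ClusterSpec(center_bin=300, width_bp=160_000, expected_hits=30),
    ),
    planted_clic_pairs=(ClicPairSpec(0, 1, boost=5.0, exclusivity=0.5),),
    seed=123,
)
bundle = run_pipeline(RunConfig(simulation=sim, alpha=0.05, outdir="out"))
print(len(bundle["clusters"]), "ICs,",
      len(bundle["clics"]), "pairs tested,",
      len(bundle["significant_clics"]), "significant CLICs")
for c in bundle["significant_clics"][:3]:
    print(c.ic_a.start_bin, c.ic_a.end_bin, "<->",
          c.ic_b.start_bin, c.ic_b.end_bin, f"p_holm={c.p_holm:.2e}")
```

prints

```
51 ICs, 296 pairs tested, 1 significant CLICs
73 87 <-> 293 306 p_holm=7.03e-05
```

i.e. among 51 detected insertion clusters and 296 intra-chromosomal
high-IC pairs, exactly the planted pair (clusters around bins 80 and 300)
is reported as a CLIC, with a Holm-adjusted co-localization p-value of
7e-5.  `out/` receives the IC BED, CLIC TSV/BEDPE, compartment bedGraph
and a `manifest.json` from which the run is reproducible byte-for-byte.

The same pipeline is scriptable from the shell:

```bash
clichunter run-all --config sim.cfg --seed 123 --alpha 0.05 --out out/
clichunter normalize --matrix chr1.matrix --out chr1.normalized.txt
```

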