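# hicscape

Multi-scale analysis of Hi-C contact maps for developmental chromatin
studies — written for the kind of question posed by hematopoietic stem and
progenitor cell (HSPC) development, where chromatin architecture starts
out relaxed and is progressively consolidated: compartments sharpen, TAD
insulation deepens, and focal loops gain strength across stages.

The package covers every layer of that analysis as an importable library:

| layer | what it computes |
| --- | --- |
| global | contact-decay curves P(s) over 500 log-spaced distance bins, Jensen–Shannon divergence between curves, Von Neumann entropy of the contact-correlation spectrum, trans-contact fraction, GenomeDISCO-style reproducibility |
| compartments | A/B calls from PC1 of the O/E correlation matrix (oriented by gene density), strength AB/(AA+BB), 50-group saddle plots, switch categories (A2A/B2B/A2B/B2A) and their expression consequences |
| domains | insulation scores, boundary calls at delta-vector zero crossings, TADs, 75 % reciprocal-overlap sharing, top-k variable-boundary ranking with hierarchical clustering |
| loops | a simplified HiCCUPS-style caller (four local neighborhoods, Poisson tests, BH within distance strata), APA, ±1-bin loop sharing, cosine similarity of loop contact vectors, enhancer/promoter anchor classes |
| elements | active enhancers (H3K27ac peaks free of H3K4me3 overlap), promoter windows (TSS ± 3 kb), FPKM-thresholded active promoters |
| tf_anchors | TF-peak enrichment at anchors vs length-matched random regions, both/one/none anchor-occupancy gene classes, occupancy–expression statistics |

Everything is driven by a synthetic contact-map generator
(`hicscape.simulate`) that plants compartment checkerboards, TAD blocks
and focal loops on a power-law decay background with Poisson sampling —
so every analysis stage can be verified against known ground truth
without any sequencing data.

## The core quantities

For a binned, symmetric contact matrix *M* per chromosome:

- **Balancing.** Weights *w* such that *W M W* has equal row sums
  (Sinkhorn iteration to the Knight–Ruiz fixed point).
- **O/E.** Each balanced entry divided by the mean balanced contact at
  the same separation *s* on that chromosome; the per-diagonal mean of
  O/E is 1 by construction.
- **Von Neumann entropy.** *C* = Pearson correlation of log2(*M* + 1)
  columns; eigenvalues λᵢ of *C* are clipped at 0 and normalized,
  λᵢ ← λᵢ / Σλⱼ, and VNE = −Σ λᵢ ln λᵢ. Bounded by ln *n*; higher means
  a more disordered map.
- **Compartment strength.** mean O/E over A–B pairs divided by the sum
  of the A–A and B–B means; 0.5 for a structureless map, lower = stronger
  segregation.
- **Insulation.** log2 of the summed balanced contacts crossing each bin
  in a 500 kb square window, relative to the chromosome mean; boundaries
  are strength-filtered minima.
- **Loops.** Pixels enriched over donut / lower-left / horizontal /
  vertical neighborhood expectations, Poisson-tested and BH-corrected
  within distance strata.

## Worked example

```python
import numpy as np
import hicscape as hs

spec = hs.make_checkerboard_spec(n_bins=400, contrast=0.6, depth=1_000_000,
                                 noise_sigma=0.2)
cmap = hs.simulate_contact_map(spec, seed=7)
oe = hs.observed_over_expected(hs.kr_balance(cmap))
density = {"chr1": np.where(spec.compartment_labels["chr1"] == "A", 2.0, 0.5)}
profile = hs.call_compartments(oe, density)
print(np.mean(profile.label["chr1"] == spec.compartment_labels["chr1"]))
print(hs.compartment_strength(oe, profile, "chr1"))
```

prints

```
1.0
0.19396744793990164
```

— the planted A/B labels are recovered on every bin, and the strength
score 0.194 sits far below the structureless value 0.5, i.e. strong
compartmentalization. The `examples/` directory holds one narrative
script per capability (`python examples/02_compartments.py` reproduces
the numbers above with a saddle summary).

The end-to-end pipeline — three stages with a relaxed first stage,
planted compartment switches, depth equalization and every layer's
summary — runs from the shell:

```bash
hicscape run --seed 1 --outdir out/
```

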