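# schic3d

Whole-genome 3D structure reconstruction from **extremely sparse, binary
single-cell Hi-C** contact maps.

Single-cell Hi-C captures the chromatin contacts of one nucleus, but at
typical sequencing depth almost every bead pair is observed at most once:
after binning, the contact matrix is effectively 0/1 and covers well under
1% of bead pairs. Tools built for bulk Hi-C (which expect graded contact
frequencies) degrade or fail outright in this regime. `schic3d` embraces
it: the input is deliberately binarized, the zeros are *imputed* into
contact probabilities, and a whole-genome bead-chain model — all
chromosomes (and both haplotypes of a diploid genome) at once, so both
intra- and inter-chromosomal contacts shape the result — is optimized by
simulated annealing. Intended users are computational biologists studying
single-cell genome architecture (chromosome territories, radial
organization, cell-to-cell structural variability).

## Model

Each chromosome is a chain of beads (one bead per genomic bin) in a cubic
lattice box of volume $V = (5l)^3$, $l$ the genome-wide bead count. The
binary matrix is imputed into a **theta matrix** $\theta_{ij} \in [0,1]$ of
estimated contact probabilities, by either

- a **2D Gaussian kernel** in matrix-index space,
  $\theta_{ij} = \max_{(u,v)\,\text{observed}} \exp\!\big({-\tfrac{(i-u)^2+(j-v)^2}{2\sigma^2}}\big)$, or
- a **graph autoencoder** (GAE): a two-layer GCN encoder
  $Z = \hat{A}\,\mathrm{ReLU}(\hat{A} X W_0) W_1$ with
  $\hat{A} = D^{-1/2}(A{+}I)D^{-1/2}$ and inner-product decoder
  $\sigma(z_i^\top z_j)$, trained by cross-entropy on observed edges vs
  sampled non-edges.

The objective treats bead pairs in three regimes (distances $d_{ij}$ in
lattice units, target contact distance $d_t = 8$):

| regime | condition | term |
|---|---|---|
| 1 | $\theta_{ij} = 1$ | $w_1 \max(0, d_{ij} - d_t)^2$ |
| 2 | $0.7 \le \theta_{ij} < 1$ | $w_2\, \theta_{ij} \max(0, d_{ij} - d_t)^2$ |
| 3 | $\theta_{ij} < 0.7$ | $w_3 \max(0, d_t - d_{ij})^2$ |

plus shared excluded volume $w_1 \max(0, d_r - d_{ij})^2$ and a backbone
term on consecutive beads. Intra-chromosomal pair terms are weighted by
$C_\mathrm{ratio} = 1/(\lfloor \mathrm{count}_1/\mathrm{count}_2 \rfloor + 1)$
(count₁/count₂ = genome-wide intra/inter contact counts) and
inter-chromosomal terms by $1 - C_\mathrm{ratio}$, so the scarce
inter-chromosomal contacts are not drowned out.

Optimization is Metropolis–Hastings simulated annealing
($T_c = T_0 \cdot \alpha^c$, $T_0 = 10$; per-temperature equilibrium at 10
accepted moves per bead or 100 attempts per bead), run **coarse-to-fine**:
anneal at a low resolution, scale coordinates by
$0.12 \times (\text{low}/\text{high})$, interpolate
$\text{low}/\text{high} - 1$ equidistant beads per segment, then refine at
the high resolution from that start.

## Worked example

No downloads needed — the package ships a generator of synthetic cells
with known ground truth. Reconstruct one and compare against the truth
(`examples/03_build_structure.py`):

```python
import schic3d as sc

spec = sc.reference_spec(seed=0)                    # 3 chromosomes x 200 beads, 1 Mbp
truth = sc.simulate_genome_structure(spec)
contacts = sc.simulate_sc_contacts(truth, spec)     # ~1% binary pair density

config = sc.MultiscaleConfig(low_resolution=10_000_000, high_resolution=1_000_000)
result = sc.two_step_build(contacts, spec.chromosomes, config, seed=1)
```

Output:

```
stage 1 (10 Mbp, 60 beads): 88 cooling steps, final loss 4.9
stage 2 (1 Mbp, 600 beads): initial loss 4612.5 -> final loss 304.9
distance-matrix Pearson vs truth: intra = 0.619, inter = 0.425
```

The intra-chromosomal Pearson of 0.62 says the reconstruction recovers
each chromosome's internal geometry (up to rigid motion and global scale)
from contacts covering only ~1% of bead pairs. Evaluating the fit to the
input contacts (`examples/04_evaluate_structure.py`):

```
contact vs non-contact distances (lattice units):
  contact mean    = 6.51
  non-contact mean = 26.99
  rank-sum p       = 0  (contact pairs significantly closer)
P(s) log-log slope = -1.35 (references: -1 fractal globule, -1.5 ideal chain)
reproducibility over 3 seeds: mean pairwise Pearson = 0.663 (sd 0.048)
```

Bead pairs with a contact sit ~4x closer than pairs without, the
contact-probability decay lies between the fractal-globule and ideal-chain
exponents, and independent seeds give consistent geometries — the three
standard structure-assessment checks. The other examples cover simulation
(`01`), both imputers with held-out link-prediction scores (`02`), and a
thin CLI mirrors the same pipeline:

```bash
schic3d simulate --chroms 3x200 --density 0.01 --seed 0 --out-prefix cell
schic3d build cell.pairs genome.sizes --low-res 10000000 --high-res 1000000 --out cell.tsv
schic3d evaluate --structure cell.tsv --contacts cell.pairs --report report/
```

Real data go in as whitespace-delimited `chrA posA chrB posB [count]`
pairs (haplotype tags `chr1(mat)` / `chr1_pat` supported) or NCC-format
records, plus a UCSC-style chrom.sizes file.

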