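# Methods

## Energy model

Segmentation is posed as minimization of

E(L) = λ · Σ_p R_p(l_p) + Σ_{(p,q)∈N} A(p,q) · δ(l_p, l_q),

over binary labelings L of the pixel grid. The regional term R_p is the
negative log-likelihood of the pixel's gray value under histogram models
Pr(I|O), Pr(I|B) estimated from marked object/background pixels; the
boundary term A(p,q) = exp(−(I_p−I_q)²/2σ²)/dist(p,q) penalizes label
discontinuities between similar, nearby pixels. λ multiplies the regional
term only, exactly as the energy is written above; the boundary term
carries no complementary weight.

The energy is represented as an s–t network: pixel p gets a t-link to the
source of capacity λ·R_p("bkg") and to the sink of capacity λ·R_p("obj")
(the cut severs the edge to the terminal the pixel is *not* assigned to),
and each neighbour pair an n-link of capacity A(p,q). Marked pixels are
clamped with a finite capacity K = 1 + max_p Σ incident n-link capacity,
which no cut through n-links alone can outweigh; finiteness keeps the
cut-capacity = energy identity exact and testable for *every* labeling,
not just feasible ones. With this construction the minimum s–t cut is the
minimum of E subject to the marks, and the package asserts the identity
both by exhaustive enumeration on small grids and on the solver's output.

### Assumptions

- Two classes only (bone vs everything else), one 2-D slice at a time.
- Gray values are 8-bit; clinical HU slices are first windowed (bone
  window, center 300 HU / width 1500 HU by default) onto 0–255.
- Intensity likelihoods are stationary over the image (one global
  histogram per class, no spatial mixture).

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| λ (`lam`) | 1.0 | — | balanced regional/boundary trade-off; 0 reduces to a pure boundary problem |
| σ (`sigma`) | `"auto"` | gray levels | RMS neighbour gray difference, floored at 1: contrasts at the image's own noise scale are cheap to cut through, true edges are not |
| connectivity | 8 | — | the 1/dist factor of A(p,q) is only non-trivial for diagonal neighbours (dist √2), so the model is built for 8-connectivity; 4 is selectable |
| histogram bins | 64 | — | 4-gray-level resolution; enough to separate the three tissue modes without starving sparse seed histograms |
| smoothing ε | 1e−6 | probability | floors each bin before renormalizing so −ln stays finite; after renormalization probabilities can sit a factor (1+kε)⁻¹ below ε, which the model type tolerates |
| trimap margin | 10 | gray levels | half-width of the to-be-segmented band around the threshold |
| hard-seed weight K | auto | capacity | 1 + max incident n-link sum (see above) |
| max refinement passes | 10 | — | fixed-point termination is the automatable reading of "iterate until no segmentation error"; 10 bounds the loop (non-convergence is reported on the run record, not raised) |

## Marker generation

*Threshold trimap.* The Otsu threshold (exhaustive scan of all 256
levels, maximizing between-class variance, ties resolved to the lowest
level) splits the histogram; pixels ≥ t+margin become hard OBJECT marks,
≤ t−margin hard BACKGROUND, and the band between is left to the cut.

*Morphological marks.* The thresholded mask is opened with a horizontal
1×3 structuring element (erosion then dilation, border treated as
background), which deletes isolated bright noise and structures thinner
than three pixels; the opened mask is the OBJECT marks. BACKGROUND marks
are the complement of the opened mask's 3×3 dilation. Taking the
background relative to the *opened* mask is deliberate: bright speckle
that the opening removed is genuine background, and routing it into the
background marks both feeds the background model the noise tail and keeps
the undecided region small — this is precisely the noise robustness the
opening buys. (Dilating the raw threshold mask instead lets speckle carve
away most of the background marks at high noise; measured on the default
suite at noise sd 30, that construction drops the morphology variant's
mean Dice from ≈0.95 to ≈0.80.) Closing (dilation then erosion) is
implemented and exposed but unused by the default pipeline.

*Corrections.* Stroke files reassign pixels to OBJECT/BACKGROUND; later
strokes win, and corrected marks are hard constraints in every pass.

## Refinement loop

The morphology variant iterates: estimate likelihoods from the current
labeling (all pixels, by label), rebuild the graph with the original
marks still clamped, re-solve, stop at a labeling fixed point or after
`max_iter` passes. Because the empirical histogram of a labeling is the
likelihood maximizer for that labeling and each cut is optimal for its
model, the energy trace is non-increasing; the suite asserts this within
1e−9 (the ε-floor perturbs exact optimality of the histogram step by
O(ε) at most). Re-estimation can be disabled (`--no-reestimate`) to
reproduce the single-pass behaviour.

## Min-cut solver

Small graphs (≤ 2048 pixels) are solved by networkx preflow-push in exact
float arithmetic. Larger grids go through scipy's C max-flow, which
requires integer capacities and wraps above 2³¹; capacities are therefore
scaled by the largest integer factor that keeps the flow bound below 2³¹
(≈1e4–1e5 for a 128×128 slice, i.e. quantization ≈1e−5 per edge) and the
partition is read off the residual network. In both paths the reported
flow value is the exact float cut capacity of the returned partition, so
the cut/energy identity holds exactly regardless of quantization; the
quantized path can in principle return a partition whose capacity exceeds
the true minimum by the accumulated rounding (≈1e−2 on a full slice,
negligible against energies of order 10³). Solver exactness is verified
against brute-force enumeration of all 2ⁿ labelings on grids up to 3×4,
with ties in the oracle broken toward the row-major-smallest labeling,
and the two solver paths are cross-checked against each other on 6×6
grids.

## Phantom generator

Each phantom is two condyle-like ellipses — bright cortical rim
(3 px, gray 220) around a darker trabecular interior (gray 140) — on a
soft-tissue background (gray 60), emulating a bone-windowed axial knee
slice on a 128×128 field: centers (62,40)/(66,88), semi-axes
(24,18)/(22,16), jittered ±3 px (centers) and ±2 px (axes) per suite
phantom. The ground truth (union of the full ellipses, bone = cortical +
trabecular) is rasterized before corruption, so blur and noise never move
the gold standard. Corruption is Gaussian blur (σ = 0.5 px, a sub-pixel
partial-volume surrogate appropriate to sharp bone reconstruction
kernels; the sub-pixel choice also keeps the uncorrupted phantom an
exact-recovery fixture — a stronger blur biases the hard threshold marks
about half a pixel outside the true boundary) followed by seeded additive
Gaussian noise, clamped to [0,255]. The default benchmark suite is 20
phantoms per noise sd ∈ {10, 20, 30}, seeds 0–59.

What the phantom does *not* emulate: anatomical shape variety, adjacent
bones in near-contact, marrow inhomogeneity, beam-hardening and streak
artifacts, and correlated (reconstruction-kernel) noise. Passing the
phantom bench therefore demonstrates correctness of the energy model,
solver and marker pipelines under controlled corruption — not clinical
accuracy. One consequence is visible in the bench itself: with only 5+5
seeds the manual variant is nearly boundary-driven (most histogram bins
tie) and convex high-contrast blobs reward that, so sparse-seed manual
scores higher here than its known behaviour on real CT, where sparse
seeding under-models the tissue mixture.

## Numerical choices and degenerate inputs

- Windowing and phantom rasterization round half-up, then clamp — fixed
  so tests can pin exact gray values.
- Otsu on a constant image, trimaps that empty a class, markers with a
  missing class, and opening that erases every object mark raise
  explicit errors naming the problem.
- Both-empty Dice is defined as 1.0 (the 0/0 case; two empty
  segmentations agree perfectly).
- Brute-force cut enumeration breaks exact-value ties toward the
  row-major-smallest labeling; the production solver's tie behaviour is
  unspecified and only its flow value is asserted.
- Benchmark problem sizes (128×128 phantoms, 60-slice suite, 200 oracle
  instances) were chosen so the whole bench re-runs from scratch in
  seconds on one CPU.

## Known limitations

- Single-slice, single-object-class segmentation; no 3-D graph.
- Histogram likelihoods only; no learned or spatially varying models.
- The quantized solver path is exact-in-practice but not provably exact;
  the exact float path is used wherever enumeration can check it.
- Runtimes are logged in benchmark output for context and are never
  asserted — they are hardware-bound.
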