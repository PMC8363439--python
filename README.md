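# bonegraphcut

Graph-cut segmentation of bone tissue in single CT slices, with automatic
marker generation and a synthetic knee-CT phantom bench.

Segmenting bone from soft tissue in knee CT is a routine need in
osteoarthritis imaging, but interactively seeded graph cuts demand many
manually placed foreground/background marks and degrade when the operator
is sparing with them. This package implements the seeded graph-cut energy
model together with two automatic front-ends that replace manual seeding —
a global-threshold trimap and morphological-opening marks — and evaluates
all three on synthetic phantoms with exact ground truth, so every stage of
the method is verifiable without patient data.

## The model

A binary labeling `L` of the pixels (`l_p = 1` foreground/bone, `0`
background) is scored by the energy

```
E(L) = λ · Σ_p R_p(l_p)  +  Σ_{(p,q)∈N} A(p,q) · δ(l_p, l_q)
```

with `δ = 1` where neighbouring labels disagree and `0` otherwise. The
regional term is the negative log-likelihood of the pixel's gray value
under histogram models of the marked object and background pixels,

```
R_p("obj") = −ln Pr(I_p | O),    R_p("bkg") = −ln Pr(I_p | B),
```

and the boundary penalty combines gray contrast with pixel distance,

```
A(p,q) = exp(−(I_p − I_q)² / 2σ²) · 1 / dist(p, q).
```

The energy is encoded as an s–t network — t-links carry regional costs,
n-links the boundary penalties, marked pixels are clamped by a large
finite capacity — and minimized exactly by max-flow/min-cut. The
morphological variant then iterates: likelihoods are re-estimated from the
current labeling (marks stay hard), the cut re-solved, until a fixed
point. Results are scored with the Dice similarity coefficient
`Dice(M, N) = 2|M∩N| / (|M| + |N|)` against ground truth.

## Worked example

Generate a noisy 128×128 phantom (two condyle-like bone ellipses, noise
sd 20) and segment it with the morphological-marker variant:

```
$ bonegraphcut phantom --out-dir demo --noise-sd 20 --seed 7
wrote 1 phantom(s) to demo
$ bonegraphcut segment --method morphology --image demo/phantom_0007.png --out demo/mask.png
iteration=1 energy=1991.657510 changed_pixels=16384
iteration=2 energy=1922.917120 changed_pixels=0
wrote demo/mask.png (foreground pixels: 2383)
```

The two log lines are the refinement trace: the first cut has energy
1991.66; re-estimating the intensity models from that labeling lowers the
energy to 1922.92 and changes no pixel, so the loop stops at its fixed
point. Scoring against the exact truth mask:

```python
>>> from bonegraphcut import dice
>>> from bonegraphcut.imageio import load_mask
>>> dice(load_mask("demo/truth_0007.png"), load_mask("demo/mask.png"))
0.9753367875647668
```

i.e. 97.5% Dice overlap with the gold standard at this noise level. The
same comparison over a whole suite (`bonegraphcut benchmark`) writes
per-run and summary CSVs for the three variants.

Library use mirrors the CLI: `generate_phantom` / `generate_suite` build
inputs, `segment_manual` / `segment_threshold_gc` / `segment_morphology_gc`
return a `SegmentationRun` (labeling, energy trace, markers), and
`run_benchmark` tabulates Dice per variant.

DICOM input is supported end to end: `load_dicom_slice` applies the
modality rescale to Hounsfield units and `window_to_bitmap` maps a bone
window (default center 300 HU, width 1500 HU) onto the 8-bit gray range
the algorithm operates on.

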