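# Methods

## The measurement

Array tomography turns a block of brain tissue into a ribbon of 70 nm
serial sections, each immunostained and imaged per channel, and reassembles
them into a voxel volume whose axial resolution (the section thickness)
beats the diffraction limit. A synaptic compartment — a presynaptic bouton
labelled by synaptophysin or GFP, a postsynaptic density labelled by PSD95,
tau labelled by Tau13 — appears as a punctum: a small bright blob spanning a
few consecutive sections.

The pipeline measures four families of quantities per mouse:

1. **Densities** (puncta/μm³) of total presynapses and of GFP-positive
   presynapses, over a cropped region of interest.
2. **% GFP-positive presynapses** = 100 × GFP-positive presynapse count /
   total presynapse count, pooled over a mouse's crops by summed counts.
3. **% postsynapses tau-positive**: a postsynaptic punctum is tau-positive
   when ≥ 50% of its voxels fall inside the tau-channel foreground. Pooled
   per mouse by summed counts (sum of positives / sum of totals), never by
   averaging crop percentages — with unequal crop sizes the two rules
   genuinely differ.
4. **% synaptic pairs tau-positive in both compartments**: a putative pair
   is a GFP-positive presynapse and a postsynapse with centroid distance
   ≤ 0.5 μm (Euclidean, in physical units, z anisotropic), matched
   one-to-one greedily by ascending distance; the pair is tau-positive iff
   both members pass the 50% rule against the tau mask.

### Stage by stage

**Registration.** Sections land on the coverslip with small random offsets,
so the stack must be aligned before 3D objects can be formed. We estimate
the integer-pixel translation between each adjacent pair of sections on one
reference channel (default: total presynapse, the densest signal) by
exhaustively scoring all integer shifts within a search radius (default
±10 px), compose the adjacent shifts cumulatively back to section 0, and
apply the same correction to every channel — all channels are imaged on the
same physical section, so they share its displacement. The score is the
mean-subtracted per-pixel cross-covariance over the overlap region
(zero-fill outside the frame). Three properties drove that choice over the
plain dot product or normalized cross-correlation (NCC): mean subtraction
removes the bias a nonzero background offset gives to small shifts;
dividing by the overlap size removes the bias a stationary background gives
to small shifts; and leaving out variance normalization means a candidate
shift must match the true shift's shared signal *energy* — under NCC a
fluke alignment of two unrelated bright puncta inside a low-variance
overlap can outscore the genuine alignment on a content-poor interface,
which we observed as rare catastrophic multi-pixel errors. Ties prefer the
smaller displacement, then lexicographic order, so results are
deterministic. Rotation and subpixel motion are out of scope: ribbon jitter
is translational to good approximation and integer translation keeps every
downstream step exactly reproducible.

**Segmentation.** Staining intensity varies section to section along a
physical ribbon, so thresholds are computed per section, on raw intensities,
with every applied threshold recorded for audit. The default "combined"
method takes the union of the Otsu foreground (tuned to the bright class)
and the triangle-algorithm foreground (which admits the dim tail). Otsu
alone places its threshold between the bright puncta and everything else,
losing dim puncta entirely; the triangle method thresholds at the foot of
the background peak and keeps them. A constant section yields a recorded
no-threshold sentinel and contributes empty foreground. The Otsu value is
reported at the midpoint between the optimal histogram bin and the next
occupied intensity, so it lies strictly between the classes it separates;
the partition is the conventional one.

**3D reconstruction and the single-section filter.** Foreground voxels are
grouped into maximal 26-connected components (8-connectivity in plane plus
inter-section diagonals — the permissive choice that keeps a punctum
continuing across sections as one object despite residual 1 px
misalignment). Any object present in only one section is removed: real
synaptic structures at these length scales must span at least two 70 nm
sections, while staining precipitates and camera artifacts do not. This is
deliberately the *only* size/noise rule — no minimum in-plane area filter.
Border-touching objects are retained by default (`exclude_border`
available). Centroids are unweighted voxel means, converted to μm in the
parent coordinate frame (voxel centres at `(index + 0.5) × spacing` plus
the crop origin); crops are half-open `[origin, origin + size)` rectangles
rounded to whole voxels.

**Colocalization and pairing.** The overlap fraction is always of the
*target* punctum's volume (which postsynapses contain tau is a question
about postsynapses), threshold inclusive (≥ 0.5). Pair matching is
one-to-one greedy by distance with deterministic tie-breaks; an
all-candidates mode exists for sensitivity analysis. The 0.5 μm boundary is
inclusive, implemented with a 10⁻⁹ relative tolerance so geometrically
exact boundary cases (a 0.3/0.4/0.5 right triangle) classify correctly
despite binary floating point.

**Group statistics.** The experimental unit is the mouse. Densities
aggregate as the mean over crops, percentages as the ratio of summed
counts. Comparisons follow the field's reporting conventions: two-way
genotype × age ANOVA for the (normally distributed) density family,
reported mean ± SEM; Kruskal–Wallis across age groups for the
colocalization percentages, reported median and IQR. Both tests are
implemented from their defining formulas. The ANOVA uses Type-II sums of
squares computed from nested least-squares fits (each main effect is the
residual-sum-of-squares reduction over the model containing the other main
effect; the interaction is the further reduction over both mains), which
coincides with the classical balanced decomposition and handles the
unbalanced group sizes (3–6 mice). Kruskal–Wallis is
H = 12/(N(N+1)) Σ R²ᵢ/nᵢ − 3(N+1) with the standard tie correction and a
χ²(k−1) p-value; all-identical data give H = 0, p = 1 by convention. A
Shapiro–Wilk gate at α = 0.05 selects the branch automatically, and the
pipeline pins the branch per statistic (ANOVA for densities and %GFP,
Kruskal–Wallis for tau percentages) so runs mirror the conventional
choices exactly; the gate's verdict is logged either way and the override
is configurable. On the default cohort the gate itself reproduces that
split (densities p ≈ 0.4, tau percentages p < 10⁻³ — the control zeros
make them strongly non-normal).

## The synthetic scene generator

Real mouse images are not available at desk scale, so validation rests on
generated scenes with known ground truth. The generator's defaults are the
study conditions:

| parameter | default | meaning |
|---|---|---|
| footprint, sections | 10 × 10 μm, 30 × 70 nm | the crop geometry of the original analysis |
| pixel size | 0.1 μm/px | 63×/1.4 NA epifluorescence scale (configurable — never hard-coded) |
| density per channel | 0.6 /μm³ (pre and post) | neuropil-realistic synapse density; absolute densities are not printed in the source study, so this is a testability choice |
| punctum radius | mean 0.25, sd 0.05 μm in-plane | diffraction-blurred synaptic blob |
| section span | 2–5 sections | ≥ 2 by construction, so the persistence filter never removes a true synapse |
| amplitude classes | dim 25–40, bright 150–220 (30% dim) | exercises the combined-threshold requirement |
| % GFP+ presynapses | 30 (cohort: 35 transgenic / 25 control) | planted genotype effect |
| % postsynapses tau+ | 10 (cohort: 10/8/9 by age in transgenics, 0 in controls) | the planted spread of tau |
| tau+ among GFP+ presynapses | 50% | tau travels in the axons of the tau-expressing (GFP-labelled) neurons; controls 0 |
| pair offset | mean 0.25, sd 0.05 μm | keeps planted pairs inside the 0.5 μm detection radius |
| jitter | ≤ 3 px per section | ribbon misalignment; section 0 is the anchor |
| speckles | 3 per section per channel | single-section noise objects — the filter's target class |
| background | Gaussian field, sd 2, correlation 2.5 px | see below |
| texture | off by default (sd 0, correlation 2 px) | stationary tissue fluorescence, identical across a channel's sections |

Puncta are rendered as radially shaded ellipsoids (rim intensity 70% of
peak — fluorescent blobs are bright-centred, and the falloff gives
registration a strict correlation optimum instead of a plateau when one
section's disc contains the next one's), truncated across their section
span, with GFP and tau rendered congruently inside flagged objects. Each
GFP-positive presynapse receives a paired postsynapse at an isotropic
random offset, subject to a volume-exclusion cap: at most 25% mutual
ellipsoid overlap, because the presynaptic terminal and the postsynaptic
density are adjacent, non-interpenetrating compartments. Without that cap,
tau in a presynapse covers enough of its paired postsynapse to trip the 50%
rule through mere apposition, inflating the measured %post-tau by ~2.5
percentage points over the planted fraction. Same-channel objects keep a
placement clearance (0.3 μm plus one section) so distinct planted puncta
cannot fuse through the threshold skirt. A single seed expands into
independent substreams per purpose (placement per channel, jitter,
speckles, noise, texture), so adding one noise source never perturbs the
others, and identical configs are bit-identical.

**The background model is spatially correlated by design.** With iid
per-pixel noise, the voxels that survive thresholding chain across sections
often enough (probability ∝ coverage² × volume) to create hundreds of
two-section objects that the single-section filter cannot remove — no
threshold on a continuous noise distribution avoids this, because the
suprathreshold fraction is scale-invariant. Real fluorescence background is
smooth (out-of-focus light seen through the PSF), so suprathreshold
background forms in-plane patches confined to one section — exactly the
noise class the filter exists to remove. The generator therefore smooths
its Gaussian field over ~2.5 px; the published pipeline's reliance on the
single-section rule as its only noise filter implicitly asserts the same
property of the real images.

**What the generator does not emulate:** optics (no PSF convolution,
chromatic shift, or depth-dependent blur), immunostaining variability
(section-to-section intensity drift, edge artifacts), tissue context
(dendrites, axon fascicles, nuclei), punctum shape irregularity, or any
spatial clustering of synapses beyond pair structure. Passing tests
therefore show the *measurement chain* is correct and calibrated under the
assumed statistical structure; they do not show robustness to staining
pathology or optical artifacts in real ribbons.

## Numerical choices and edge cases

- Constant images: registration raises ("no registration signal");
  thresholding records a sentinel and yields empty foreground; the
  normality test refuses (zero variance).
- Empty denominators are *missing*, never zero: %GFP of an empty presynapse
  collection, %tau of zero postsynapses, %pairs of zero pairs, a mouse
  whose crop denominators sum to zero.
- Component ordering is deterministic (lexicographic by minimum voxel), as
  are pair matching (distance, then ids) and shift tie-breaks (smaller
  displacement first) — byte-identical reruns are a tested contract.
- ANOVA guards: every design cell must be occupied; at least one residual
  degree of freedom; tiny negative round-off in Type-II SS is clamped to 0.
- The scene placement sampler retries under its exclusion rules and fails
  loudly, naming the channel, when a requested density cannot be placed; a
  presynapse whose pairing neighbourhood is fully occupied goes unpaired
  rather than failing the scene.

## Validation design and problem sizes

The suite validates each stage against an independent oracle: exhaustive
between-class-variance search for Otsu; explicit flood fill for 3D
labelling; brute-force O(n²) matching for pairing; materialized-translation
Pearson correlation for registration; hand-computed rank sums and
statsmodels/scipy cross-checks for the statistics. End-to-end checks
recover planted quantities: registration recovers 100/100 noise-free
jittered series exactly (those scenes enable the stationary texture,
sd 40 — content-poor ribbon-end sections otherwise make exact recovery
information-theoretically unreliable); the full pipeline recovers a planted
10% postsynaptic tau fraction within its 95% binomial CI over ≥ 500
postsynapses pooled across 5 scenes; object-level detection F1 against
ground truth exceeds 0.95 on default scenes (typically ~0.98); type-I error
of both omnibus tests at the study's group sizes lies in [0.035, 0.065]
over 2,000 null simulations. The unbiasedness check runs over 10 default
scenes: tau-fraction estimates are unbiased within 2 SE; the density
estimate sits ~2% low because noise patches and speckles occasionally
bridge two true puncta into one 26-connected object (clean scenes count
exactly) — an inherent property of connected-component counting under
noise, kept within a 3% bound rather than asserted to be zero.

## Known limitations

- Translation-only, integer-pixel registration; rotation or warping in a
  real ribbon would require a different aligner.
- The combined-threshold pair {Otsu, triangle} is a documented stand-in for
  the original unnamed multi-algorithm script; the algorithm set is
  configurable.
- Greedy pair matching is order-robust but not globally optimal; a maximum
  matching could differ on dense scenes (the brute-force oracle pins the
  greedy semantics, not optimality).
- Merging of touching puncta biases counts slightly downward at high
  density; watershed splitting is deliberately out of scope.
- The 0.5 μm pairing criterion is centroid-to-centroid; an edge-to-edge
  reading would pair more liberally for large puncta.
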