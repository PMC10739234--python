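# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `neurofuse`, in the order the pipeline runs.

## Coordinates and data model

All grids are isotropic, 0-based and voxel-centered: the world position (mm,
RAS) of voxel `(i, j, k)` is `origin + spacing · (i, j, k)`. Anisotropic
NIfTI input is rejected at load time rather than silently resampled — the
pipeline's geometric reasoning (tube radii, gap lengths, registration
bounds) assumes one spacing, and hiding a resampling step would mask
acquisition errors. Intensities are stored as float32, labels as uint8 with
the fixed legend `0=REST, 1=CSF, 2=BRAINSTEM, 3=NERVE, 4=VESSEL`. Rigid
transforms are parameterized by three Euler angles (degrees, applied
x-then-y-then-z) about the volume center plus a translation (mm), and map
TOF world coordinates to CISS world coordinates.

## The phantom

The phantom stands in for the patient cohort: a deterministic function of
(config, seed) producing a paired CISS-like and TOF-like acquisition with
complete ground truth. Defaults: 96³ voxels at 0.4 mm; 25 seeds (0–24) form
the default study, mirroring a typical prospective series size.

Geometry (offsets in mm from the grid center): an ellipsoidal basal cistern
(semi-axes 8.5 × 6.5 × 11) of bright CSF; dorsal to it an elliptic-cylinder
brainstem; two 0.6 mm cranial nerves running from the brainstem into the
cistern. The nine-vessel tree — BA (radius 1.7 mm) with two terminal
branches, VA-le/ri (1.4 mm) joining it caudally, and PICA (1.0 mm),
AICA/SCA (0.8 mm) with two distal twigs each — is rasterized as capsule
tubes around polylines; non-junction waypoints get a small seeded jitter
(σ 0.15 mm). Wherever a vessel travels outside the cistern it carries a
snug perivascular CSF sleeve (tube radius + 1.2 mm), so every centerline
point lies in CSF and, importantly, the CSF compartment hugs the
vasculature tightly — this is what makes rigid registration against the
flow-void pattern well-posed. The left SCA passes within a thin CSF cleft
of the left nerve's tip; the contact site on the SCA surface is the
compression point used by the rating scale. The nerve deliberately stops
one CSF voxel short of the vessel: if the tubes touched, the background
could escape through the nerve tunnel and the flow-void network would no
longer be a closed hole of the CSF compartment.

Intensities are flat per-tissue means plus Gaussian noise (σ 4 by default):
CISS — CSF 100, flow voids 25, brainstem 55, nerve 70, rest 28; TOF —
arteries 180, everything else 25. No partial-volume or physics simulation
is attempted: the pipeline consumes contrast relations, not physics. One
consequence matters quantitatively: flow voids make up ≈12% of the CSF
area (cistern ∪ sleeves ∪ voids), so the 10th percentile of CISS intensity
over the CSF area sits *inside the flow-void intensity cluster* (≈28).
The intensity-inversion map exploits exactly this.

The TOF volume is rendered in its own frame, displaced by the inverse of a
true transform drawn per seed (uniform, ≤5 mm and ≤10° per axis); the tubes
are rasterized from the inverse-transformed centerlines, so mapping them
back through the true transform lands exactly on the truth vessels.

**Flow artifacts** are intensity substitutions: on each configured
wide-lumen vessel (radius ≥ 1.25 mm: BA and both VA), one or more random
trunk intervals of 3–8 mm have their lumen voxels raised to the CSF level —
the vessel segment simply disappears from CISS, which is the visual effect
the pipeline must compensate. **Pulsation artifacts** are additive ghost
replicas of the flow-void signal, displaced along grid axis 1 at a fixed
period (12 voxels = 4.8 mm) in both directions with amplitude 0.9 of the
void depth and geometric decay 0.5 per replica. The period/amplitude pair
is calibrated to the geometry: the first replica of the vessel plane must
land inside the cistern and be dark enough to cross the void/CSF Otsu
split, otherwise no counter (automated or visual) would register it.
Ghosts are confined to the one-voxel erosion of the CSF∪vessel compartment
so each blob is strictly surrounded by CSF — mimicking that ghosting is
conspicuous only against the bright cistern, and guaranteeing the blobs are
topological holes of the bright region.

What the phantom does **not** emulate: veins (indistinguishable from
arteries in these contrasts and poorly seen in TOF), partial-volume
gradients, intensity inhomogeneity/shading, anatomical variability beyond
waypoint jitter, and deformable motion. Tests passing on phantoms therefore
demonstrate the pipeline's *mechanics* (artifact compensation, geometric
fidelity, scoring logic), not clinical-grade robustness.

## Segmentation

Volume growing accepts the connected component (6-connected by default, to
avoid diagonal leaks between CSF and vessels) of voxels whose intensity
lies within a fixed band around the mean of the seed values. The band is
fixed rather than adapted to a running region mean: an adaptive mean makes
the result depend on the frontier processing order and is provably
non-monotone in the tolerance (an early-accepted outlier can shift the mean
and expel voxels a smaller tolerance would have kept), whereas the fixed
band is order-independent, monotone, and identical to a brute-force flood
fill — properties the test suite asserts. The phantoms have no shading, so
nothing is lost; on shaded data the tolerance simply has to cover the
shading range.

The CSF stage grows the bright cisterns (tolerance 25) and then performs
leak-robust hole filling: dilate by 0.8 mm, `binary_fill_holes`, erode
back, and union with the grown mask. Plain hole filling is fragile here —
one dark artifact blob cutting the thin perivascular sleeve connects the
entire flow-void network to the outside and silently drops *all* vessels
from the CSF area (observed on roughly half the seeds before sealing). The
erode-back construction seals channels narrower than ~1.6 mm while leaving
the outer surface in place; its only side effect is a sprinkling of dark
fillet voxels at concave sleeve/cistern junctions, which is why the
pulsation-blob counter ignores a perivascular exclusion zone (below). The
brainstem stage grows inside a user (or truth-derived) bounding box,
outside the CSF mask, within a ±12 band — tight enough to exclude both the
darker background (28) and the brighter nerves (70). Nerves are tube
rasterizations of marked centerlines; in phantom studies the truth
centerlines are passed in, playing the expert. TOF vessels grow from one
seed per trunk (band ±40) after a hyperintensity sanity check against the
99.9th percentile. Label assembly resolves overlaps with precedence
VESSEL > NERVE > BRAINSTEM > CSF > REST.

"Manual editing" is a declarative, replayable script of ball additions/
removals, component keeps/removals, hole fills and dilations/erosions; the
study driver derives one automatically by removing detected pulsation
blobs (small balls on every blob voxel) — a scripted stand-in for what an
expert does interactively, and the only difference between the `-opt` and
plain variants.

## Registration and fusion

The moving image is the binary TOF vessel mask; the fixed target is the
flow-void component of the CSF sub-volume (CSF-labeled voxels at or below
the void/CSF Otsu split). Registering against the whole CSF area is
ill-posed by construction — the CSF strictly contains the vessels with a
≥1.2 mm sleeve margin, so the overlap objective is flat over a plateau far
wider than the accuracy target; the void pattern is the informative signal
and keeps the procedure label-driven. Search is coarse-to-fine and fully
deterministic: a rotation grid (±10° in 5° steps per axis) with an
exhaustive FFT translation sweep on a 2× downsampled grid, then coordinate
descent over all six parameters with step halving (0.8 mm/4° down to
0.05 mm/0.05°). The refinement objective transforms the moving-mask voxel
centers and samples the fixed mask trilinearly — with both mask sums
constant this is soft Dice up to normalization, is smooth in the
parameters (enabling sub-voxel optima), and costs one 6000-point
interpolation per evaluation instead of a full-volume resample. Measured
recovery on the default misalignment distribution: 10/10 seeds within
0.03 mm and 0.31°, about 2 s per phantom. Mutual information over raw
intensities is available as a config alternative (`registration.metric`).

The inversion map is linear and monotone decreasing with clamping: source
range = 5th/95th percentile of TOF intensity inside the vessel mask; target
range = [0, t_hi] with t_hi the 10th percentile of CISS intensity over the
CSF area. Because the CSF area includes the flow voids (≈12% of it), t_hi
lands at the native void level — fused vessels come out at least as dark as
native flow voids, which is the whole point of inversion. Fusion resamples
the vessel mask into CISS geometry (nearest-neighbor; no label bleeding)
and *replaces* the CISS value with the inverted, trilinearly resampled TOF
intensity at every mask voxel — replacement rather than blending keeps the
locality invariant exact (fused ≡ CISS outside the provenance mask), and
all vessel voxels are replaced, not only gap voxels, since fusion is
supposed to clarify intact vessels too. The provenance mask records every
replaced voxel and doubles as the VESSEL label of the fused variants.

## Rendering

Orthographic, unlit emission-absorption ray casting: per pixel, samples at
spacing/2 steps fetch trilinear intensity and nearest-neighbor label
(labels are categorical; interpolating them would invent tissue), classify
through the per-label piecewise-linear transfer function, and composite
front-to-back (`C += (1−A)·α·c`, `A += (1−A)·α`) with early termination at
A ≥ 0.99 and the background under the remaining transparency. No lighting:
the images are evaluated for structure presence, and the unshaded operator
admits an exact hand oracle (the recursive back-to-front "over" operator),
which the suite checks to 1e-6. Default tables: the CSF table maps the
void level to opaque red fading to transparent at 35% of the way to the
CSF level; VESSEL (fused) is opaque red; nerves yellow (α 0.8); brainstem
light grey (α 0.15); REST fully transparent.

## Rating and artifact accounting

Each branch centerline is sampled at 1 mm arc length. A sample is *shown*
when some voxel of its local cross-section disk (radius + 0.2 mm margin,
±half a voxel axially) either is CSF-labeled with intensity at or below
the visibility threshold, or lies in the fusion provenance mask. The
threshold is t_hi for fused variants and the void/CSF Otsu split otherwise.
The disk (rather than a ball) keeps gap-boundary localization near one
voxel; with 1 mm sampling, isolated gap lengths are recovered to well
under 1 mm, while overlapping or branch-crossing gaps merge — as they do
visually.

The 0–5 score is a decision table over four monotone statistics (overall
coverage, proximal/branching-zone sample covered, compression-zone samples
all covered, every branch complete):

| condition | score |
|---|---|
| nothing covered | 0 |
| every branch fully covered | 5 |
| coverage < 0.15 | 1 |
| compression zone covered | 4 |
| branching zone covered | 3 |
| otherwise | 2 |

evaluated top to bottom. All cut-offs live in `ScoringConfig`. The
compression zone is the 5 mm neighborhood of the compression point; a
vessel with no samples there falls back to "trunk complete" as its
relevant-parts criterion. Because every statistic is monotone in the
covered set and the table is ordered, the score never decreases when
coverage grows (property-tested). The anchors are exact: score 0 ⇔ empty,
score 5 ⇔ all branches complete.

Flow artifacts: a vessel of radius ≥ 1.25 mm flags when any maximal
uncovered interval is ≥ 2 mm. Pulsation artifacts: connected hypointense
components inside the CSF sub-volume, of ≥ 5 voxels, lying entirely
outside the perivascular exclusion zone (vessel tubes dilated by 1.6 mm —
wide enough to skip both true voids and the hole-sealing fillets, far
inside the ≥4 mm ghost displacement). Blobs are attributed per voxel to
the nearest vessel centerline; study tables count phantoms-with-artifact
per vessel and variant.

## Study conditions and problem sizes

The default study is 25 phantoms at 96³ (seeds 0–24) with flow gaps on
BA/VA, pulsation ghosts, and random misalignment; each phantom is
segmented, registered, fused, edited and scored in all four variants
(~4 s/phantom, ~100 s for the study). Registration parameter recovery is
measured on 10 phantoms. Segmentation fidelity (per-label Dice) is
measured on aligned, artifact-free phantoms at noise σ 0 and σ 4 — the
statistic isolates segmentation, and registration accuracy is already
covered by its own experiment; a sub-voxel registration residual would
otherwise dominate the Dice of thin, one-voxel-wide twigs.

## Known limitations

- Flat per-tissue intensities: no shading field, so the fixed-band growth
  criterion is untested against the inhomogeneity it would face on real
  scanner data.
- The sleeve construction gives registration strong geometric anchors;
  real cisternal anatomy is less cooperative, and the reported recovery
  numbers should be read as a best case for the optimizer, not the
  modality.
- The rating thresholds (0.15 coverage, 2 mm gap, 5-voxel blobs) are
  calibration choices over a verbal scale; they are config-exposed and the
  anchors (0 and 5) are threshold-free.
- One compression site per phantom; multi-vessel compression is not
  simulated.
- Veins are absent by design, matching the arterial focus of the imaging
  contrasts involved.
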