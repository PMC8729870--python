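# Methods

This note records the models behind `petmoco`, the parameters that matter,
what the synthetic phantom does and does not emulate, and the numerical
choices a maintainer should know about.

## 1. The phantom as a stated world

The simulator emulates a 60-min dynamic ¹⁸F-FDG brain acquisition rebinned
as 24×5 s, 1×60 s, 1×120 s, 11×300 s (37 frames, 3600 s).  Geometry is a
desk-scale 64×64×48 grid at 3 mm isotropic (stand-in for a clinical
344×344×127 at ~2 mm): an ellipsoidal brain with a gray-matter shell
(outer semi-axes 60/72/45 mm) and white-matter core, two deliberately
asymmetric lateral-ventricle-like low-uptake ellipsoids (without them a
smooth ellipsoid is nearly rotation-symmetric and in-plane rotations become
unidentifiable to any registration), and two vessel cylinders
(3 mm radius = 2-voxel diameter, 30 mm apart) standing in for the petrous
internal carotid arteries, kept clear of the brain so the local
two-compartment assumption of the partial-volume correction holds.

Per-region kinetics are typical human FDG values
(GM K1 = 0.102, k2 = 0.130, k3 = 0.062 min⁻¹, Vb = 0.05;
WM 0.054/0.109/0.045, Vb = 0.03; CSF-like ventricles near zero; vessels are
pure blood pool, Vb = 1).  Each frame holds the frame-duration average of
the continuous regional curve (how PET frames integrate activity), blurred
with an isotropic Gaussian PSF (default FWHM 4.5 mm).  Radioactive decay is
omitted — the images represent decay-corrected activity, as reconstructed
PET does.

Counting noise: expected counts per voxel and frame are
`value · duration · count_sensitivity` with a single scalar sensitivity
(default 1e-4 counts per Bq/mL·s·voxel, chosen so a late 300-s frame has
~100–300 counts/voxel — clinically plausible statistics — while 5-s early
frames are substantially degraded).  Relative noise then falls as
1/√duration, which reproduces the qualitative regime in which very short
early frames are hardest.

The arterial plasma input is a tri-exponential bolus with linear rise
(A₁(t−t₀) − A₂ − A₃)e^(−λ₁t) + A₂e^(−λ₂t) + A₃e^(−λ₃t); defaults give a
peak ~50 s after injection (~21 kBq/mL).  The mid decay rate is set to
0.35 min⁻¹ (≈2-min half-life distribution phase): with a slower tail the
Patlak transient for brain-like k2+k3 has not settled by 25 min and the
graphical slope is biased several percent — an input-function property, not
an estimator defect.  Whole blood = plasma / ratio(t) with
ratio(t) = r∞ − (r∞ − r0)e^(−t/τ) (1 → 1.25, τ = 600 s).

What the phantom does **not** emulate: attenuation, scatter, randoms,
reconstruction artefacts, anatomical detail beyond the region geometry,
decay, and non-rigid motion.  A green test therefore establishes the
*algorithmic* correctness of the chain under a known forward model — not
clinical performance.

### Simulated-motion experiments

*Interframe*: every non-reference frame receives a random rigid transform
with per-axis translations drawn from {0, 1, 2} voxels (random sign) and
per-axis rotations from {0, 0.5, 1}°; ten repetitions over six base
subjects give the 60-dataset protocol.  Margins are sized so the head stays
in the field of view (total activity preserved within 2%).
*Intraframe*: the noise-free reference frame is partitioned into
independent Poisson subframes (valid because Poisson thinning of list-mode
counts yields independent Poisson subframes) — 10×30 s or 20×15 s — and a
random subset receives 3–5 mm translations and sub-degree rotations.

## 2. Tissue model and Patlak analysis

The irreversible two-tissue-compartment model (k4 = 0) is evaluated in
closed form: C_T = (1−Vb)[Ki·∫Cp + (K1k2/(k2+k3))·e^(−(k2+k3)t) ⊛ Cp]
+ Vb·C_blood with Ki = K1k3/(k2+k3); integrals by trapezoid on a 1-s grid,
the exponential convolution as a discrete trapezoid-weighted convolution
(verified against ODE integration to 3×10⁻⁶ sup-norm).

Patlak: ordinary least squares of C_T/Cp against ∫Cp/Cp over frames whose
interval **ends** at or after t* = 1500 s.  This inclusion rule yields
exactly 8 points on the 37-frame schedule (a midpoint rule would give 7);
it is a reconstruction of an ambiguous convention, chosen to match the
protocol's stated count.  CMRGlc = 0.1·slope·glucose/LC (LC = 0.65,
glucose in µmol/L; 0.1 converts to µmol/100 g/min at density 1 g/mL).
Slope-recovery accuracy on noiseless phantoms is ~1–2%; with Vb > 0 the
Patlak slope estimates ≈ (1−Vb)·Ki plus a small blood-term drift — the
AIF-vs-IDIF comparisons are unaffected because both input functions see the
same tissue data.

## 3. The conditional GAN at desk scale

Generator: 3D U-net-like encoder–decoder, depth 3 (2× average-pool down,
nearest-neighbour up), one 3³ convolution per level, 16 base channels,
skip concatenation at mirrored resolutions, tanh output; dropout (p = 0.3)
in the bottleneck/decoder realises the stochastic input z and is disabled
at inference, making predictions deterministic.  Discriminator: PatchGAN
emitting an 8× downsampled grid of logits, with two extra convolutional
layers over the canonical patch classifier.  All layers, their analytic
gradients, and Adam are implemented in NumPy (float32); convolutions are
decomposed over the 27 kernel offsets into batched BLAS matmuls.
Finite-difference checks confirm the gradients.

Training: per-volume robust (0.1/99.9 percentile) min–max normalisation to
[−1,1]; random 32³ patches; alternating D/G Adam steps (G lr 1e-3,
D lr 2e-4, β₁ = 0.5).  The nominal objective weighting λ = 1 depends on how
the two loss terms are normalised; with per-element means on both (the
pix2pix convention, used here) it lets the adversarial gradient swamp the
L1 anchor and desk-scale training diverges — the pix2pix lineage uses
λ = 100 for the same reason.  We keep λ_L1 = 1 as the objective weight and
scale the non-saturating adversarial gradient by `lambda_adv = 0.05`.

Two desk-scale findings shaped the inference path:

* **Border hallucination.** Zero-padded convolutions synthesise bright rims
  at the volume faces.  These rims are locked to the voxel grid, not the
  anatomy, and bias any registration of mapped images toward the identity
  rotation.  Predictions therefore zero a 3-voxel border shell
  (`edge_crop`), which carries no anatomy at this geometry.
* **Pose bias and its cancellation.** The small generator carries a
  systematic residual pose error (an apparent 1–2° rotation of its output
  relative to the raw reference).  `moco_cgan` therefore registers each
  mapped frame against the *reference frame passed through the same
  mapping*: both images share the generator's appearance and its pose bias,
  which cancels in the relative transform, while the estimates still live
  in F_ref's geometry.  (`map_reference=False` restores the literal
  raw-reference arrangement; at full scale, with a deep well-trained
  network, the distinction should vanish.)

Desk scale also permits a single *pooled* mapping trained on pairs from
several late-frame indices and shared between them (mappings are matched by
frame mid-time); training all 36 per-index mappings remains available.
With 8 synthetic subjects, 3 epochs and no augmentation this trains in
~5 min on one CPU and reduces validation L1 from ~0.50 to ~0.10; on a
held-out subject with the interframe protocol, every evaluated frame is
then recovered within 0.2 mm / 0.45°.  Augmentation (shared spatial
transform, independent intensity perturbation) is implemented and tested
but off in the short desk-scale recipes: at ~100 gradient steps it costs
more pose fidelity than it buys.  The augmentation yield of the full-scale
protocol is an exposed parameter (`augment_factor`), not a hard-coded
count.  Mapped images are appearance proxies for registration only — never
quantitative images.

## 4. Registration

Rigid 6-DOF (mm translations; intrinsic Z-Y-X Euler degrees about the image
centre), multiscale MI, coarse-to-fine with pyramid shrink factors (4,2,1)
and per-level Gaussian smoothing (2,1,0 voxels).  Numerical choices that
proved load-bearing:

* **Powell** (derivative-free) rather than gradient descent: the binned MI
  has no cheap analytic gradient.  Per-level direction-set cycle budgets
  (6,8,2) and xtol = 0.01.
* **Cubic-spline metric resampling** (moving image spline-prefiltered once
  per level): with trilinear resampling the interpolation low-pass loss
  outweighs the alignment gain of small rotations on smooth images and the
  optimiser systematically under-rotates.
* **48 histogram bins**, joint histogram by a single `bincount` per cost
  evaluation (fixed image binned once per level); optional per-level output
  sampling stride (1,2,1) for speed; optional dilated foreground mask
  (`mask_threshold`, off by default).
* Convergence flag: final MI must not fall more than 0.5% below the
  identity-start MI of the finest level; non-convergence is reported,
  never silently accepted.

Measured accuracy: a noise-free reference shifted by (2,1,0) voxels and
rotated 1° is recovered within 0.05 mm / 0.06°; on smooth generator
outputs the rotation precision floor is ~0.3°, which dominates the error
budget of the cGAN-aided path.

`moco_standard` sums frames within the first 3 min (duration-weighted,
180 s of data) into an early reference, registers later frames to it with
4-mm presmoothing, and composes every estimate with the early-reference →
F_ref transform so both methods are comparable in F_ref space.
`correct_series` resamples frames by the inverse estimates with cubic
splines (trilinear double-resampling costs 2–4% in-brain RMS at 3-mm
voxels; cubic keeps the round trip under 2% of the dynamic range).

## 5. IDIF chain

The vessel ROI lives in F_ref space (ground-truth mask in simulation; an
externally supplied mask for real data).  Motion is handled ROI-side: the
mask is moved by each frame's vector before sampling — the frame data are
never resampled for TAC extraction.

Partial-volume correction is a two-compartment (vessel / locally uniform
background) iterative forward-blur scheme: since only the vessel mask's
blur pattern enters, the update is scalar —
v ← v·m/(b + (v−b)·R) with R the vessel self-recovery coefficient of the
PSF-blurred mask — run per frame to relative tolerance 1e-3, max 50
iterations, non-convergence flagged.  The background estimate comes from a
lateral dilation ring restricted to the vessel's own z-slab (an
unrestricted ring reaches the hot brain above the vessels and corrupts the
estimate).  On the noiseless phantom the recovery is exact to <0.1%.

Postprocessing order (fixed): PCHIP interpolation to a 1-s grid (monotone,
no bolus-peak overshoot) → cross-calibration scale (1 in simulation) →
plasma conversion via the plasma-to-blood ratio → delay correction
(upslope-derivative cross-correlation against the AIF within ±30 s at 1-s
resolution; a window-edge hit is flagged) → convolution with the τ = 5 s
monoexponential dispersion kernel, discretely normalised to unit integral.
Whether delay precedes dispersion is not determinate from the source
pipeline's prose; delay-then-dispersion follows the order in which the
corrections are described.  End-to-end on a noiseless motion-free phantom
the IDIF AUC is within ~1% of the true AIF's.

## 6. Assessment machinery

|%Δ| = |a − b|/|b| × 100 (reference in the denominator; scale-free).  The
histogram-area index is reconstructed as the **intensity-weighted**
histogram area over above-background bins (reference-locked absolute bin
edges, background = lowest 2% of the reference range): a count-only area
degenerates to a suprathreshold voxel tally and is unstable under
interpolation, whereas the intensity-weighted form is sensitive to the
intensity-scale relationship between images (halving intensities gives a
50% delta) and motion-stable to <0.2% on measured frames.  Mutual
information doubles as an image-quality index (joint histogram, nats,
MI = 0 for constant images by convention).

The interframe experiment tabulates AUC and CMRGlc |%Δ| (mean ± SD per
arm) over base-subjects × repetitions for the cGAN-aided, standard,
uncorrected and ground-truth-oracle arms; CMRGlc_AIF and CMRGlc_IDIF are
computed from the *same* motion-corrected GM time-activity curve, so their
|%Δ| isolates the input-function error.  GM means are ROI-level (the
voxelwise parametric map of the clinical pipeline is out of desk scope).
No hypothesis testing — the experiments report descriptive statistics only.

## 7. Known limitations

* The NumPy networks are desk-scale by design; full-scale training
  (full-resolution volumes, dozens of epochs, all 36 per-index mappings) is
  configurable but takes CPU-days.  Cross-platform bit-identity of trained
  weights is not guaranteed across BLAS builds; same-platform runs are
  bit-reproducible by seed.
* Rotation precision of the cGAN-aided path is limited to ~0.3–0.5° by the
  smoothness of generator outputs; translations are recovered an order of
  magnitude more precisely.
* The phantom's uniform-background neck region makes PVC easier than in
  vivo, where the carotids sit in heterogeneous soft tissue; the <2%
  end-to-end IDIF accuracy should be read as an upper bound of the chain's
  own fidelity, not a clinical claim.
* Real-data ingestion is NIfTI + JSON sidecar only; no DICOM, no list-mode.
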