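# Methods

This note documents the models, algorithms and numerical choices behind
`usblt`, and what the packaged synthetic studies do and do not demonstrate.

## Forward model

Light propagation is modelled with the continuous-wave diffusion
approximation,

    (-div kappa grad + mu_a) Phi = q,      kappa = 1 / (3 (mu_a + mu_s')),

valid in highly scattering, weakly absorbing media such as soft tissue in
the red band. The boundary carries a Robin condition
`kappa dPhi/dn + Phi / (2 A(n)) = 0`, with the internal-reflection factor
`A(n)` computed from the refractive-index mismatch by the Groenhuis/Keijzer
polynomial approximation (`A(1.33) ≈ 2.95`).

Optical properties are spectral: absorption follows Beer's law over a
chromophore list (water, oxy- and deoxy-haemoglobin by default) and reduced
scattering follows the power law `mu_s' = a (lambda/1 um)^(-b)`. The slab
defaults are `a = 0.14`, `b = 2.8`, `n = 1.33` — muscle-like values under
which `mu_s' ≈ 0.59 mm^-1` and `mu_a ≈ 0.01–0.025 mm^-1` across 600–640 nm.
The bundled extinction curves are smooth representative spectra with the
correct magnitudes and spectral slopes in the red band; they are
deliberately replaceable (CSV loader) and none of the packaged studies'
conclusions depend on their fine structure, because every method comparison
uses the same forward model on both sides. Chromophore concentrations
default to water fraction 0.5, HbO 0.01 mM, Hb 0.005 mM.

Discretisation: linear (P1) tetrahedra on a structured grid. Each grid cube
is split into six tetrahedra along its main diagonal (Kuhn split), which is
conforming and gives every interior node the same lumped volume `h^3`; a
volume-symmetric alternative (the alternating five-tet split) was rejected
because its lumped volumes alternate 1:5 between node parities, which would
imprint a checkerboard onto the total-sensitivity field that the
permissible region is computed from. The Kuhn split is not mirror
symmetric, so symmetric configurations are symmetric only to discretisation
accuracy (a few percent on coarse meshes), not to solver tolerance.
The stiffness term uses exact P1 gradients, absorption the consistent
element mass matrix, and the Robin term the triangle mass matrix on
boundary faces. Systems are factorised once per wavelength
(`scipy.sparse.linalg.splu`; diagonally preconditioned CG above 1e5 nodes)
and reused across all detectors.

The Jacobian row for detector `j` at wavelength `lambda` is assembled by
reciprocity from one adjoint solve per (detector, wavelength): a unit
source at the boundary node nearest the detector gives the adjoint field
`Phi_adj`, and `J[(lambda, j), n] = gamma_lambda Phi_adj[n] V_n` with `V_n`
the lumped nodal volume and `gamma_lambda` the emission-spectrum weight
(uniform across the five simulation wavelengths by default; a Gaussian
spectrum generator covers chemiluminescent-dye configurations). The
measurement operator is the field value at the boundary node nearest the
detector; any constant exitance factor is common to all methods and cancels
in the comparisons. Small negative field values from the discretisation are
clipped to zero; a warning reports clips exceeding 1e-10 of the field
maximum (they can reach ~1% on very coarse meshes, and vanish with
refinement).

## Permissible region

Total sensitivity: `s_n = sum_j J[j, n]` over all stacked rows. Given a
guide coordinate (the ultrasound-reported source position), the nearest
node is the reference node (`s0 = s[ref]`); the nodes of interest are the
inclusive band `{ i : s0/d <= s_i <= s0 d }`. Consequences used by the
tests: the reference node is always a member; the band is monotone in `d`;
the truncated system's sensitivity dynamic range is bounded by `d^2`
(against ~1.5e4 for the whole desk-scale model). Zero-sensitivity nodes are
excluded from dynamic-range computations. In the simulated studies the
guide coordinate is the true source centroid (exact knowledge), with
optional seeded Gaussian jitter to emulate ultrasound localisation error;
for multiple sources, the centroid of the source centres is used. A helper
converts an ultrasound depth measured from the far face of a slab to the
depth below the detector face (a 20 mm slab with the source reported at
15.5 mm gives a region centre depth of 4.5 mm).

The comparator regions are the whole mesh (no constraint) and a "large PR"
box bounded laterally (default half-width 7.5 mm — visibly larger than the
default source, chosen once) with no depth limit, mirroring the standard
camera-only practice in which depth cannot be constrained.

## Solver

All three methods share one solver, so performance differences isolate the
region effect. The solver is a sparsity-promoting conjugate-gradient
scheme on the (truncated) linear system:

1. **Row whitening.** Rows are weighted by `1/|y_i|`, the maximum-likelihood
   weighting when the noise standard deviation is proportional to the
   signal (the package's default noise convention). Without it the fit is
   dominated by the few largest measurements.
2. **Damped CGLS.** `scipy.sparse.linalg.lsqr` with Tikhonov damp
   `0.01 * 10^(-SNR/20) * ||y_w||`, i.e. scaled to the relative noise level
   taken from the measurement provenance. The damp vanishes for noiseless
   data, so consistent sparse sources are recovered exactly; under noise it
   suppresses the semiconvergent speckle that otherwise makes hard
   thresholding land on spurious support. 40 inner iterations per round.
3. **Nonnegative support shrinkage.** After each round the iterate is
   projected onto `x >= 0` and entries below `tau * max(x)` (default
   `tau = 0.1`) are zeroed; the next round re-solves on the shrunken
   support. Up to 8 rounds, stopping when the support stabilises.

Columns are not normalised by default (a flag restores normalisation):
keeping the natural column scaling preserves the sensitivity weighting
whose noise amplification the permissible region is designed to remove, and
the damped, whitened iteration handles the resulting conditioning. The
damp scale (0.01) and keep fraction (0.1) were fixed once on the default
testbed by requiring stable residuals at the noise level and exact
noiseless recovery, and are shared by every method and experiment. The
solver is deterministic: identical inputs give bit-identical
reconstructions. Zero columns are dropped with a warning; `y = 0` returns
`x = 0`.

## Metrics

With `|S|` the physical volume of node set `S` (lumped nodal volumes, not
node counts):

- `VR = |ROI| / |tROI|`, ideal 1 (volume agreement only — VR can be 1 with
  the source in the wrong place);
- `DICE = 2 |ROI ∩ tROI| / (|ROI| + |tROI|)`, ideal 1;
- `MSE = (1/N) sum_i (x_i - x0_i)^2` over **all** N mesh nodes (the printed
  normalisation is by the model size, not the region size).

The reconstructed ROI is the set of nodes strictly above a median
threshold; because most nodes are exactly zero, the median is computed over
the nodes above 1% of the expected source intensity. An empty candidate
set is an error (nothing recovered); the even-size median is the midpoint
of the two central values. Repeated-trial summaries report the mean and
population standard deviation (a single realization has std 0).

Profile tools sample the nodal lattice along an axis through a fixed point.
FWHM interpolates the half-maximum crossings linearly around the global
peak and is flagged undefined when a crossing is missing on either side.
Two-source contrast is the Michelson form `(p - v)/(p + v)` with `p` the
smaller of the two dominant peaks and `v` the valley between them; it is
undefined (flagged, not fatal) when the profile has fewer than two local
maxima.

## Synthetic studies and their scale

The packaged study conditions reproduce the slab protocol at desk scale:
40 × 40 × 20 mm slab, **2 mm** node spacing (4851 nodes), a 30 × 30 mm
detector grid at **3 mm** pitch (121 detectors) on z = 20 mm, wavelengths
600–640 nm in 10 nm steps, a cylindrical source (r = 1.5 mm, h = 5 mm,
intensity 10 a.u.) at 15 mm depth, Gaussian noise at SNR 20 dB, and **20**
paired noise realizations (the acceptance script uses 40 to tighten the
Monte-Carlo means). The full-scale protocol (0.5 mm nodes, 0.75 mm pitch —
1681 detectors, 100 realizations) is reachable through the same
configuration object but is not the test default. Noise is per-measurement
proportional (`sigma_i = |y_i| 10^(-SNR/20)`); a global-RMS convention is
available behind a flag. Realization `k` uses seed `base_seed + k`, and all
methods see identical noisy data per seed, so method differences are fully
paired.

At this scale the painted source covers only two mesh nodes, so the set
metrics (VR, DICE) are far more granular than at full scale: a
reconstruction one node off the truth scores DICE 0. The packaged tests
therefore check *orderings* and *relative improvements* between methods —
which are stable at desk scale — rather than absolute metric values, which
are not transferable across scales. What passing tests show: the guided
region yields the lowest MSE (≈25–30% below whole-mesh at d = 3), VR and
DICE closest to 1, an MSE-optimal dynamic range at small d (≤ 3), and
higher two-source profile contrast at 8 mm separation. What they do not
show: performance on unstructured anatomical meshes, heterogeneous-tissue
atlases, or real camera data — the forward model supports per-region
optical properties so such studies can be built, but no atlas import is
provided.

## Known limitations

- Structured slab meshes only; node counts follow the regular-grid formula
  and will not match unstructured meshers run at the same nominal spacing.
- The diffusion approximation misrepresents transport within ~1 transport
  mean free path of sources and boundaries; the analytic-comparison test
  deliberately evaluates at 3.75–7.5 mm from the source.
- The solver is a documented, reproducible variant of the
  compressive-sensing CG family, not a re-implementation of any specific
  published code; absolute reconstruction values depend on its defaults,
  method comparisons much less so.
- The ultrasound guide is an input coordinate; no image segmentation is
  performed. Guide error is modelled only as isotropic Gaussian jitter.
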