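# usblt

Ultrasound-guided, model-driven permissible-region reconstruction for
bioluminescence tomography (BLT).

## The problem

Bioluminescence tomography reconstructs the 3D distribution of a
light-emitting source inside scattering tissue from multi-wavelength images
of the light reaching the surface. The discrete model is linear,

```
J x = y,
```

where `x` holds nodal source intensities on a finite-element mesh, `y`
stacks all (detector, wavelength) boundary readings, and the Jacobian `J`
encodes diffuse light propagation. The system is strongly underdetermined
(hundreds of measurements, thousands of unknowns) and the inversion
amplifies noise on nodes the detectors can barely see, so unconstrained
reconstructions of deep sources localise poorly and misestimate intensity.

`usblt` implements a permissible-region strategy that is *guided* by an
externally measured source coordinate (in practice: ultrasound) and
*driven* by the forward model itself. With the total sensitivity of node
`n` defined as

```
s_n = sum_j J[j, n],
```

the mesh node nearest the guide coordinate `(x0, y0, z0)` becomes the
reference node with sensitivity `s0`, and the nodes of interest are

```
NOI(d) = { i : s0/d <= s_i <= s0 * d },
```

a band of configurable dynamic range `d` around the reference. Truncating
`J` to the NOI columns bounds the dynamic range of the retained
sensitivities by `d^2`, confines the reconstruction in all three dimensions
(including depth, which camera data alone cannot fix), and removes the
low-sensitivity nodes whose noise amplification destabilises the solve.

The package provides, end to end:

- structured tetrahedral slab meshes and boundary detector grids
  (`usblt.mesh`);
- chromophore-based optical properties and a CW diffusion FEM forward model
  with Robin boundaries; multi-wavelength Jacobian assembly by adjoint
  solves (`usblt.spectral`, `usblt.fem`, `usblt.forward`);
- the permissible-region machinery and a sparsity-promoting conjugate-
  gradient solver, plus the two comparator methods — whole-mesh and a
  laterally bounded "large PR" box (`usblt.inversion`);
- VR / DICE / MSE evaluation with median thresholding, FWHM and two-source
  contrast profile tools (`usblt.metrics`);
- synthetic-study drivers: source painting, SNR-specified Gaussian noise,
  repeated-trial statistics, dynamic-range sweeps, two-source resolution
  experiments (`usblt.experiments`);
- plain-text file formats and a CLI (`usblt.io`, `usblt.cli`).

## Worked example

```python
import usblt as u

# Desk-scale slab study: 40 x 40 x 20 mm slab, 2 mm nodes, 11 x 11 detector
# grid on z = 20 mm, five wavelengths 600-640 nm, a cylindrical source
# (r = 1.5 mm, h = 5 mm, intensity 10) at 15 mm depth, SNR 20 dB.
testbed = u.Testbed(u.ExperimentConfig())

report = u.run_repeated(testbed, methods=("whole", "large_pr", "us_guided"), d=3.0)
print(report.summary()[["method", "vr_mean", "dice_mean", "mse_mean"]])
```

Output (20 paired noise realizations, base seed 0):

```
      method  vr_mean  dice_mean  mse_mean
0      whole  16.7500   0.111803  0.040300
1   large_pr   4.9875   0.344236  0.031465
2  us_guided   3.0250   0.449524  0.029155
```

Reading: the ultrasound-guided region gives the volume ratio and DICE
closest to the ideal value of 1 (best localisation) and the smallest mean
square error versus the known truth — here 28% below the whole-mesh MSE, a
reduction consistent with running the same comparison at full scale. A
dynamic-range sweep shows *why* `d` matters:

```python
sweep = u.dynamic_range_sweep(testbed, (1.2, 1.5, 2, 2.5, 3, 4, 6, 10))
print(sweep[["d", "noi_size", "mse_mean"]])
```

```
      d  noi_size  mse_mean
0   1.2       419  0.059081
1   1.5       907  0.017047
2   2.0      1528  0.018798
3   2.5      1984  0.032185
4   3.0      2346  0.029155
5   4.0      2828  0.020738
6   6.0      3521  0.037236
7  10.0      4142  0.037685
```

Too small a band (`d = 1.2`) excludes the true source nodes; too large a
band re-admits the noisy low-sensitivity nodes. The optimum sits at small
`d` (here 1.5), and `d = 3` acts as a safe upper choice when the optimum
cannot be known in advance.

The same study is available from the shell:

```sh
usblt experiment slab-15mm --reps 20 --seed 0 --out-dir out/
usblt experiment dr-sweep --d 1.2,1.5,2,2.5,3,4,6,10 --reps 20 --out-dir out/
usblt experiment two-source --separations 4,6,8 --out-dir out/
```

## Documentation

`docs/methods.md` describes the forward model, the solver, the metric
definitions, the synthetic-data conditions and the package's numerical
choices and limitations.
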