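# cdsfcrf

Sparse reconstruction of compressive-sensing MRI with a **cross-domain
stochastically fully connected conditional random field** (CD-SFCRF), evaluated
against the zero-filled least-squares baseline on a synthetic prostate phantom.

MRI measurements are made in k-space, but the image prior lives in the spatial
domain. Compressive sensing undersamples k-space (here with radial line
patterns) to cut acquisition time, and the reconstruction must supply the
missing information. This package is for researchers studying CRF-based
reconstruction: it simulates the whole acquisition–reconstruction–evaluation
loop on images with known ground truth, so no scanner data is required.

## The model

Given undersampled k-space observations $X = \{x_\omega\}$ on a sampling mask
$\Omega$, the reconstruction $Y$ minimizes the energy

$$\psi(Y \mid X) \;=\; \lambda_u \sum_{\omega \in \Omega}
\bigl|\mathcal{F}(Y)_\omega - x_\omega\bigr|^2
\;+\; \lambda_p \sum_{\{i,j\} \in C} \bigl(1 - f(y_i, y_j, X)\bigr),$$

where $\mathcal{F}$ is the unitary centered 2-D DFT and the pairwise feature is
the guided similarity kernel

$$f(y_i, y_j, X) = \exp\!\left(\frac{-(y_i - y_j)^2 \,(x_i - x_j)^2}{3\sigma^2}\right),$$

with $x_i$ the zero-filled spatial representation of the measurements (the
guide). The unary term pins the estimate to every measured frequency; the
pairwise term suppresses intensity differences between pixel pairs whose guide
values disagree — exactly the streak artifacts the zero-filled image exposes.

The clique set $C$ makes the field *stochastically fully connected*: every
pixel pair $\{i,j\}$ within a truncation radius is included independently with
probability

$$P(i,j) = \rho \,\exp\!\left(\frac{-d_{ij}^2}{2\gamma^2}\right)
\exp\!\left(\frac{-(g_i - g_j)^2}{2\sigma^2}\right),$$

so informative (nearby, similar-intensity) pairs participate with higher
probability, with the 4-neighborhood always present. Inference is gradient
descent with a backtracking step size from the zero-filled initialization, so
the energy trace is non-increasing by construction.

## Worked example

`examples/03_reconstruct.py` reconstructs a 128×128 textured phantom from 32 %
radial sampling:

```
sampling rate: 0.319
energy: 28.4262 -> 6.549398 in 214 iterations (converged=True)
PSNR zero-filled L2 : 25.59 dB
PSNR CRF            : 36.26 dB
```

The energy falls monotonically until the relative change drops below the
tolerance; the CRF reconstruction beats the zero-filled baseline by ~10.7 dB at
this rate because the pairwise term removes radial streaks while the unary term
keeps every measured k-space coefficient exact. The full sweep
(`examples/04_rate_sweep.py`) shows the gain at each operating point —
+4.5 dB at 17 %, +10.4 dB at 32 %, +15.4 dB at 47 % sampling — and that PSNR
rises with the sampling rate for both methods.

The other examples generate the phantom (`01_phantom.py`) and the radial masks
(`02_radial_sampling.py`). A thin CLI mirrors the pipeline:

```bash
cdsfcrf phantom --height 128 --width 128 --texture 0.15 --out ph
cdsfcrf acquire --image ph_image.nii.gz --rate 0.32 --out k.h5
cdsfcrf reconstruct --kspace k.h5 --method cdsfcrf --out recon.nii.gz
cdsfcrf evaluate --reference ph_image.nii.gz --test recon.nii.gz
```

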