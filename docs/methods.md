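# Methods

## Model

The reconstruction is posed as MAP-style energy minimization in a conditional
random field whose two potentials live in different domains. States $Y$ are
complex pixel values on the image grid; observations $X$ are the measured
k-space coefficients on the sampling mask $\Omega$.

**Unary (k-space data fidelity).**
$\psi_u = \lambda_u \sum_{\omega \in \Omega} |\mathcal{F}(Y)_\omega - x_\omega|^2$
with $\mathcal{F}$ the *unitary, centered* 2-D DFT (DC at `(H//2, W//2)`).
The squared-magnitude residual per sampled frequency makes the energy real,
non-negative and differentiable; a plain sum of complex residuals could cancel
and is not bounded below. Unitarity (Parseval) means the unary gradient,
$2\lambda_u\,\mathcal{F}^{-1}(\Omega \odot (\mathcal{F}(Y) - X))$, carries no
grid-size factors.

**Pairwise (guided spatial smoothness).** Over the sampled clique set $C$,
$\psi_p = \lambda_p \sum_{\{i,j\} \in C} (1 - f)$ with
$f = \exp(-(y_i-y_j)^2 (x_i-x_j)^2 / 3\sigma^2)$, evaluated on magnitudes; the
guide $x$ is the magnitude of the zero-filled reconstruction. The kernel is
kept verbatim with its $3\sigma^2$ denominator. $f$ is maximal when a pair
*agrees*, so it enters the minimized energy as $1-f$: minimizing then promotes
agreement, i.e. guided smoothing. The orientation of the feature inside the
energy was a genuinely open design point; $1-f$ is the only choice under which
gradient descent reduces artifacts rather than amplifying differences.

**Stochastic cliques.** Each unordered pair within `max_radius` is included
independently with probability
$P(i,j) = \rho \exp(-d_{ij}^2/2\gamma^2)\exp(-(g_i-g_j)^2/2\sigma^2)$.
The law combines spatial proximity and guide similarity so informative pairs
dominate; no closed-form distribution was prescribed for the indicator, so an
independent-Bernoulli law with Gaussian decays was chosen as the simplest
model with both properties. The 4-neighborhood is always included so
connectivity never vanishes as $\rho \to 0$. Cliques are drawn once per run
from the fixed guide (not the evolving estimate): this keeps the energy
well-defined during descent and the run reproducible; per-iteration resampling
exists behind `resample_cliques_every` but is off by default.

**Complex handling.** $Y$ stays complex during optimization (the k-space
residual demands it); pairwise terms act on $|y_i|$ and are routed through the
phase $y/|y|$ in the gradient (zero where the magnitude vanishes — the
magnitude is non-differentiable at the origin, an event of measure zero in
practice). The reported image is the magnitude.

## Inference

Gradient descent from the zero-filled initialization
$Y^0 = \mathcal{F}^{-1}(\Omega \odot X)$ with a backtracking line search: the
step halves whenever a trial step would increase the energy and resets after
each success. This guarantees a non-increasing energy trace on every run.
Convergence is declared when the relative energy drop falls below `tol`
(default 1e-6), when the energy falls below the absolute floor `energy_atol`
(1e-18, machine-zero scale — relative change is meaningless at round-off), or
at `max_iters` (default 500). A non-finite energy or gradient raises
`SolverDivergenceError` naming the iteration.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `lambda_u` | 1.0 | — | weight of the k-space fidelity term |
| `lambda_p` | 0.01 | — | weight of the pairwise term |
| `sigma` | 0.004 | intensity² (kernel) / intensity (clique law) | kernel bandwidth |
| `clique_gamma` | 3.0 | pixels | spatial decay of the clique law |
| `clique_rho` | 0.5 | — | clique density scale in (0, 1] |
| `max_radius` | 8 | pixels | clique candidate truncation |
| `step_size` | 0.25 | — | initial descent step (the unary curvature is $2\lambda_u$, so any step below $1/2\lambda_u$ is stable; backtracking covers the rest) |

The kernel argument is the *product* of the state and guide differences, so
$\sigma$ sets a saturation scale: pairs whose difference product exceeds
$\sqrt{3}\sigma$ contribute a nearly constant penalty and hence almost no
gradient. Small $\sigma$ therefore freezes strong true edges (their penalty is
saturated) while smoothing low-amplitude streak artifacts (still in the
quadratic regime) — the robust/truncated-quadratic mechanism familiar from
edge-preserving regularization. Calibration on the default textured-phantom
fixture showed exactly this: at $\sigma \ge 0.01$ the penalty blurs anatomy
and *loses* PSNR relative to the zero-filled baseline, while
$\sigma = 0.004, \lambda_p = 0.01$ gives +4.5/+10.4/+15.4 dB at 17/32/47 %
sampling (seed 0) and positive gains across every seed tested. $\lambda_u$ is
fixed at 1 (only the ratio matters); $\lambda_p$ and $\sigma$ are the
calibrated defaults, overridable in `CRFConfig`. The same $\sigma$ also enters
the clique law's guide-similarity factor, where at the default it concentrates
cliques on nearly-equal-intensity pairs — the "informative cliques" behavior.

## Sampling and acquisition simulation

Radial masks are unions of straight lines through the DC cell at angles
$k\pi/n$, rasterized nearest-cell at one step per cell along the dominant
axis, symmetric about the center by construction (so masks are point-symmetric
and conjugate symmetry is preserved for real images). `lines_for_rate` scans
line counts for the rate closest to a target, breaking ties toward fewer
lines; the scan is capped near $\pi \cdot \mathrm{diag}(H, W)$ lines, beyond
which angular spacing drops below the grid's angular resolution and coverage
has saturated (rate 1.0 is reachable on the grids used). Acquisition
multiplies the transformed image by the mask, with optional complex Gaussian
noise (default off — the reference workflow subsamples noiseless simulated
spectra).

## Synthetic phantom

The generator emulates a 2-D slice of a commercial prostate training phantom:
a 5 × 4.5 cm prostate ellipse, a 7 mm urethra disk on the midline, and
rejection-sampled hypoechoic lesions with diameters uniform in 5–10 mm,
disjoint and interior to the prostate. Intensity levels
(background/urethra/lesion/prostate = 0.1/0.2/0.4/0.7) are synthetic contrast
choices mimicking hypoechoic appearance, not a physical ultrasound or MR
simulation; they are overridable. `add_texture` superimposes smooth
band-limited noise (Gaussian-filtered white noise, peak amplitude ≤ 0.5)
inside the prostate footprint only, giving reconstructions fine detail to
preserve. The rectal wall of the physical phantom is omitted — it does not
affect reconstruction behavior. Because the phantom is piecewise-constant plus
smooth texture, passing tests demonstrate artifact suppression and detail
preservation on *this* morphology; real prostate MRI has richer texture and
coil/noise characteristics the generator does not model, so absolute PSNR
gains here overstate what clinical data would show (simpler scenes are easier
to reconstruct).

## Default problem sizes

The standard benchmark is a 128×128 phantom at 0.5 mm/pixel (the prostate
spans 100×90 px) with texture amplitude 0.15, swept at 17/32/47 % radial
sampling; unit tests use 64×64 at 1 mm/pixel. These sizes make a full sweep a
matter of seconds while keeping several pixels across the smallest lesion.

## Numerical choices and degenerate inputs

- PSNR uses peak = max |reference| (documented because no universal constant
  exists); identical images return `inf`; an identically zero reference is an
  error.
- The minimum-norm least-squares baseline is the closed-form zero-filled
  inverse (for a unitary partial-Fourier operator they coincide); an empty
  mask warns and returns zeros. The complex solution is idempotent under
  re-acquisition; the magnitude display image is not (phase is discarded),
  hence the `magnitude` flag.
- Masks store exact boolean grids; rates are exact cell-count ratios.
- Sweep cells derive their seeds from the master seed via a counter, so adding
  a method leaves other cells' randomness untouched.

## Known limitations

2-D single-coil simulation only: no NUFFT/non-Cartesian gridding, no parallel
imaging, no 3-D volumes, no physics-based contrast. The pairwise weight and
bandwidth were calibrated on the default phantom; substantially different
intensity scales require rescaling `sigma` (it is not scale-invariant).
Clique-weight learning is out of scope — $\lambda$ values are configuration,
not trained parameters.
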