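"""Reconstruct a 32 %-sampled phantom with the CRF solver and compare to
the zero-filled least-squares baseline.

The solver starts from the zero-filled estimate, samples long-range
cliques from its magnitude, and descends the cross-domain energy
(k-space data fidelity + guided pairwise smoothness) with a
backtracking step size, so the energy trace is non-increasing.
"""

from cdsfcrf import (
    CRFConfig, SolverConfig, acquire, add_texture, generate_phantom,
    l2_reconstruct, lines_for_rate, psnr, radial_mask, reconstruct,
)

truth = add_texture(generate_phantom(128, 128, 3, 0.5, seed=0), 0.15, seed=0)
mask = radial_mask(128, 128, lines_for_rate(128, 128, 0.32))
kdata = acquire(truth.image, mask)

baseline = l2_reconstruct(kdata)
result = reconstruct(kdata, CRFConfig(seed=0), SolverConfig(max_iters=300))

print(f"sampling rate: {mask.rate:.3f}")
print(f"energy: {result.energy_trace[0]:.4f} -> {result.energy_trace[-1]:.6f} "
      f"in {result.iterations} iterations (converged={result.converged})")
print(f"PSNR zero-filled L2 : {psnr(truth.image, baseline):.2f} dB")
print(f"PSNR CRF            : {psnr(truth.image, result.image):.2f} dB")
# The CRF gains several dB by suppressing the radial streak artifacts
# the zero-filled guide exposes, while the k-space term pins the
# reconstruction to every measured frequency.
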