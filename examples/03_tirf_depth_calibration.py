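"""Calibrate the TIRF evanescent penetration depth (raisin-cake method).

Simulates 84 gold nanospheres suspended above a slightly tilted coverslip,
with an epi-illumination z-scan (for per-sphere z) and a TIRF exposure (for
per-sphere SNR), then recovers the 1/e decay length of the evanescent field.
"""

from smnd import calibrate_from_zscan, simulate_zscan_pair

dataset = simulate_zscan_pair(
    n_spheres=84,
    tilt=(1e-5, 2e-5, 300.0),       # coverslip plane z0 = a*x + b*y + c (nm)
    depth_true=50.0,                # ground-truth penetration depth, nm
    noise_sd=0.05,
    seed=0,
)
result = calibrate_from_zscan(dataset)

print(f"fitted penetration depth: {result.penetration_depth:.1f} nm "
      f"(truth {dataset.depth_true:.0f} nm)")
print(f"tilt plane (a, b, c):     ({result.plane[0]:.2e}, {result.plane[1]:.2e}, "
      f"{result.plane[2]:.1f})")
print(f"z-error width of the fit: {result.sigma_z:.1f} nm over {result.n_bins} bins")
# The depth comes from binned SNR-vs-depth data fitted with an exponential
# decay convolved with a Gaussian; ~50 nm means the field probes only the
# membrane-proximal slab of the cell.
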