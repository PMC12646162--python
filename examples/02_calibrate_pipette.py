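"""Calibrate a micropipette force sensor from hanging water droplets.

Each droplet's weight follows from its imaged radius (sphere of water);
the spring constant k is the through-origin slope of weight vs tip
deflection. A second route presses the pipette against an already
calibrated one.
"""

from trichomech import synthio, fit_droplet_calibration, two_pipette_k

series = synthio.gen_calibration_droplets(k_true=0.10, n=10, noise_frac=0.01,
                                          seed=3)
calib = fit_droplet_calibration(series["radius_um"], series["deflection_um"])

print("droplet series (first 3 rows):")
print(series.head(3).to_string(index=False))
print(f"\nfitted k      : {calib.k:.4f} +/- {calib.sigma_k:.4f} uN/um")
print(f"residual sd   : {calib.residual_sd:.3f} um over {calib.n_points} droplets")

k_cross = two_pipette_k(k_ref=calib.k, d_ref=10.0, d_unknown=5.0)
print(f"\ntwo-pipette cross-check: a pipette deflecting half as much as this")
print(f"one under the same tip force is twice as stiff: k = {k_cross:.4f} uN/um")
print("\nManufactured pipettes span k = 0.04-1.17 uN/um; the fitted")
print("uncertainty (<= 0.01 uN/um) sets the force resolution via F = k dx.")
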