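"""Fluence fidelity of the log-based reconstruction.

Simulates delivering a modulated field with realistic recording noise
(0.2 mm leaf-position jitter and 0.01 cm quantization), reconstructs the
sequence from the logs alone (actual mode), and gamma-compares the
reconstructed fluence with the true delivered fluence at 3%/3 mm.
"""

from dynaqa import (
    ErrorModel,
    compute_fluence,
    gamma_analysis,
    make_sliding_window_plan,
    reconstruct_beam,
    simulate_delivery,
)

beam = make_sliding_window_plan(1, "random", seed=1000).beams[0]
sim = simulate_delivery(beam, 300.0, ErrorModel(jitter_sd_mm=0.2), seed=2000)
recon = reconstruct_beam(sim.record, mode="actual", total_mu=beam.total_mu)

truth = compute_fluence(sim.delivered_beam)     # what the leaves really did
reconstructed = compute_fluence(recon)          # what the logs say they did
result = gamma_analysis(truth, reconstructed, dose_pct=3.0, dta_mm=3.0,
                        threshold_pct=10.0)

print(f"snapshots in log:      {len(sim.record.bank_a_log.snapshots)}")
print(f"control points found:  {len(recon.control_points)}")
print(f"gamma 3%/3 mm pass:    {result.passing_rate:.2f}% "
      f"({result.n_evaluated} pixels above the 10% threshold)")
print("-> a passing rate near 100% shows the 55 ms log stream retains "
      "the delivered fluence to within the gamma criterion.")
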