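"""Planned-mode round trip: the conversion chain's inherent accuracy.

Simulates an error-free delivery of a five-beam sliding-window plan,
reconstructs each beam from the logs using only planned positions and
fractions, and compares DVH metrics of the original and reconstructed
plans computed with the same toy dose engine.  A correct interpolation
chain leaves every metric essentially unchanged (well under 0.1%).
"""

from dynaqa import planned_mode_round_trip

result = planned_mode_round_trip(seed=1)

print("structure        dD98%    dD2%   dDmean%   (reconstructed - original)")
for name, (d98, d2, dmean) in sorted(result.metric_diffs.items()):
    print(f"{name:<12s} {d98:+9.4f} {d2:+8.4f} {dmean:+8.4f}")
print(f"\nmax |difference| over {result.n_metrics} metrics: "
      f"{result.max_abs_diff:.4f}% of the isocenter dose")
print("-> differences this small mean the log-to-sequence conversion "
      "itself adds no clinically relevant error.")
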