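"""Process one synthetic respirometry trial into resting metabolic rate.

Simulates a 2-hour 1 Hz oxygen-analyzer trace for an 85 g animal with a
known resting VO2 of 1.5 ml O2/min (at STP), including chamber washout,
sensor drift and two activity bouts per hour, then runs the full analysis
chain: two-point drift-corrected calibration -> Lighton mass balance ->
STP correction -> lowest stable 10-min window.
"""

from thermoneutral import TraceParams, extract_rmr, simulate_trace, trace_to_vo2

trace, start_cal, end_cal, truth = simulate_trace(
    resting_vo2_stp_ml_min=1.5,
    params=TraceParams(),
    duration_s=7200,
    ta_c=28.0,
    body_mass_g=85.0,
    seed=12,
)
series = trace_to_vo2(trace, start_cal, end_cal)
result = extract_rmr(series, body_mass_g=85.0)

print(f"true resting msRMR : {truth['msrmr']:.4f} ml O2 g-1 h-1")
print(f"recovered msRMR    : {result.msrmr:.4f} ml O2 g-1 h-1 "
      f"(window {result.window_start_s:.0f}-{result.window_end_s:.0f} s, "
      f"CV {result.window_cv:.3f})")
print(f"relative error     : {abs(result.msrmr / truth['msrmr'] - 1):.2%}")
print("The recovered value is the lowest stable 10-min mean after the "
      "30-min acclimation; activity bouts are avoided by the minimum.")
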