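"""Extract the seven kinetic curve parameters P1-P7 from single traces.

Profiles a noise-free sustained (CRP-like) and transient (thrombin-like)
trace.  P1 is the pre-injection baseline (= F0), P2 the maximal increase
F - F0, P3 the rise rate, P4 the peak, P5/P6 the post-peak and late-phase
slopes, and P7 the baseline-subtracted area under the curve.
"""

from calscreen import generate_trace, locate_injection, profile_trace
from calscreen.synthetic import NO_EFFECT, default_templates

for agonist, template in default_templates().items():
    trace = generate_trace(template, NO_EFFECT, template.injection_time_s, 0.0, seed=0)
    idx, _ = locate_injection(trace, template.injection_time_s)
    p = profile_trace(trace, agonist, idx)
    print(f"{agonist} ({'sustained' if template.sustained else 'transient'}):")
    print(f"  P1 baseline      {p.p1_baseline_au:10.1f} AU")
    print(f"  P2 max increase  {p.p2_max_increase_au:10.1f} AU")
    print(f"  P3 slope 1       {p.p3_slope1_au_s:10.2f} AU/s")
    print(f"  P4 peak          {p.p4_peak_au:10.1f} AU")
    print(f"  P5 slope 2       {p.p5_slope2_au_s:10.3f} AU/s")
    print(f"  P6 slope 3       {p.p6_slope3_au_s:10.3f} AU/s")
    print(f"  P7 AUC           {p.p7_auc_au_s:10.0f} AU*s")

print(
    "\nThe transient trace decays quickly after its peak (negative P5),"
    "\nwhile the sustained trace declines only partially and rises again"
    "\nlate (positive P6)."
)
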