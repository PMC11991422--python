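"""Detect compensatory co-movements and norm exceedance.

Simulates a subject who, during left lateral flexion, also rotates left —
a classic cross-plane compensation: the rotation channel receives -0.3
times the primary side-bend profile (left rotation is negative by
convention).  Normative limits are user configuration; here flexion's limit
is set below the subject's peak to show the exceedance flag.
"""

import cervitrack as ct

cfg = ct.default_protocol(
    seed=7,
    couplings={"left_lateral": {"rotation": -0.30, "flexion_extension": -0.05}},
)
stream, _ = ct.simulate_protocol(cfg)
norms = ct.NormativeRanges({"flexion": 40.0, "left_lateral": 45.0})
result = ct.analyze_stream(stream, norms=norms)

for ep in result.bundle.episodes:
    comp = ep.compensation
    if not comp.flags:
        continue
    print(f"{ep.rom.label}: primary {comp.primary_peak_deg:+.1f} deg")
    for ch, (peak, ratio) in comp.off_plane.items():
        print(f"   off-plane {ch}: peak {peak:+6.2f} deg, coupling {ratio:+.3f}")
    print(f"   flags: {comp.flags}")

# Expected output: the left_lateral episode reports a rotation co-movement
# near -10.5 deg (coupling ratio about -0.30, the injected value) and a
# co_movement flag; flexion reports norm_exceeded because its 45 deg peak
# passes the configured 40 deg limit.
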