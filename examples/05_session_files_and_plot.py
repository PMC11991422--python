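"""Session files, report export and the posturographic trajectory plot.

Writes a simulated session to its on-disk format (samples CSV with
w-first quaternion columns + metadata JSON), reads it back losslessly,
analyses it, and exports the report bundle: schema-validated JSON, a
summary CSV with one row per movement, and the trajectory plot — the
measured head trace in red over two fixed orthogonal reference lines
crossing at the calibrated neutral origin.
"""

import tempfile
from pathlib import Path

import cervitrack as ct
from cervitrack.io_report import export_report, render_trajectory_plot

out = Path(tempfile.mkdtemp(prefix="cervitrack_"))
stream, _ = ct.simulate_protocol(ct.default_protocol(seed=9))
ct.write_session(stream, ct.SessionMeta(user_id="demo", seed=9), out / "session")

back, meta = ct.read_session(out / "session")
print("lossless round trip:", (back.quat_wxyz == stream.quat_wxyz).all())

result = ct.analyze_stream(back, meta=meta)
plot_path, model = render_trajectory_plot(
    result.series, result.episodes, out / "report" / "trajectory.png"
)
result.bundle.plot_paths = [plot_path.name]
paths = export_report(result.bundle, out / "report")

print("reference lines cross at", model.reference_angle_deg(), "deg")
print("report:", paths["report"])
print((out / "report" / "summary.csv").read_text())

# The summary CSV has one row per movement (min/max/mean signed ROM and
# mean duration); with a single session min = max = mean.  The 90.0 deg
# reference-line angle is the posturographic grid geometry the trace is
# judged against.
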