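"""Build the block design for both feedback methods and write an events table.

Each run interleaves 30-s neutral blocks with 46-s emotion blocks (four
tenderness, four anguish) for 608 s = 304 volumes at TR = 2 s. The ROI
method alternates the emotions; the SVM method groups them.
"""

import tempfile
from pathlib import Path

from nfbsim import build_run_schedule, build_session_design, label_volumes, write_events

for method in ("ROI", "SVM"):
    run = build_run_schedule(method, "tenderness", run_index=1)
    order = "".join(b.condition.value[0].upper() for b in run.blocks)
    print(f"{method} run 1 block order: {order}  ({run.n_volumes} volumes, {run.total_duration_s:.0f} s)")

design = build_session_design("ROI", "tenderness")
print(f"session: {len(design.runs)} runs, {design.total_volumes} volumes total")

labels = label_volumes(design.runs[0], shift_volumes=2)
print(f"shifted labels: first 4 = {labels[:4]} (hemodynamic delay of 2 volumes)")

out = Path(tempfile.mkdtemp()) / "run-1_events.tsv"
write_events(design.runs[0], out)
print(f"events table written to {out}; first rows:")
print("\n".join(out.read_text().splitlines()[4:8]))
# N = neutral, T = tenderness, A = anguish; the counts check the design
# arithmetic: 8*30 + 8*46 = 608 s per run, 4*304 = 1,216 volumes per session.
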