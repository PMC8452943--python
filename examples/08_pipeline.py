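"""Batch pipeline: CSV inputs -> artifacts + manifest -> Markdown report.

Writes a synthetic response matrix and Q-matrix to CSV, runs every pipeline
stage (fit, classify, validate_q, itemfit, accuracy), and renders the run
report.  The manifest records input hashes, the seed and per-stage status,
so a deterministic run is reproducible byte-for-byte.
"""

import tempfile
from pathlib import Path

import numpy as np

import cdmkit as ck
from cdmkit.io import write_responses

rng = np.random.default_rng(2024)
q = ck.default_qmatrix(J=10, K=3)
profiles = ck.generate_profiles(300, 3, rng=rng)
truth = ck.generate_item_parameters(q, guess=0.1, slip=0.1, rng=rng)
X = ck.simulate_responses(truth, profiles, rng)

workdir = Path(tempfile.mkdtemp(prefix="cdmkit_demo_"))
write_responses(X, workdir / "responses.csv")
ck.write_qmatrix(q, workdir / "q.csv")

config = ck.PipelineConfig(
    responses=str(workdir / "responses.csv"),
    qmatrix=str(workdir / "q.csv"),
    out_dir=str(workdir / "out"),
    model="gdina",
    seed=1,
)
manifest = ck.run_pipeline(config)
print("stages:", {k: v["status"] for k, v in manifest["stages"].items()})
print("artifacts:", sorted(p.name for p in (workdir / "out").iterdir()))

text = ck.render_report(workdir / "out")
print("\nreport preview:")
print("\n".join(text.splitlines()[:14]))
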