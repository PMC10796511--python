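"""The file-based pipeline: simulate -> analyze -> report.

Equivalent to the shell commands

    dhinducer simulate --out study/ --seed 9 --n-markers 800
    dhinducer analyze  --in study/ --out bundle/
    dhinducer report   --bundle bundle/

Every stage writes plain TSV/CSV so any step can be re-run in isolation.
"""

import tempfile
from pathlib import Path

from dhinducer.pipeline import AnalysisParams, run_analyze, run_report, run_simulate
from dhinducer.simulate import SimConfig

with tempfile.TemporaryDirectory() as tmp:
    study_dir = Path(tmp) / "study"
    bundle_dir = Path(tmp) / "bundle"
    run_simulate(study_dir, SimConfig(n_markers=800, n_dh_per_cross=8), seed=9)
    run_analyze(study_dir, bundle_dir, AnalysisParams())
    print(run_report(bundle_dir))
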