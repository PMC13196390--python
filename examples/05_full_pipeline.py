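"""One-call reproducible pipeline run.

Simulates a study, runs every stage (differential, proximity, mechanisms,
antigens) and writes all artifacts plus a digest manifest; rerunning with the
same seed reproduces every file byte for byte.
"""

import json
import tempfile
from pathlib import Path

from pepwire import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    manifest = run_pipeline(Path(tmp) / "run", seed=1)
    print("tables written:")
    for name, meta in manifest["tables"].items():
        print(f"  {name:24s} {meta['rows']:6d} rows")
    print(f"selected kinases: {', '.join(manifest['selected_kinases'])}")
    print(f"stage order: {' -> '.join(manifest['stages'])}")
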