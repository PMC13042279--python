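"""Run every stage end to end and show the overlap between the circRNA and
linear-splicing programmes.

Equivalent to `novapipe demo --outdir scratch/demo --seed 7`. The manifest
records a SHA-256 for every output, so the same seed always reproduces the
same files.
"""

import json
from pathlib import Path

from novapipe.pipeline import RunConfig, run_pipeline

outdir = Path("scratch/demo")
manifest = run_pipeline(RunConfig(seed=7, outdir=str(outdir)))

for stage, info in manifest["stages"].items():
    print(f"{stage:8s} {info}")

venn = (outdir / "overlap_venn.tsv").read_text().strip().splitlines()
print("\ngene-level overlap (circ-only / splice-only / shared):", venn[1])
records = (outdir / "overlap_records.tsv").read_text().strip()
print(records)
print(f"\n{len(manifest['files'])} output files hashed into manifest.json; "
      "rerunning with seed 7 reproduces them bit for bit.")
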