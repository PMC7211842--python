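#!/usr/bin/env python
"""Generate the synthetic study datasets.

Writes an AFM campaign (200 good traces plus one of every defect kind) and
a 10-pull SMD ensemble under scratch/data/.  Traces are headered TSVs with
a manifest and a ground-truth sidecar; everything is reproducible from the
seed.
"""

import argparse
from pathlib import Path

from fimpull.synthetic import (
    DEFECT_KINDS,
    SMDSpec,
    SyntheticSpec,
    generate_dataset,
    generate_smd_dataset,
)
from fimpull.trace_io import DatasetManifest, ManifestEntry, write_manifest, write_trace

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-good", type=int, default=200)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "data")
    args = ap.parse_args()

    afm_dir = args.out / "afm"
    defects = {k: 1 for k in DEFECT_KINDS if k != "none"}
    manifest = generate_dataset(afm_dir, spec=SyntheticSpec(), n_good=args.n_good,
                                defect_counts=defects, master_seed=args.seed)
    print(f"AFM: wrote {len(manifest.entries)} traces "
          f"({args.n_good} good + {len(defects)} defect probes) to {afm_dir}")

    smd_dir = args.out / "smd"
    entries = []
    for i, (trace, _) in enumerate(generate_smd_dataset(SMDSpec(), 10,
                                                        master_seed=args.seed)):
        name = f"smd_{i:02d}.tsv"
        trace.metadata["source_id"] = f"smd_{i:02d}"
        write_trace(trace, smd_dir / name)
        entries.append(ManifestEntry(path=name, kind="smd"))
    write_manifest(DatasetManifest(entries=entries, notes="synthetic SMD ensemble"),
                   smd_dir / "manifest.json")
    print(f"SMD: wrote {len(entries)} pull traces to {smd_dir}")


if __name__ == "__main__":
    main()
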