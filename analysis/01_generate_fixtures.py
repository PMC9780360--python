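#!/usr/bin/env python
"""Generate the synthetic study inputs (no downloads).

Writes the complete demo bundle — toy ring octamer, rotated second state,
EX1/EX2 envelope CSV over the five labelling timepoints in two ligand
conditions, crosslink list with held-out truth labels, and a run config —
under scratch/demo/ for the downstream analysis scripts.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

from sarmdyn.workbench import make_demo  # noqa: E402


def main() -> None:
    out = ROOT / "scratch" / "demo"
    cfg_path = make_demo(out, seed=SEED)
    truth = json.loads((out / "truth.json").read_text())["labels"]
    print(f"demo bundle written to {out} (seed {SEED})")
    print(f"  config: {cfg_path}")
    print(f"  crosslinks: {len(truth)} ({sum(truth.values())} true contacts, "
          f"{len(truth) - sum(truth.values())} decoys)")
    print("  envelope conditions: NMN (fast opening), NAD (slow opening), undeut")


if __name__ == "__main__":
    main()
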