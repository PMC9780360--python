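#!/usr/bin/env python
"""Quantify the rigid-body motion between the two synthetic states.

Aligns the two states on the seven stationary protomers, measures the
residual rotation of the mobile protomer (generated with a known 30°
rigid rotation), and reports marker-atom displacements — the same
procedure used to quantify a domain swing between ligand-bound
conformations of a real assembly.
"""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from sarmdyn.motion import domain_motion, rmsd_selection  # noqa: E402
from sarmdyn.structure_io import AtomSelection, load_structure  # noqa: E402


def main() -> None:
    demo = ROOT / "scratch" / "demo"
    if not (demo / "state_b.pdb").is_file():
        raise SystemExit("run 01_generate_fixtures.py first")
    a = load_structure(demo / "ring.pdb")
    b = load_structure(demo / "state_b.pdb")
    ref = AtomSelection(chain_ids=frozenset("BCDEFGH"), atom_names=frozenset({"CA"}))
    mobile = AtomSelection(chain_ids=frozenset({"A"}), atom_names=frozenset({"CA"}))
    markers = [("A", 1, "CA"), ("A", 20, "CA"), ("A", 40, "CA")]

    dm = domain_motion(a, b, ref, mobile, markers)
    fit_rmsd = rmsd_selection(a, b, mobile)
    payload = {
        "angle_deg": dm.angle_deg,
        "ref_rmsd_a": dm.ref_rmsd,
        "mobile_fit_rmsd_a": fit_rmsd,
        "mobile_rmsd_after_ref_align_a": dm.mobile_rmsd_after_ref_align,
        "marker_displacements_a": {
            f"{c}:{r}:{n}": d for (c, r, n), d in dm.marker_displacements.items()
        },
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "motion.json").write_text(json.dumps(payload, indent=2))

    print(f"mobile protomer rotation after reference alignment: {dm.angle_deg:.3f} deg "
          "(applied: 30.000)")
    print(f"reference-protomer RMSD: {dm.ref_rmsd:.4f} A "
          f"(internal rigidity check: mobile fit-RMSD {fit_rmsd:.4f} A)")
    for key, d in payload["marker_displacements_a"].items():
        print(f"  marker {key}: displaced {d:.2f} A")


if __name__ == "__main__":
    main()
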