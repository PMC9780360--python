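"""Run configuration, pipeline orchestration, and the synthetic demo.

A single TOML file configures up to three analysis blocks — ``hdx``
(uptake, differencing, EX1 deconvolution and kinetics), ``xl``
(crosslink-to-structure mapping), and ``motion`` (superposition and
domain rotation).  Unknown keys are rejected outright so a misspelled
option can never silently fall back to a default.  Every run writes a
machine-readable manifest, even on failure.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from .errors import ConfigError, SarmdynError
from .hdx import (
    HdxConfig,
    UptakeMeasurement,
    compute_uptake,
    diff_uptake,
    fit_bimodal,
    fit_transition_kinetics,
    read_envelope_csv,
    read_peptide_csv,
    classify_bimodality,
)
from .structure_io import AtomSelection, load_structure, write_pdb
from .xlmap import (
    XlConfig,
    assignments_to_frame,
    parse_crosslinks,
    summarize,
    write_pseudobonds,
)
from .motion import domain_motion
from .synthetic import (
    SyntheticConfig,
    apply_rigid_motion,
    generate_ring_complex,
    simulate_crosslinks,
    simulate_envelope,
    simulate_ex1_series,
    write_crosslink_csv,
    write_truth_json,
)

log = logging.getLogger("sarmdyn")

_TOP_KEYS = {"output_dir", "seed", "log_level", "hdx", "xl", "motion"}
_HDX_KEYS = {
    "envelope_csv",
    "peptide_csv",
    "condition_a",
    "condition_b",
    "undeut_condition",
    "significance_threshold_da",
    "bimodal_peptides",
}
_XL_KEYS = {"crosslink_csv", "structure", "cutoff_ca_ca", "regions", "weight_by_csms"}
_MOTION_KEYS = {
    "structure_a",
    "structure_b",
    "ref_chains",
    "ref_res_range",
    "mobile_chains",
    "mobile_res_range",
    "atom_names",
    "markers",
    "chain_map",
}


@dataclass
class HdxBlock:
    envelope_csv: Path
    peptide_csv: Path
    condition_a: str
    condition_b: str
    undeut_condition: str = "undeut"
    bimodal_peptides: Optional[list[str]] = None
    config: HdxConfig = field(default_factory=HdxConfig)


@dataclass
class XlBlock:
    crosslink_csv: Path
    structure: Path
    weight_by_csms: bool = False
    config: XlConfig = field(default_factory=XlConfig)


@dataclass
class MotionBlock:
    structure_a: Path
    structure_b: Path
    ref_sel: AtomSelection = field(default_factory=AtomSelection)
    mobile_sel: AtomSelection = field(default_factory=AtomSelection)
    markers: list[tuple[str, int, str]] = field(default_factory=list)
    chain_map: dict[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    hdx: Optional[HdxBlock] = None
    xl: Optional[XlBlock] = None
    motion: Optional[MotionBlock] = None


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _require(mapping: dict, key: str, where: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required key {where}.{key}")
    return mapping[key]


def _resolve_path(base: Path, value: str, where: str) -> Path:
    p = Path(value)
    if not p.is_absolute():
        p = base / p
    if not p.is_file():
        raise ConfigError(f"{where}: file not found: {p}")
    return p


def validate_config(path: str | Path) -> RunConfig:
    """Parse and strictly validate a TOML run configuration."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"config does not parse as TOML: {exc}") from exc
    _reject_unknown(raw, _TOP_KEYS, "top level")
    base = path.parent
    out_dir = Path(raw.get("output_dir", "sarmdyn_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    cfg = RunConfig(
        output_dir=out_dir,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    if "hdx" in raw:
        block = raw["hdx"]
        _reject_unknown(block, _HDX_KEYS, "hdx")
        hdx_cfg = HdxConfig(
            significance_threshold_da=float(block.get("significance_threshold_da", 0.4))
        )
        cfg.hdx = HdxBlock(
            envelope_csv=_resolve_path(base, _require(block, "envelope_csv", "hdx"), "hdx.envelope_csv"),
            peptide_csv=_resolve_path(base, _require(block, "peptide_csv", "hdx"), "hdx.peptide_csv"),
            condition_a=str(_require(block, "condition_a", "hdx")),
            condition_b=str(_require(block, "condition_b", "hdx")),
            undeut_condition=str(block.get("undeut_condition", "undeut")),
            bimodal_peptides=list(block["bimodal_peptides"]) if "bimodal_peptides" in block else None,
            config=hdx_cfg,
        )
    if "xl" in raw:
        block = raw["xl"]
        _reject_unknown(block, _XL_KEYS, "xl")
        xl_cfg = XlConfig(cutoff_ca_ca=float(block.get("cutoff_ca_ca", 30.0)))
        if "regions" in block:
            xl_cfg.regions = {
                str(k): (int(v[0]), int(v[1])) for k, v in block["regions"].items()
            }
        cfg.xl = XlBlock(
            crosslink_csv=_resolve_path(base, _require(block, "crosslink_csv", "xl"), "xl.crosslink_csv"),
            structure=_resolve_path(base, _require(block, "structure", "xl"), "xl.structure"),
            weight_by_csms=bool(block.get("weight_by_csms", False)),
            config=xl_cfg,
        )
    if "motion" in raw:
        block = raw["motion"]
        _reject_unknown(block, _MOTION_KEYS, "motion")
        atom_names = frozenset(block.get("atom_names", ["CA"]))

        def _sel(prefix: str) -> AtomSelection:
            chains = frozenset(block.get(f"{prefix}_chains", []))
            rr = block.get(f"{prefix}_res_range")
            return AtomSelection(
                chain_ids=chains,
                res_range=(int(rr[0]), int(rr[1])) if rr else None,
                atom_names=atom_names,
            )

        markers = [
            (str(m[0]), int(m[1]), str(m[2])) for m in block.get("markers", [])
        ]
        cfg.motion = MotionBlock(
            structure_a=_resolve_path(base, _require(block, "structure_a", "motion"), "motion.structure_a"),
            structure_b=_resolve_path(base, _require(block, "structure_b", "motion"), "motion.structure_b"),
            ref_sel=_sel("ref"),
            mobile_sel=_sel("mobile"),
            markers=markers,
            chain_map={str(k): str(v) for k, v in block.get("chain_map", {}).items()},
        )
    if cfg.hdx is None and cfg.xl is None and cfg.motion is None:
        raise ConfigError("config must contain at least one analysis block (hdx, xl, motion)")
    return cfg


# ---------------------------------------------------------------------------
# block runners


def _run_hdx(block: HdxBlock, out: Path) -> dict:
    envelopes = read_envelope_csv(block.envelope_csv)
    peptides = read_peptide_csv(block.peptide_csv)
    undeut = {}
    for e in envelopes:
        if e.condition == block.undeut_condition:
            undeut.setdefault((e.peptide_id, e.charge), e)
    measurements: list[UptakeMeasurement] = []
    for e in envelopes:
        if e.condition == block.undeut_condition:
            continue
        ref = undeut.get((e.peptide_id, e.charge))
        if ref is None or e.peptide_id not in peptides:
            log.warning("no undeuterated reference or peptide entry for %s; skipped", e.peptide_id)
            continue
        measurements.append(compute_uptake(e, ref, peptides[e.peptide_id]))

    uptake_rows = [
        {
            "peptide_id": m.peptide_id,
            "condition": m.condition,
            "timepoint_s": m.timepoint_s,
            "replicate": m.replicate,
            "uptake_da": round(m.uptake_da, 4),
            "percent_d": round(m.percent_d, 2),
        }
        for m in measurements
    ]
    import pandas as pd

    pd.DataFrame(uptake_rows).to_csv(out / "uptake.tsv", sep="\t", index=False)

    cond_a = [m for m in measurements if m.condition == block.condition_a]
    cond_b = [m for m in measurements if m.condition == block.condition_b]
    diff = diff_uptake(cond_a, cond_b, block.config, peptides)
    diff.to_csv(out / "differences.tsv", sep="\t", index=False)

    # bimodal deconvolution + kinetics per condition
    targets = block.bimodal_peptides
    bimodal_rows = []
    kinetics: dict[str, dict] = {}
    by_key: dict[tuple[str, str], list] = {}
    for e in envelopes:
        if e.condition == block.undeut_condition:
            continue
        if targets is not None and e.peptide_id not in targets:
            continue
        if targets is None:
            label, _ = classify_bimodality(e)
            if label != "bimodal":
                continue
        by_key.setdefault((e.peptide_id, e.condition), []).append(e)
    for (pid, cond), env_list in sorted(by_key.items()):
        f_by_t: dict[float, list[float]] = {}
        for e in env_list:
            fit = fit_bimodal(e)
            bimodal_rows.append(
                {
                    "peptide_id": pid,
                    "condition": cond,
                    "timepoint_s": e.timepoint_s,
                    "replicate": e.replicate,
                    "mu_low": round(fit.mu_low, 4),
                    "mu_high": round(fit.mu_high, 4),
                    "sigma": round(fit.sigma, 4),
                    "f_open": round(fit.f_open, 4),
                    "converged": fit.converged,
                }
            )
            f_by_t.setdefault(e.timepoint_s, []).append(fit.f_open)
        series = sorted((t, float(np.mean(fs))) for t, fs in f_by_t.items())
        if len(series) >= 3:
            kin = fit_transition_kinetics(series)
            kinetics[f"{pid}/{cond}"] = {
                "k_open_per_s": kin.k_open,
                "f0": kin.f0,
                "f_inf": kin.f_inf,
                "rss": kin.rss,
                "n_timepoints": len(series),
            }
    pd.DataFrame(bimodal_rows).to_csv(out / "bimodal.tsv", sep="\t", index=False)
    (out / "kinetics.json").write_text(json.dumps(kinetics, indent=2))
    n_sig = int(diff["significant"].sum())
    return {
        "n_envelopes": len(envelopes),
        "n_uptake_measurements": len(measurements),
        "n_differences": len(diff),
        "n_significant": n_sig,
        "n_bimodal_fits": len(bimodal_rows),
        "kinetics": kinetics,
    }


def _run_xl(block: XlBlock, out: Path) -> dict:
    records = parse_crosslinks(block.crosslink_csv)
    structure = load_structure(block.structure)
    summary, assignments, bests = summarize(
        records, structure, block.config, weight_by_csms=block.weight_by_csms
    )
    assignments_to_frame(assignments).to_csv(out / "assignments.tsv", sep="\t", index=False)
    assignments_to_frame(bests).to_csv(out / "best_assignments.tsv", sep="\t", index=False)
    (out / "xl_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    write_pseudobonds(records, bests, out / "pseudobonds.txt")
    return summary.to_dict()


def _run_motion(block: MotionBlock, out: Path) -> dict:
    a = load_structure(block.structure_a)
    b = load_structure(block.structure_b)
    result = domain_motion(
        a, b, block.ref_sel, block.mobile_sel, block.markers, block.chain_map
    )
    payload = {
        "angle_deg": result.angle_deg,
        "screw_translation_a": result.screw_translation,
        "ref_rmsd_a": result.ref_rmsd,
        "mobile_rmsd_after_ref_align_a": result.mobile_rmsd_after_ref_align,
        "marker_displacements_a": {
            f"{c}:{r}:{n}": d for (c, r, n), d in result.marker_displacements.items()
        },
    }
    (out / "motion.json").write_text(json.dumps(payload, indent=2))
    return payload


def run_pipeline(cfg: RunConfig) -> int:
    """Execute the configured blocks (hdx, then xl, then motion).

    Returns a process exit status; the manifest is written even when a
    block fails, recording partial completion.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": cfg.seed,
        "blocks": {},
        "status": "incomplete",
    }
    status = 0
    try:
        for name, block, runner in (
            ("hdx", cfg.hdx, _run_hdx),
            ("xl", cfg.xl, _run_xl),
            ("motion", cfg.motion, _run_motion),
        ):
            if block is None:
                continue
            log.info("running %s block", name)
            try:
                manifest["blocks"][name] = {"summary": runner(block, out), "ok": True}
            except SarmdynError as exc:
                log.error("%s block failed: %s", name, exc)
                manifest["blocks"][name] = {"error": str(exc), "ok": False}
                status = 1
        manifest["status"] = "ok" if status == 0 else "partial"
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return status


# ---------------------------------------------------------------------------
# synthetic end-to-end demo


def make_demo(output_dir: str | Path, seed: int = 0) -> Path:
    """Write a complete, self-consistent synthetic input bundle.

    Emits the toy ring octamer, a second state with chain A rigidly
    rotated 30°, an envelope CSV (EX1 bimodal peptide plus an EX2-like
    unimodal control, two ligand conditions over the five labelling
    timepoints, triplicate), a crosslink CSV with truth labels, and a
    ready-to-run TOML config.  Returns the config path.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = SyntheticConfig(seed=seed)
    ring = generate_ring_complex(base)
    write_pdb(ring, out / "ring.pdb")

    mobile_sel = AtomSelection(chain_ids=frozenset({"A"}))
    moved = apply_rigid_motion(ring, mobile_sel, (0.0, 0.0, 1.0), 30.0)
    write_pdb(moved, out / "state_b.pdb")

    # two ligand conditions differing only in opening rate: the activator
    # (NMN) accelerates the closed-to-open conversion, the substrate (NAD)
    # stabilises the closed state
    conditions = {
        "NMN": SyntheticConfig(seed=seed, k_open=0.01),
        "NAD": SyntheticConfig(seed=seed, k_open=0.001, f_inf=0.6),
    }
    rng = np.random.default_rng(seed)
    envelopes = []
    for cond, ccfg in conditions.items():
        for rep in (1, 2, 3):
            envelopes.extend(
                simulate_ex1_series(
                    ccfg, peptide_id="pep_ex1", condition=cond, replicate=rep, rng=rng
                )
            )
            # EX2-like unimodal control: one subpopulation whose mean
            # uptake relaxes with the same first-order law
            for t in ccfg.timepoints:
                mean_t = 12.0 * (1.0 - np.exp(-0.002 * t)) + 2.0
                envelopes.append(
                    simulate_envelope(
                        ccfg,
                        [mean_t],
                        [1.0],
                        peptide_id="pep_ex2",
                        condition=cond,
                        timepoint_s=t,
                        replicate=rep,
                        rng=rng,
                    )
                )
    for pid in ("pep_ex1", "pep_ex2"):
        envelopes.append(
            simulate_envelope(
                base, [0.0], [1.0], peptide_id=pid, condition="undeut",
                timepoint_s=0.0, replicate=1, rng=rng,
            )
        )
    from .hdx import envelopes_to_frame

    envelopes_to_frame(envelopes).to_csv(out / "envelopes.csv", index=False)
    import pandas as pd

    pd.DataFrame(
        [
            {"peptide_id": "pep_ex1", "sequence": "A" * 21, "start": 236, "end": 256},
            {"peptide_id": "pep_ex2", "sequence": "A" * 21, "start": 300, "end": 320},
        ]
    ).to_csv(out / "peptides.csv", index=False)

    records, labels = simulate_crosslinks(ring, base, condition="NMN")
    write_crosslink_csv(records, out / "crosslinks.csv")
    write_truth_json(labels, base, out / "truth.json")

    config_text = f"""# synthetic end-to-end demo (seed {seed})
output_dir = "demo_out"
seed = {seed}

[hdx]
envelope_csv = "envelopes.csv"
peptide_csv = "peptides.csv"
condition_a = "NMN"
condition_b = "NAD"
undeut_condition = "undeut"
bimodal_peptides = ["pep_ex1"]

[xl]
crosslink_csv = "crosslinks.csv"
structure = "ring.pdb"

[motion]
structure_a = "ring.pdb"
structure_b = "state_b.pdb"
ref_chains = ["B", "C", "D", "E", "F", "G", "H"]
mobile_chains = ["A"]
markers = [["A", 1, "CA"], ["A", 40, "CA"]]
"""
    cfg_path = out / "config.toml"
    cfg_path.write_text(config_text)
    return cfg_path
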