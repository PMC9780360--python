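"""Crosslink-to-structure mapping on multimeric assemblies.

A lysine-reactive crosslinker (DSBU-class) restrains two CA atoms to lie
within roughly 30 Å, but on a homo-multimer the identification alone
cannot tell within-protomer (intra) from between-protomer (inter) links.
Each residue-pair identification is therefore enumerated over all chain
pairs of the assembly, the minimum-distance assignment is taken as the
structural interpretation, and a link counts as satisfied only when that
distance is within the cutoff **and** the straight CA-CA vector does not
pierce the protein core (a link whose vector passes directly through a
domain cannot form intramolecularly).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .structure_io import StructureModel

#: default residue-range -> domain table (construct numbering of the
#: octameric NADase: armadillo-repeat, SAM oligomerisation, TIR catalytic)
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "ARM": (60, 402),
    "SAM": (403, 549),
    "TIR": (561, 701),
}


@dataclass
class CrosslinkRecord:
    """One crosslink identification (residue pair in construct numbering)."""

    xl_id: str
    res_a: int
    res_b: int
    condition: str = ""
    n_csms: int = 1

    def __post_init__(self):
        if self.res_a > self.res_b:  # canonical order
            self.res_a, self.res_b = self.res_b, self.res_a
        if self.n_csms < 1:
            raise InputError(f"{self.xl_id}: n_csms must be >= 1")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.res_a, self.res_b)


@dataclass
class XlConfig:
    cutoff_ca_ca: float = 30.0  # Å
    inclusive_cutoff: bool = True  # satisfied iff d <= cutoff (else strict <)
    clash_probe_radius: float = 2.0  # Å
    clash_step: float = 0.5  # Å
    endpoint_margin: float = 0.10  # fraction of segment length excluded at each end
    neighbor_window: int = 1  # residues around the linked sites excluded from clash
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self):
        if self.cutoff_ca_ca <= 0:
            raise InputError("cutoff must be > 0")

    def is_satisfied_distance(self, d: float) -> bool:
        return d <= self.cutoff_ca_ca if self.inclusive_cutoff else d < self.cutoff_ca_ca


@dataclass
class XlAssignment:
    """One crosslink placed on one chain pair."""

    xl_id: str
    chain_a: str
    chain_b: str
    distance_ca_ca: float
    satisfied: bool
    topology: str  # "intra" | "inter"
    clash: bool = False
    is_best: bool = False


@dataclass
class XlSummary:
    n_records: int
    n_mapped: int
    n_unmappable: int
    n_satisfied: int
    satisfaction_fraction: Optional[float]  # percent; None when nothing mapped
    by_topology: dict[str, dict[str, int]] = field(default_factory=dict)
    by_region: dict[str, dict[str, int]] = field(default_factory=dict)
    unmappable_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_mapped": self.n_mapped,
            "n_unmappable": self.n_unmappable,
            "n_satisfied": self.n_satisfied,
            "satisfaction_fraction": self.satisfaction_fraction,
            "fraction_undefined": self.satisfaction_fraction is None,
            "by_topology": self.by_topology,
            "by_region": self.by_region,
            "unmappable_ids": self.unmappable_ids,
        }


def parse_crosslinks(path: str | Path) -> list[CrosslinkRecord]:
    """Read a crosslink CSV (columns res_a, res_b; optional xl_id,
    condition, n_csms).

    Residue pairs are put in canonical order (res_a <= res_b) and
    duplicate (pair, condition) rows are merged with summed CSM counts.
    """
    df = pd.read_csv(path)
    required = {"res_a", "res_b"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"crosslink table missing columns: {sorted(missing)}")
    merged: dict[tuple[int, int, str], dict] = {}
    order: list[tuple[int, int, str]] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            ra, rb = int(row["res_a"]), int(row["res_b"])
        except (TypeError, ValueError):
            raise InputError(
                f"non-integer residue number at line {line}: "
                f"res_a={row['res_a']!r} res_b={row['res_b']!r}"
            ) from None
        if ra > rb:
            ra, rb = rb, ra
        cond = str(row["condition"]) if "condition" in df.columns else ""
        n_csms = int(row["n_csms"]) if "n_csms" in df.columns and not pd.isna(row.get("n_csms")) else 1
        xl_id = str(row["xl_id"]) if "xl_id" in df.columns else f"xl{line - 1:03d}"
        key = (ra, rb, cond)
        if key in merged:
            merged[key]["n_csms"] += n_csms
        else:
            merged[key] = {"xl_id": xl_id, "n_csms": n_csms}
            order.append(key)
    return [
        CrosslinkRecord(
            xl_id=merged[k]["xl_id"],
            res_a=k[0],
            res_b=k[1],
            condition=k[2],
            n_csms=merged[k]["n_csms"],
        )
        for k in order
    ]


def _ca_positions(structure: StructureModel, res_num: int) -> dict[str, np.ndarray]:
    """CA coordinate of ``res_num`` in every chain where it exists."""
    out = {}
    for chain in structure.chains:
        res = chain.residue(res_num)
        if res is not None and not res.hetero:
            ca = res.atom("CA")
            if ca is not None:
                out[chain.chain_id] = ca.coords
    return out


def enumerate_assignments(
    record: CrosslinkRecord,
    structure: StructureModel,
    cfg: XlConfig | None = None,
) -> list[XlAssignment]:
    """All chain-pair placements of one crosslink.

    One assignment per canonical chain pair (chain_a <= chain_b); for a
    heterologous residue pair on distinct chains both orientations are
    evaluated and the shorter kept.  Returns an empty list when either
    residue is absent from every chain (unmappable).
    """
    cfg = cfg or XlConfig()
    pos_a = _ca_positions(structure, record.res_a)
    pos_b = _ca_positions(structure, record.res_b)
    if not pos_a or not pos_b:
        return []
    out = []
    chain_pairs = set()
    for ca in pos_a:
        for cb in pos_b:
            chain_pairs.add(tuple(sorted((ca, cb))))
    for ca, cb in sorted(chain_pairs):
        dists = []
        if ca in pos_a and cb in pos_b:
            dists.append(float(np.linalg.norm(pos_a[ca] - pos_b[cb])))
        if ca != cb and cb in pos_a and ca in pos_b:
            dists.append(float(np.linalg.norm(pos_a[cb] - pos_b[ca])))
        if ca == cb and record.res_a == record.res_b:
            continue  # a residue cannot crosslink to itself within one chain
        if not dists:
            continue
        d = min(dists)
        out.append(
            XlAssignment(
                xl_id=record.xl_id,
                chain_a=ca,
                chain_b=cb,
                distance_ca_ca=d,
                satisfied=cfg.is_satisfied_distance(d),
                topology="intra" if ca == cb else "inter",
            )
        )
    return out


def best_assignment(assignments: Sequence[XlAssignment]) -> XlAssignment:
    """Minimum-distance assignment; ties within 0.01 Å prefer intra over
    inter, then the lexicographically smallest chain pair."""
    if not assignments:
        raise InputError("no assignments to choose from")
    d_min = min(a.distance_ca_ca for a in assignments)
    candidates = [a for a in assignments if a.distance_ca_ca <= d_min + 0.01]
    best = min(
        candidates,
        key=lambda a: (0 if a.topology == "intra" else 1, a.chain_a, a.chain_b),
    )
    best.is_best = True
    return best


def line_clash(
    structure: StructureModel,
    point_a: Sequence[float],
    point_b: Sequence[float],
    exclude: set[tuple[str, int]],
    cfg: XlConfig | None = None,
) -> bool:
    """Does the straight segment between two points pierce the structure?

    The open segment is sampled at ``clash_step`` intervals with 10%
    margins at either end excluded; a clash is any heavy atom outside the
    excluded residues (the linked residues plus ``neighbor_window``
    residues on either side, on their own chains) within
    ``clash_probe_radius`` of a sample point.
    """
    cfg = cfg or XlConfig()
    pa = np.asarray(point_a, dtype=float)
    pb = np.asarray(point_b, dtype=float)
    length = float(np.linalg.norm(pb - pa))
    if length <= 0:
        raise InputError("clash segment endpoints must be distinct")
    expanded = {
        (cid, r + k)
        for cid, r in exclude
        for k in range(-cfg.neighbor_window, cfg.neighbor_window + 1)
    }
    coords = []
    for chain_id, res, atom in structure.heavy_atoms():
        if res.hetero or (chain_id, res.res_num) in expanded:
            continue
        coords.append(atom.coords)
    if not coords:
        return False
    coords = np.asarray(coords)
    t0, t1 = cfg.endpoint_margin, 1.0 - cfg.endpoint_margin
    n_steps = max(int(np.ceil((t1 - t0) * length / cfg.clash_step)), 1)
    ts = np.linspace(t0, t1, n_steps + 1)
    samples = pa[None, :] + ts[:, None] * (pb - pa)[None, :]
    # min distance from any atom to any sample point
    d2 = ((coords[:, None, :] - samples[None, :, :]) ** 2).sum(axis=2)
    return bool(d2.min() < cfg.clash_probe_radius**2)


def _region_of(res_num: int, regions: Mapping[str, tuple[int, int]]) -> str:
    for name, (lo, hi) in regions.items():
        if lo <= res_num <= hi:
            return name
    return "other"


def _clash_for_best(
    structure: StructureModel,
    record: CrosslinkRecord,
    best: XlAssignment,
    cfg: XlConfig,
) -> bool:
    pos_a = _ca_positions(structure, record.res_a)
    pos_b = _ca_positions(structure, record.res_b)
    # reconstruct the orientation that realised the best distance
    options = []
    if best.chain_a in pos_a and best.chain_b in pos_b:
        options.append((pos_a[best.chain_a], pos_b[best.chain_b], best.chain_a, best.chain_b))
    if best.chain_a != best.chain_b and best.chain_b in pos_a and best.chain_a in pos_b:
        options.append((pos_a[best.chain_b], pos_b[best.chain_a], best.chain_b, best.chain_a))
    pa, pb, ca, cb = min(
        options, key=lambda o: float(np.linalg.norm(o[0] - o[1]))
    )
    exclude = {(ca, record.res_a), (cb, record.res_b)}
    return line_clash(structure, pa, pb, exclude, cfg)


def summarize(
    records: Iterable[CrosslinkRecord],
    structure: StructureModel,
    cfg: XlConfig | None = None,
    weight_by_csms: bool = False,
) -> tuple[XlSummary, list[XlAssignment], list[XlAssignment]]:
    """Map every record, pick best assignments, and tally satisfaction.

    A record is satisfied when its best (minimum-distance) assignment is
    within the cutoff and its CA-CA vector is clash-free.  Returns the
    summary plus all enumerated assignments and the per-record best
    assignments.  The satisfaction fraction counts unique residue pairs
    by default; ``weight_by_csms`` weights by spectral evidence instead.
    """
    cfg = cfg or XlConfig()
    records = list(records)
    all_assignments: list[XlAssignment] = []
    bests: list[XlAssignment] = []
    unmappable: list[str] = []
    n_mapped = n_satisfied = 0
    w_mapped = w_satisfied = 0.0
    by_topology: dict[str, dict[str, int]] = {}
    by_region: dict[str, dict[str, int]] = {}
    for rec in records:
        assignments = enumerate_assignments(rec, structure, cfg)
        all_assignments.extend(assignments)
        if not assignments:
            unmappable.append(rec.xl_id)
            continue
        best = best_assignment(assignments)
        best.clash = _clash_for_best(structure, rec, best, cfg)
        satisfied = best.satisfied and not best.clash
        bests.append(best)
        n_mapped += 1
        w_mapped += rec.n_csms
        if satisfied:
            n_satisfied += 1
            w_satisfied += rec.n_csms
        topo = by_topology.setdefault(best.topology, {"mapped": 0, "satisfied": 0})
        topo["mapped"] += 1
        topo["satisfied"] += int(satisfied)
        region_pair = "-".join(
            sorted((_region_of(rec.res_a, cfg.regions), _region_of(rec.res_b, cfg.regions)))
        )
        reg = by_region.setdefault(region_pair, {"mapped": 0, "satisfied": 0})
        reg["mapped"] += 1
        reg["satisfied"] += int(satisfied)
    if weight_by_csms:
        fraction = 100.0 * w_satisfied / w_mapped if w_mapped > 0 else None
    else:
        fraction = 100.0 * n_satisfied / n_mapped if n_mapped > 0 else None
    summary = XlSummary(
        n_records=len(records),
        n_mapped=n_mapped,
        n_unmappable=len(unmappable),
        n_satisfied=n_satisfied,
        satisfaction_fraction=fraction,
        by_topology=by_topology,
        by_region=by_region,
        unmappable_ids=unmappable,
    )
    return summary, all_assignments, bests


def condition_specific(
    records_a: Iterable[CrosslinkRecord],
    records_b: Iterable[CrosslinkRecord],
) -> list[CrosslinkRecord]:
    """Records of ``a`` whose residue pair never appears in ``b``."""
    pairs_b = {r.pair for r in records_b}
    return [r for r in records_a if r.pair not in pairs_b]


def assignments_to_frame(assignments: Iterable[XlAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "xl_id": a.xl_id,
                "chain_a": a.chain_a,
                "chain_b": a.chain_b,
                "distance_ca_ca": round(a.distance_ca_ca, 3),
                "satisfied": a.satisfied,
                "topology": a.topology,
                "clash": a.clash,
                "is_best": a.is_best,
            }
            for a in assignments
        ]
    )


def write_pseudobonds(
    records: Sequence[CrosslinkRecord],
    bests: Sequence[XlAssignment],
    path: str | Path,
) -> None:
    """Molecular-graphics pseudo-bond list: one ``chain:res-chain:res`` per line."""
    by_id = {r.xl_id: r for r in records}
    lines = []
    for b in bests:
        rec = by_id[b.xl_id]
        lines.append(f"{b.chain_a}:{rec.res_a}-{b.chain_b}:{rec.res_b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
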