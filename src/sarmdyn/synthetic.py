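"""Seeded generators for every fixture the pipeline consumes.

Emulated features of the real study design:

* EX1 isotopic envelopes — a mixture of a low-mass ("closed") and a
  high-mass ("open") deuteration subpopulation whose mixing weight
  relaxes exponentially in labelling time, plus EX2-like unimodal
  controls.  Each subpopulation is a binomial per-site deuteration
  distribution convolved with a coarse 3-peak natural-isotope profile
  and a Gaussian instrument peak shape.
* A ring-shaped toy octamer of identical protomers for crosslink
  mapping, with lysine-rich chains long enough that residue pairs on
  opposite ends violate the distance restraint even within one chain.
* Crosslink lists mixing true contacts (within the cutoff, with margin)
  and decoys (beyond it, with margin), with truth labels kept separate.
* State pairs related by a known rigid-body motion of one selection, the
  ground truth for rotation-angle and displacement recovery.

Every generator is a pure function of its configuration, including the
seed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .hdx import (
    DEUTERIUM_INCREMENT_DA,
    PROTON_MASS_DA,
    SpectrumEnvelope,
)
from .structure_io import (
    Atom,
    AtomSelection,
    Chain,
    Residue,
    StructureModel,
    list_crosslinkable_sites,
    resolve_selection,
)

#: spacing of adjacent natural-isotope peaks, Da
ISOTOPE_SPACING_DA = 1.0033548

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with the defaults used throughout.

    The HDX defaults mirror the experimental design: five labelling
    timepoints from 10 s to 30 min, a ~20-amide peptide, triplicate-level
    multiplicative intensity noise of a few percent, charge 2.
    """

    seed: int = 0
    # ring assembly
    n_protomers: int = 8
    ring_radius: float = 40.0  # Å, protomer reference point to ring axis
    # envelope simulation
    n_exchangeable: int = 20
    peak_sigma: float = 0.4  # Da, instrument Gaussian width on the mass axis
    intensity_noise_cv: float = 0.02
    charge: int = 2
    base_mass: float = 800.0  # Da, undeuterated monoisotopic neutral mass
    # EX1 interconversion
    k_open: float = 0.005  # 1/s
    f0: float = 0.05
    f_inf: float = 0.9
    timepoints: tuple[float, ...] = (10.0, 30.0, 60.0, 300.0, 1800.0)
    # crosslink sampling
    n_true: int = 8
    n_decoy: int = 2
    distance_noise_sd: float = 1.0  # Å, safety margin scale around the cutoff

    def __post_init__(self):
        if self.n_protomers < 1:
            raise InputError("n_protomers must be >= 1")
        if min(self.n_true, self.n_decoy) < 0 or self.n_exchangeable < 0:
            raise InputError("counts must be >= 0")
        if self.charge < 1:
            raise InputError("charge must be >= 1")
        if len(self.timepoints) and np.any(np.diff(self.timepoints) <= 0):
            raise InputError("timepoints must be strictly increasing")


# ---------------------------------------------------------------------------
# structures

_TEMPLATE_N_RES = 40
_LYSINE_EVERY = 4  # residues 4, 8, ..., 40 are lysines
_HELIX_RADIUS = 2.3  # Å
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue


def _template_coords() -> np.ndarray:
    """CA trace of one protomer: residue 1 at the local origin (the ring
    placement reference), the rest an idealised helix rising along z."""
    coords = np.zeros((_TEMPLATE_N_RES, 3))
    for i in range(1, _TEMPLATE_N_RES):
        ang = math.radians(_HELIX_TWIST * i)
        coords[i] = (
            _HELIX_RADIUS * math.cos(ang),
            _HELIX_RADIUS * math.sin(ang),
            _HELIX_RISE * i,
        )
    return coords


def generate_ring_complex(cfg: SyntheticConfig) -> StructureModel:
    """A toy C_n ring of identical lysine-rich protomers.

    The protomer template is translated so that residue 1's CA sits
    exactly at ``ring_radius`` from the ring (z) axis, then copies are
    placed by rotating the template by 360/n degrees per protomer;
    chains are labelled A, B, C, ...
    """
    if cfg.n_protomers > len(_CHAIN_IDS):
        raise InputError(f"at most {len(_CHAIN_IDS)} protomers supported")
    template = _template_coords() + np.array([cfg.ring_radius, 0.0, 0.0])
    model = StructureModel(id=f"synthetic-ring-{cfg.n_protomers}")
    for k in range(cfg.n_protomers):
        theta = 2 * math.pi * k / cfg.n_protomers
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        coords = template @ rot.T
        chain = Chain(chain_id=_CHAIN_IDS[k])
        for i in range(_TEMPLATE_N_RES):
            res_num = i + 1
            name = "LYS" if res_num % _LYSINE_EVERY == 0 else "ALA"
            chain.residues.append(
                Residue(
                    res_num=res_num,
                    insertion_code="",
                    res_name=name,
                    atoms=[Atom(name="CA", element="C", coords=coords[i].copy())],
                )
            )
        model.chains.append(chain)
    return model


def apply_rigid_motion(
    structure: StructureModel,
    sel: AtomSelection,
    axis: Sequence[float],
    angle_deg: float,
    translation: Sequence[float] = (0.0, 0.0, 0.0),
) -> StructureModel:
    """Rotate the selected atoms about ``axis`` through their centroid, then translate.

    All other atoms are unchanged; intra-selection distances are preserved
    exactly (rigid motion).
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise InputError("rotation axis must have unit norm")
    translation = np.asarray(translation, dtype=float)
    resolved = resolve_selection(structure, sel)
    selected = {a.key for a in resolved.atoms}
    centroid = resolved.coords.mean(axis=0)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)

    out = structure.copy()
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                key = (chain.chain_id, res.res_num, res.insertion_code, atom.name)
                if key in selected:
                    atom.coords = rot.apply(atom.coords - centroid) + centroid + translation
    return out


# ---------------------------------------------------------------------------
# isotopic envelopes


def _isotope_profile(base_mass: float) -> np.ndarray:
    """Coarse averagine-like 3-peak profile; heavier peptides carry more
    heavy-isotope intensity (geometric ratio grows with nominal mass)."""
    r = min(max(5.5e-4 * base_mass, 0.01), 0.95)
    w = np.array([1.0, r, r * r])
    return w / w.sum()


def _binomial_pmf(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def _subpop_envelope(
    grid: np.ndarray, cfg: SyntheticConfig, mean_uptake: float
) -> np.ndarray:
    """Noiseless, unit-sum envelope of one deuteration subpopulation."""
    n = cfg.n_exchangeable
    p = mean_uptake / (n * DEUTERIUM_INCREMENT_DA) if n > 0 else 0.0
    if not -1e-9 <= p <= 1 + 1e-9:
        raise InputError(
            f"subpopulation mean {mean_uptake} Da outside [0, "
            f"{n * DEUTERIUM_INCREMENT_DA:.3f}] Da"
        )
    p = min(max(p, 0.0), 1.0)
    pmf = _binomial_pmf(n, p)
    iso = _isotope_profile(cfg.base_mass)
    y = np.zeros_like(grid)
    for k in range(n + 1):
        if pmf[k] < 1e-12:
            continue
        for j, wj in enumerate(iso):
            mu = cfg.base_mass + k * DEUTERIUM_INCREMENT_DA + j * ISOTOPE_SPACING_DA
            y += pmf[k] * wj * np.exp(-0.5 * ((grid - mu) / cfg.peak_sigma) ** 2)
    total = y.sum()
    if total <= 0:
        raise InputError("degenerate envelope (no intensity on grid)")
    return y / total


def _mass_grid(cfg: SyntheticConfig) -> np.ndarray:
    lo = cfg.base_mass - 4.0
    hi = (
        cfg.base_mass
        + cfg.n_exchangeable * DEUTERIUM_INCREMENT_DA
        + 2 * ISOTOPE_SPACING_DA
        + 4.0
    )
    step = max(cfg.peak_sigma / 4.0, 0.02)
    return np.arange(lo, hi + step, step)


def simulate_envelope(
    cfg: SyntheticConfig,
    subpop_means: Sequence[float],
    subpop_weights: Sequence[float],
    *,
    peptide_id: str = "pep1",
    condition: str = "synthetic",
    timepoint_s: float = 0.0,
    replicate: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> SpectrumEnvelope:
    """Mixture isotopic envelope of deuteration subpopulations.

    Each subpopulation is normalised to unit summed intensity before
    mixing, so the noiseless mixture is exactly the pointwise weighted sum
    of the pure envelopes and totals 1.  Multiplicative Gaussian intensity
    noise with coefficient of variation ``intensity_noise_cv`` is applied
    last.  The m/z axis is ``(mass + z*m_proton)/z``.
    """
    weights = np.asarray(subpop_weights, dtype=float)
    if len(weights) != len(subpop_means):
        raise InputError("subpop_means and subpop_weights must have equal length")
    if np.any(weights < 0):
        raise InputError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InputError(f"weights must sum to 1 (got {weights.sum():.12f})")
    grid = _mass_grid(cfg)
    y = np.zeros_like(grid)
    for mean, w in zip(subpop_means, weights):
        if w > 0:
            y += w * _subpop_envelope(grid, cfg, mean)
    if cfg.intensity_noise_cv > 0:
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        factors = 1.0 + cfg.intensity_noise_cv * rng.standard_normal(len(y))
        y = y * np.clip(factors, 0.0, None)
    mz = (grid + cfg.charge * PROTON_MASS_DA) / cfg.charge
    return SpectrumEnvelope(
        peptide_id=peptide_id,
        condition=condition,
        timepoint_s=timepoint_s,
        replicate=replicate,
        charge=cfg.charge,
        mz=mz,
        intensity=y,
    )


def ex1_open_fraction(cfg: SyntheticConfig, t: float) -> float:
    """Open-subpopulation weight at labelling time t (first-order relaxation)."""
    return cfg.f_inf - (cfg.f_inf - cfg.f0) * math.exp(-cfg.k_open * t)


def simulate_ex1_series(
    cfg: SyntheticConfig,
    subpop_means: tuple[float, float] = (4.0, 16.0),
    *,
    peptide_id: str = "pep1",
    condition: str = "synthetic",
    replicate: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> list[SpectrumEnvelope]:
    """EX1 time series: envelopes whose open-state weight follows
    ``f(t) = f_inf - (f_inf - f0)*exp(-k_open*t)`` at the configured
    timepoints."""
    if not cfg.timepoints:
        raise InputError("no timepoints configured")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = []
    for t in cfg.timepoints:
        f = ex1_open_fraction(cfg, t)
        out.append(
            simulate_envelope(
                cfg,
                subpop_means,
                (1.0 - f, f),
                peptide_id=peptide_id,
                condition=condition,
                timepoint_s=t,
                replicate=replicate,
                rng=rng,
            )
        )
    return out


# ---------------------------------------------------------------------------
# crosslinks


def simulate_crosslinks(
    structure: StructureModel,
    cfg: SyntheticConfig,
    cutoff: float = 30.0,
    condition: str = "synthetic",
):
    """Sample true-contact and decoy crosslink records on a structure.

    True records are residue pairs whose minimum CA-CA distance over all
    chain-pair assignments is at most ``cutoff - 2*distance_noise_sd``
    and whose shortest assignment is clash-free; decoys have minimum
    distance beyond ``cutoff + 2*distance_noise_sd``.  The margins make
    the downstream satisfied/violated classification reproduce the truth
    labels exactly.  Returns ``(records, labels)`` with labels kept
    separate (xl_id -> True for true contacts).
    """
    from .xlmap import CrosslinkRecord, XlConfig, line_clash

    sites = list_crosslinkable_sites(structure)
    if len(sites) < 2:
        raise InputError("structure has fewer than 2 crosslinkable sites")
    xl_cfg = XlConfig(cutoff_ca_ca=cutoff)
    # CA position of every (chain, res) site
    pos: dict[tuple[str, int], np.ndarray] = {}
    for chain_id, res_num in sites:
        res = structure.chain(chain_id).residue(res_num)
        pos[(chain_id, res_num)] = res.atom("CA").coords
    res_nums = sorted({r for _, r in sites})

    def min_assignment(a: int, b: int):
        best = None
        for (ca, ra), pa in pos.items():
            if ra != a:
                continue
            for (cb, rb), pb in pos.items():
                if rb != b or (ca == cb and ra == rb):
                    continue
                d = float(np.linalg.norm(pa - pb))
                if best is None or d < best[0]:
                    best = (d, pa, pb, ca, cb)
        return best

    margin = 2.0 * cfg.distance_noise_sd
    true_pool, decoy_pool = [], []
    for a, b in itertools.combinations(res_nums, 2):
        found = min_assignment(a, b)
        if found is None:
            continue
        d, pa, pb, ca, cb = found
        if d <= cutoff - margin:
            exclude = {(ca, a), (cb, b)}
            if not line_clash(structure, pa, pb, exclude, xl_cfg):
                true_pool.append((a, b))
        elif d > cutoff + margin:
            decoy_pool.append((a, b))

    if len(true_pool) < cfg.n_true:
        raise InputError(
            f"only {len(true_pool)} true-contact pairs available, need {cfg.n_true}"
        )
    if len(decoy_pool) < cfg.n_decoy:
        raise InputError(
            f"only {len(decoy_pool)} decoy pairs available, need {cfg.n_decoy}"
        )
    rng = np.random.default_rng(cfg.seed)
    chosen_true = [true_pool[i] for i in rng.choice(len(true_pool), cfg.n_true, replace=False)]
    chosen_decoy = [
        decoy_pool[i] for i in rng.choice(len(decoy_pool), cfg.n_decoy, replace=False)
    ]
    records, labels = [], {}
    for i, ((a, b), is_true) in enumerate(
        [(p, True) for p in chosen_true] + [(p, False) for p in chosen_decoy], start=1
    ):
        xl_id = f"xl{i:03d}"
        records.append(
            CrosslinkRecord(xl_id=xl_id, res_a=a, res_b=b, condition=condition)
        )
        labels[xl_id] = is_true
    return records, labels


# ---------------------------------------------------------------------------
# fixture writers


def write_crosslink_csv(records, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "xl_id": r.xl_id,
                "protein": "synthetic",
                "res_a": r.res_a,
                "res_b": r.res_b,
                "condition": r.condition,
                "n_csms": r.n_csms,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_truth_json(labels: dict, cfg: SyntheticConfig, path: str | Path) -> None:
    payload = {"config": asdict(cfg), "labels": labels}
    Path(path).write_text(json.dumps(payload, indent=2))
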