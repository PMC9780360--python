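"""Structure reading, writing, and atom selection.

Atomic models (PDB or mmCIF) are parsed with gemmi into a light-weight
in-memory representation indexed by author chain id, author residue number,
and insertion code — the addressing used throughout the crosslink-mapping
and superposition stages.  Alternate locations are collapsed to a single
conformer on load and hydrogens are never used in geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import EmptySelectionError, EmptyStructureError, InputError

#: canonical backbone ordering; any other atom name sorts after these,
#: alphabetically.
_BACKBONE_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3}

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _atom_sort_key(name: str) -> tuple:
    return (_BACKBONE_ORDER.get(name, 4), name)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    res_num: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.res_name in _WATER_NAMES


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, res_num: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.res_num == res_num and r.insertion_code == insertion_code:
                return r
        return None

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.hetero]


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for ch in self.chains:
            for res in ch.residues:
                for a in res.atoms:
                    yield ch.chain_id, res, a

    def heavy_atoms(self) -> list[tuple[str, Residue, Atom]]:
        return [(c, r, a) for c, r, a in self.iter_atoms() if not a.is_hydrogen]

    def copy(self) -> "StructureModel":
        chains = []
        for ch in self.chains:
            residues = []
            for r in ch.residues:
                atoms = [replace(a, coords=a.coords.copy()) for a in r.atoms]
                residues.append(replace(r, atoms=atoms))
            chains.append(Chain(ch.chain_id, residues))
        return StructureModel(self.id, chains)


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom selection.

    Empty ``chain_ids`` means all chains; ``res_range=None`` means all
    residue numbers; empty ``atom_names`` means every heavy atom.
    """

    chain_ids: frozenset[str] = frozenset()
    res_range: Optional[tuple[int, int]] = None
    atom_names: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "chain_ids", frozenset(self.chain_ids))
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if self.res_range is not None:
            start, end = self.res_range
            if start > end:
                raise InputError(f"res_range start {start} > end {end}")


@dataclass(frozen=True)
class AtomRef:
    """One resolved atom with its full address."""

    chain_id: str
    res_num: int
    insertion_code: str
    res_name: str
    atom_name: str
    coords: np.ndarray

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.res_num, self.insertion_code, self.atom_name)


@dataclass
class ResolvedSelection:
    atoms: list[AtomRef]
    skipped: list[tuple[str, int, str, tuple[str, ...]]]  # (chain, res, icode, missing names)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.atoms)


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, then smallest altloc id."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def load_structure(
    path: str | Path,
    format: str = "auto",
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Altlocs are collapsed (highest occupancy wins, ties by smallest altloc
    id), waters and other non-polymer entities are retained but flagged
    ``hetero``, and only one model is kept (``model_index``, default the
    first) for multi-model files.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"structure file not found: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise InputError(f"unknown structure format: {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"could not parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    if model_index >= len(st):
        raise InputError(
            f"model index {model_index} out of range; file has {len(st)} model(s)"
        )
    gm = st[model_index]

    model = StructureModel(id=st.name or path.stem)
    n_polymer_atoms = 0
    for gchain in gm:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            hetero = gres.het_flag == "H" or gres.name in _WATER_NAMES
            res = Residue(
                res_num=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                res_name=gres.name,
                hetero=hetero,
            )
            raw = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                    occupancy=float(ga.occ),
                    altloc=(ga.altloc or "\x00").replace("\x00", ""),
                )
                for ga in gres
            ]
            res.atoms = _resolve_altlocs(raw)
            if not np.all(np.isfinite([a.coords for a in res.atoms])):
                raise InputError(
                    f"non-finite coordinates in {path} at {gchain.name}/{gres.seqid.num}"
                )
            if not hetero:
                n_polymer_atoms += len(res.atoms)
            chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if n_polymer_atoms == 0:
        raise EmptyStructureError(f"no polymer atoms in {path}")
    return model


_ELEMENT_GUESS = {"CA": "C", "N": "N", "C": "C", "O": "O", "CB": "C", "S": "S"}


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a fixed-width PDB file (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.res_name
            gr.seqid = gemmi.SeqId(res.res_num, res.insertion_code or " ")
            gr.het_flag = "H" if res.hetero else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or _ELEMENT_GUESS.get(a.name, "C"))
                ga.pos = gemmi.Position(*[float(x) for x in a.coords])
                ga.occ = float(a.occupancy)
                if a.altloc:
                    ga.altloc = a.altloc
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.write_pdb(str(path))


def resolve_selection(structure: StructureModel, sel: AtomSelection) -> ResolvedSelection:
    """Resolve a selection to a deterministic, ordered atom list.

    Atoms are ordered by (chain_id, res_num, insertion_code, backbone-first
    atom-name order N < CA < C < O < others).  Residues in range that lack a
    requested atom contribute what they have and are recorded in
    ``skipped``.  Hetero residues and hydrogens are never selected.
    """
    chains = sorted(structure.chains, key=lambda c: c.chain_id)
    atoms: list[AtomRef] = []
    skipped: list[tuple[str, int, str, tuple[str, ...]]] = []
    want = sel.atom_names
    for chain in chains:
        if sel.chain_ids and chain.chain_id not in sel.chain_ids:
            continue
        residues = sorted(
            chain.polymer_residues(), key=lambda r: (r.res_num, r.insertion_code)
        )
        for res in residues:
            if sel.res_range is not None and not (
                sel.res_range[0] <= res.res_num <= sel.res_range[1]
            ):
                continue
            present = {a.name: a for a in res.atoms if not a.is_hydrogen}
            if want:
                names = [n for n in sorted(want, key=_atom_sort_key) if n in present]
                missing = tuple(sorted(set(want) - set(names), key=_atom_sort_key))
                if missing:
                    skipped.append(
                        (chain.chain_id, res.res_num, res.insertion_code, missing)
                    )
            else:
                names = sorted(present, key=_atom_sort_key)
            for n in names:
                atoms.append(
                    AtomRef(
                        chain_id=chain.chain_id,
                        res_num=res.res_num,
                        insertion_code=res.insertion_code,
                        res_name=res.res_name,
                        atom_name=n,
                        coords=present[n].coords,
                    )
                )
    if not atoms:
        raise EmptySelectionError(f"selection matched no atoms: {sel}")
    return ResolvedSelection(atoms=atoms, skipped=skipped)


def list_crosslinkable_sites(structure: StructureModel) -> list[tuple[str, int]]:
    """Residues a lysine-reactive crosslinker can label.

    Returns every lysine plus each chain's first polymer residue (the
    protein N-terminal primary amine), restricted to residues with a CA
    atom present.
    """
    sites: list[tuple[str, int]] = []
    for chain in structure.chains:
        poly = chain.polymer_residues()
        if not poly:
            continue
        seen: set[int] = set()
        first = poly[0]
        if first.atom("CA") is not None:
            sites.append((chain.chain_id, first.res_num))
            seen.add(first.res_num)
        for res in poly:
            if res.res_name != "LYS" or res.res_num in seen:
                continue
            if res.atom("CA") is None:
                warnings.warn(
                    f"lysine {chain.chain_id}/{res.res_num} lacks a CA atom; "
                    "excluded from crosslinkable sites"
                )
                continue
            sites.append((chain.chain_id, res.res_num))
            seen.add(res.res_num)
    return sites
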