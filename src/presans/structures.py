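"""Minimal multi-chain structure model, PDB I/O and rigid-body fitting.

The pipeline only needs coordinates, atom identities and a per-chain
deuteration label, so structures are stored as flat parallel arrays rather
than a full crystallographic hierarchy.  PDB files are read and written
through :mod:`gemmi`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "ParseError",
    "Structure",
    "AtomSelection",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "superpose",
    "rmsd_between",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclasses.dataclass
class Structure:
    """A multi-chain structure: parallel per-atom arrays plus chain metadata.

    ``deuteration`` maps chain id to the fraction of non-exchangeable
    hydrogens carrying deuterium (0 for a protonated chain).
    """

    chain_order: list[str]
    chain_id: np.ndarray  # (n,) str
    res_id: np.ndarray  # (n,) int
    res_name: np.ndarray  # (n,) str
    atom_name: np.ndarray  # (n,) str
    element: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float, aangstroem
    is_hetatm: np.ndarray  # (n,) bool
    deuteration: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        declared = set(self.chain_order)
        present = set(np.unique(self.chain_id))
        if not present <= declared:
            raise ValueError(f"atoms reference undeclared chains: {present - declared}")
        for cid, frac in self.deuteration.items():
            if cid not in declared:
                raise ValueError(f"deuteration map names unknown chain {cid!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"deuteration fraction for chain {cid!r} outside [0,1]: {frac}")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def chain_deuteration(self, chain: str) -> float:
        return self.deuteration.get(chain, 0.0)

    def copy(self) -> "Structure":
        return Structure(
            list(self.chain_order),
            self.chain_id.copy(),
            self.res_id.copy(),
            self.res_name.copy(),
            self.atom_name.copy(),
            self.element.copy(),
            self.coords.copy(),
            self.is_hetatm.copy(),
            dict(self.deuteration),
        )

    def atom_index(self, chain: str, resid: int, atom: str) -> int:
        hit = np.flatnonzero(
            (self.chain_id == chain) & (self.res_id == resid) & (self.atom_name == atom)
        )
        if hit.size == 0:
            raise KeyError(f"atom {chain}/{resid}/{atom} not found")
        return int(hit[0])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chains: Iterable[str] | None = None) -> "Structure":
        """Apply x -> R x + t, optionally to a subset of chains only."""
        out = self.copy()
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        if chains is None:
            mask = np.ones(self.n_atoms, dtype=bool)
        else:
            mask = np.isin(self.chain_id, list(chains))
        out.coords[mask] = out.coords[mask] @ rotation.T + translation
        return out


class AtomSelection:
    """A named predicate over (chain id, residue number, atom name, residue name).

    Applying a selection returns atom indices in the structure's own atom
    order, so two structures with identical topology yield paired lists.
    HETATM records are excluded from the named selections.
    """

    def __init__(self, predicate: Callable[[str, int, str, str], bool],
                 name: str = "custom", chains: Iterable[str] | None = None):
        self._predicate = predicate
        self.name = name
        self._chains = frozenset(chains) if chains is not None else None

    def __repr__(self) -> str:  # pragma: no cover
        return f"AtomSelection({self.name!r})"

    @classmethod
    def backbone(cls, chains: Iterable[str] | None = None) -> "AtomSelection":
        return cls(lambda c, r, a, rn: a in BACKBONE_ATOMS, "backbone", chains)

    @classmethod
    def cb(cls, chains: Iterable[str] | None = None) -> "AtomSelection":
        return cls(lambda c, r, a, rn: a == "CB", "CB", chains)

    @classmethod
    def methyl_carbon(cls, chains: Iterable[str] | None = None) -> "AtomSelection":
        from .tables import METHYL_CARBONS

        def pred(c: str, r: int, a: str, rn: str) -> bool:
            return a in METHYL_CARBONS.get(rn, ())

        return cls(pred, "methyl-carbon", chains)

    @classmethod
    def all_atoms(cls, chains: Iterable[str] | None = None) -> "AtomSelection":
        return cls(lambda c, r, a, rn: True, "all", chains)

    def indices(self, structure: Structure) -> np.ndarray:
        idx = []
        for i in range(structure.n_atoms):
            if structure.is_hetatm[i]:
                continue
            cid = str(structure.chain_id[i])
            if self._chains is not None and cid not in self._chains:
                continue
            if self._predicate(cid, int(structure.res_id[i]),
                               str(structure.atom_name[i]), str(structure.res_name[i])):
                idx.append(i)
        return np.asarray(idx, dtype=np.intp)

    def keys(self, structure: Structure) -> list[tuple[str, int, str]]:
        idx = self.indices(structure)
        return [
            (str(structure.chain_id[i]), int(structure.res_id[i]), str(structure.atom_name[i]))
            for i in idx
        ]


# ---------------------------------------------------------------------------
# PDB I/O


def _validate_pdb_text(path: Path) -> int:
    """Pre-scan a PDB file; returns the ATOM/HETATM record count.

    Raises :class:`ParseError` with a line number for malformed coordinate
    fields, since downstream parsing must be able to point at the offence.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise ParseError(
                        f"{path}: malformed coordinate field on line {lineno}"
                    ) from None
    return n


def _structure_from_gemmi(model: gemmi.Model, deuteration: dict[str, float]) -> Structure:
    chain_order: list[str] = []
    cid, rid, rname, aname, elem, xyz, het = [], [], [], [], [], [], []
    for chain in model:
        if chain.name not in chain_order:
            chain_order.append(chain.name)
        for residue in chain:
            # altloc policy: keep the highest-occupancy location per atom
            # name; ties resolve to the first encountered.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > prev.occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                cid.append(chain.name)
                rid.append(residue.seqid.num)
                rname.append(residue.name)
                aname.append(name)
                elem.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                het.append(residue.het_flag == "H")
    return Structure(
        chain_order,
        np.asarray(cid, dtype=object),
        np.asarray(rid, dtype=int),
        np.asarray(rname, dtype=object),
        np.asarray(aname, dtype=object),
        np.asarray(elem, dtype=object),
        np.asarray(xyz, dtype=float).reshape(len(xyz), 3),
        np.asarray(het, dtype=bool),
        dict(deuteration),
    )


def read_structure(path: str | Path, deuteration_map: dict[str, float] | None = None) -> Structure:
    """Read the first model of a PDB file.

    ``deuteration_map`` attaches a per-chain deuteration fraction; chains it
    names must exist in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if _validate_pdb_text(path) == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise ParseError(f"{path}: {exc}") from exc
    return _structure_from_gemmi(st[0], deuteration_map or {})


def read_ensemble(path: str | Path, deuteration_map: dict[str, float] | None = None) -> list[Structure]:
    """Read every MODEL of a (possibly multi-model) PDB file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if _validate_pdb_text(path) == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    st = gemmi.read_pdb(str(path))
    return [_structure_from_gemmi(model, deuteration_map or {}) for model in st]


def _gemmi_from_structure(structure: Structure, model_num: int = 1) -> gemmi.Model:
    model = gemmi.Model(model_num)
    for cname in structure.chain_order:
        mask = structure.chain_id == cname
        if not mask.any():
            continue
        # gemmi's add_residue/add_chain copy their argument, so each level
        # must be fully built before being appended.
        groups: list[tuple[tuple[int, str, bool], list[int]]] = []
        for i in np.flatnonzero(mask):
            key = (int(structure.res_id[i]), str(structure.res_name[i]),
                   bool(structure.is_hetatm[i]))
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(int(i))
        chain = gemmi.Chain(cname)
        for (rid, rname, het), idx in groups:
            residue = gemmi.Residue()
            residue.seqid = gemmi.SeqId(rid, " ")
            residue.name = rname
            residue.het_flag = "H" if het else "A"
            for i in idx:
                atom = gemmi.Atom()
                atom.name = str(structure.atom_name[i])
                el = str(structure.element[i])
                atom.element = gemmi.Element(el if el else "X")
                atom.pos = gemmi.Position(*structure.coords[i])
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    return model


def write_structure(structure: Structure, path: str | Path) -> None:
    st = gemmi.Structure()
    st.add_model(_gemmi_from_structure(structure))
    st.setup_entities()
    st.write_pdb(str(path))


def write_ensemble(structures: Sequence[Structure], path: str | Path) -> None:
    st = gemmi.Structure()
    for k, s in enumerate(structures, start=1):
        st.add_model(_gemmi_from_structure(s, model_num=k))
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Superposition and RMSD


def _paired_coordinates(mobile: Structure, reference: Structure,
                        selection: AtomSelection) -> tuple[np.ndarray, np.ndarray]:
    km = selection.keys(mobile)
    kr = selection.keys(reference)
    if km != kr:
        raise ValueError(
            f"selection {selection.name!r} does not pair identically: "
            f"{len(km)} vs {len(kr)} atoms or mismatched identities"
        )
    if len(km) < 3:
        raise ValueError(f"selection {selection.name!r} yields {len(km)} atoms; need >= 3")
    return mobile.coords[selection.indices(mobile)], reference.coords[selection.indices(reference)]


def _kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form least-squares rigid fit; reflections are forbidden."""
    cm = mobile_xyz.mean(axis=0)
    cr = reference_xyz.mean(axis=0)
    x = mobile_xyz - cm
    y = reference_xyz - cr
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("selection atoms are collinear; rotation is underdetermined")
    u, _, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    corr = np.diag([1.0, 1.0, d])
    rotation = (u @ corr @ vt).T
    translation = cr - rotation @ cm
    fitted = x @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def superpose(mobile: Structure, reference: Structure,
              selection: AtomSelection) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t with R x_mobile + t ~ x_ref.

    Returns (rotation, translation, rmsd over the selection).
    """
    xm, xr = _paired_coordinates(mobile, reference, selection)
    return _kabsch(xm, xr)


def rmsd_between(a: Structure, b: Structure, fit_selection: AtomSelection,
                 measure_selection: AtomSelection | None = None) -> float:
    """Superpose b onto a over ``fit_selection``, measure RMSD over
    ``measure_selection`` (defaults to the fit selection)."""
    rotation, translation, fit_rmsd = superpose(b, a, fit_selection)
    if measure_selection is None:
        return fit_rmsd
    mb, ma = _paired_coordinates(b, a, measure_selection)
    moved = mb @ rotation.T + translation
    return float(np.sqrt(np.mean(np.sum((moved - ma) ** 2, axis=1))))
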