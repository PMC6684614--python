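"""Coarse-grained contrast-matched SANS back-calculation and consensus scoring.

Model curves are computed on a one-bead-per-residue representation: each
bead sits on the C-alpha and carries the residue's excess neutron
scattering length, which depends on the chain's growth deuteration, the
buffer D2O fraction (through both the exchangeable hydrogens and the
excluded-solvent term) and the residue volume.  Orientationally averaged
intensities follow from the Debye formula

    I(q) = sum_i sum_j b_i b_j sin(q r_ij) / (q r_ij),

candidate structures are fitted to each measured curve with a free scale
factor (reduced chi^2), and per-dataset chi^2 values are min-max normalised
across the candidate set so a consensus fitness -- the sum of normalised
chi^2 over datasets -- can rank structures against several contrast
conditions at once.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import tables
from .structures import Structure

__all__ = [
    "LabelingScheme",
    "ScatteringBeads",
    "SANSCurve",
    "bead_model",
    "debye_intensity",
    "guinier_rg",
    "chi2_fit",
    "normalize_chi2_set",
    "consensus_fitness",
    "read_sans_curve",
    "write_sans_curve",
]


@dataclasses.dataclass(frozen=True)
class LabelingScheme:
    """Deuteration design of one SANS sample.

    ``deuteration`` maps chain id -> fraction of non-exchangeable H
    replaced by D (growth labelling); ``f_d2o`` is the buffer D2O fraction;
    exchangeable hydrogens equilibrate with the buffer with the given
    efficiency.
    """

    deuteration: tuple[tuple[str, float], ...]
    f_d2o: float
    exchange_efficiency: float = 0.9
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_d2o <= 1.0:
            raise ValueError(f"f_d2o must be in [0,1], got {self.f_d2o}")
        for cid, frac in self.deuteration:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"deuteration for chain {cid!r} outside [0,1]: {frac}")
        if not 0.0 <= self.exchange_efficiency <= 1.0:
            raise ValueError("exchange efficiency must be in [0,1]")

    @classmethod
    def make(cls, deuteration: dict[str, float], f_d2o: float,
             exchange_efficiency: float = 0.9, name: str = "") -> "LabelingScheme":
        return cls(tuple(sorted(deuteration.items())), f_d2o, exchange_efficiency, name)

    def chain_fraction(self, chain: str) -> float:
        return dict(self.deuteration).get(chain, 0.0)


@dataclasses.dataclass
class ScatteringBeads:
    """One bead per residue: position (A) and excess scattering length (fm)."""

    xyz: np.ndarray  # (n, 3)
    b: np.ndarray  # (n,)
    chain: np.ndarray  # (n,) str
    resid: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, float).reshape(-1, 3)
        self.b = np.asarray(self.b, float).reshape(-1)
        if len(self.xyz) != len(self.b):
            raise ValueError("positions and scattering lengths must pair")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("scattering lengths must be finite")


@dataclasses.dataclass
class SANSCurve:
    """Scattering intensity versus momentum transfer.

    q in 1/A (strictly ascending, q = 0 allowed as first point), I and
    sigma in the same arbitrary units.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    scheme: LabelingScheme | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be strictly positive where present")
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and I must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly ascending")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")


def bead_model(structure: Structure, scheme: LabelingScheme) -> ScatteringBeads:
    """Residue beads at C-alpha positions with contrast-dependent lengths.

    Residues lacking a C-alpha fall back to their geometric centre.
    Unknown residue names are an error (the composition table is the
    contract for what can be scattered).
    """
    xyz, b, chains, resids = [], [], [], []
    # group atoms by (chain, resid) preserving order
    seen: dict[tuple[str, int], list[int]] = {}
    for i in range(structure.n_atoms):
        if structure.is_hetatm[i]:
            continue
        seen.setdefault((str(structure.chain_id[i]), int(structure.res_id[i])), []).append(i)
    for (cid, rid), idx in seen.items():
        names = [str(structure.atom_name[i]) for i in idx]
        rname = str(structure.res_name[idx[0]])
        if rname.upper() not in tables.RESIDUES:
            raise KeyError(f"residue {rname!r} ({cid}{rid}) not in composition table")
        if "CA" in names:
            pos = structure.coords[idx[names.index("CA")]]
        else:
            pos = structure.coords[idx].mean(axis=0)
        b.append(tables.residue_scattering_length(
            rname, scheme.chain_fraction(cid), scheme.f_d2o, scheme.exchange_efficiency))
        xyz.append(pos)
        chains.append(cid)
        resids.append(rid)
    if not xyz:
        raise ValueError("structure contains no residues to bead")
    return ScatteringBeads(np.array(xyz), np.array(b),
                           np.asarray(chains, object), np.asarray(resids, int))


def debye_intensity(beads: ScatteringBeads, q_grid: np.ndarray,
                    scheme: LabelingScheme | None = None) -> SANSCurve:
    """Orientationally averaged intensity by the Debye formula.

    The self terms and the q -> 0 limit (sinc -> 1) are handled
    analytically, so I(0) = (sum b)^2 exactly.
    """
    q = np.asarray(q_grid, float)
    if len(beads.b) == 0:
        raise ValueError("empty bead list")
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    self_term = float((beads.b**2).sum())
    n = len(beads.b)
    if n == 1:
        return SANSCurve(q, np.full_like(q, self_term), scheme=scheme)
    d = pdist(beads.xyz)  # condensed i<j distances
    iu = np.triu_indices(n, k=1)
    bb = 2.0 * beads.b[iu[0]] * beads.b[iu[1]]
    # sinc(x) in numpy is sin(pi x)/(pi x); handles x=0 and the q=0 row.
    x = np.outer(q, d) / np.pi
    intensity = self_term + np.sinc(x) @ bb
    return SANSCurve(q, intensity, scheme=scheme)


def contrast_weighted_rg(beads: ScatteringBeads) -> float:
    """Direct second-moment radius of gyration, sqrt(sum b (r-rbar)^2 / sum b).

    Only meaningful for all-positive (or all-negative) contrast.
    """
    w = beads.b
    total = w.sum()
    if total == 0:
        raise ValueError("zero net scattering length")
    centre = (w[:, None] * beads.xyz).sum(axis=0) / total
    r2 = ((beads.xyz - centre) ** 2).sum(axis=1)
    val = (w * r2).sum() / total
    if val < 0:
        raise ValueError("negative apparent Rg^2 (mixed contrast)")
    return float(np.sqrt(val))


def guinier_rg(curve: SANSCurve, qrg_max: float = 1.3, max_iter: int = 20) -> float:
    """Radius of gyration from the low-q Guinier slope of ln I vs q^2.

    The fitting window is chosen iteratively so that q*Rg <= ``qrg_max``.
    """
    mask0 = (curve.q > 0) & (curve.intensity > 0)
    q = curve.q[mask0]
    intensity = curve.intensity[mask0]
    sigma = curve.sigma[mask0] if curve.sigma is not None else None
    if len(q) < 5:
        raise ValueError("no valid Guinier window: need >= 5 positive-I points")
    n_window = len(q)
    rg = None
    for _ in range(max_iter):
        qq = q[:n_window]
        ii = intensity[:n_window]
        w = None if sigma is None else (ii / sigma[:n_window]) ** 2  # ln-space weights
        coeff = np.polyfit(qq**2, np.log(ii), 1, w=w)
        slope = coeff[0]
        if slope >= 0:
            raise ValueError("no valid Guinier window: non-decaying low-q intensity")
        rg_new = float(np.sqrt(-3.0 * slope))
        keep = int(np.searchsorted(q, qrg_max / rg_new, side="right"))
        if keep < 5:
            raise ValueError("no valid Guinier window: fewer than 5 points at q*Rg <= "
                             f"{qrg_max}")
        if keep == n_window and rg is not None and abs(rg_new - rg) < 1e-9:
            return rg_new
        converged = keep == n_window
        n_window, rg = keep, rg_new
        if converged:
            return rg_new
    return float(rg)


def chi2_fit(calc: SANSCurve, exp: SANSCurve,
             fit_background: bool = False) -> tuple[float, float]:
    """Reduced chi^2 of a calculated curve against data with a fitted scale.

    The calculated curve is linearly interpolated onto the experimental q
    grid; the scale c minimising sum(((I_exp - c*I_calc)/sigma)^2) has a
    closed form.  With ``fit_background`` a flat additive term is fitted
    too (then the denominator is N-2).
    """
    if exp.sigma is None:
        raise ValueError("experimental curve must carry errors")
    n = len(exp.q)
    if n < 2:
        raise ValueError("need >= 2 experimental points")
    icalc = np.interp(exp.q, calc.q, calc.intensity)
    if np.allclose(icalc, 0.0):
        raise ValueError("calculated curve is identically zero")
    w = 1.0 / exp.sigma**2
    if not fit_background:
        c = float((w * exp.intensity * icalc).sum() / (w * icalc**2).sum())
        resid = (exp.intensity - c * icalc) / exp.sigma
        return float((resid**2).sum() / (n - 1)), c
    a = np.vstack([icalc / exp.sigma, 1.0 / exp.sigma]).T
    y = exp.intensity / exp.sigma
    sol, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ sol
    return float((resid**2).sum() / (n - 2)), float(sol[0])


def normalize_chi2_set(values: Sequence[float]) -> np.ndarray:
    """Min-max normalisation of chi^2 across structures for one dataset:

        chi2_norm = (chi2 - chi2_min) / (chi2_max - chi2_min)

    An all-equal set maps to zeros with a warning.
    """
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need >= 2 chi2 values to normalise")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("all chi2 values equal; normalised set is all zeros", stacklevel=2)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def consensus_fitness(per_dataset_norms: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Sum of normalised chi^2 across datasets for each structure (lower = better).

    Input is a (structures x datasets) matrix; a ragged or incomplete
    matrix is an error.
    """
    try:
        mat = np.asarray(per_dataset_norms, dtype=float)
    except (ValueError, TypeError):
        raise ValueError("normalised chi2 matrix is ragged or non-numeric") from None
    if mat.ndim != 2:
        raise ValueError(f"expected a structures x datasets matrix, got ndim={mat.ndim}")
    if np.any(np.isnan(mat)):
        raise ValueError("normalised chi2 matrix has missing cells")
    return mat.sum(axis=1)


# ---------------------------------------------------------------------------
# Curve file I/O: whitespace 3-column text (q, I, sigma), '#' comments.


def read_sans_curve(path: str | Path, q_units: str = "A") -> SANSCurve:
    """Read a 3-column (q, I, sigma) text curve; ``q_units`` 'A' or 'nm'."""
    path = Path(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (q, I)")
    q = data[:, 0]
    if q_units == "nm":
        q = q / 10.0
    elif q_units != "A":
        raise ValueError(f"unknown q units {q_units!r}; use 'A' or 'nm'")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SANSCurve(q, data[:, 1], sigma, name=path.stem)


def write_sans_curve(curve: SANSCurve, path: str | Path, header: str = "") -> None:
    path = Path(path)
    sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q(1/A)  I  sigma\n")
        for qi, ii, si in zip(curve.q, curve.intensity, sigma):
            fh.write(f"{qi:.6e} {ii:.6e} {si:.6e}\n")
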