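"""Synthetic study generator: toy complexes, decoy ensembles, PRE peak
tables, relaxation series and contrast-variation SANS curves with a known
ground truth.

Every generator is a pure function of its parameters and seed, so any
generated dataset can be regenerated bit-identically.  The defaults mimic
a methyl-PRE / contrast-matched SANS study of a multi-chain complex: a
ring of pseudo-helical chains, a nitroxide-like tag with an 81 ns
electron-nucleus correlation time measured at 850 MHz, spectral noise of a
few percent of the diamagnetic peak height, and SANS curves with 3%
Gaussian counting noise at the deuteration/D2O combinations used for
contrast matching (protonated, 70%-deuterated or perdeuterated chains in
0%, 42% or 100% D2O).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .pre import (
    K_SOLOMON_BLOEMBERGEN,
    PREPhysics,
    PRERecord,
    TagSite,
    distance_to_gamma2,
    intensity_ratio_model,
)
from .sans import LabelingScheme, SANSCurve, bead_model, debye_intensity
from .structures import AtomSelection, Structure, write_structure

__all__ = [
    "default_physics",
    "make_toy_complex",
    "make_decoys",
    "default_tag_site",
    "simulate_pre_gamma2",
    "simulate_pre_dataset",
    "simulate_relaxation_table",
    "simulate_sans",
    "generate_study",
    "DELAYS_DIAHC",
    "DELAYS_DIAH",
    "DEFAULT_Q_GRID",
]

#: Relaxation delay grids (s) for the double-quantum and single-quantum series.
DELAYS_DIAHC = np.array([0.0, 2.0, 4.0, 7.0, 10.0, 13.0, 20.0]) * 1e-3
DELAYS_DIAH = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 13.0, 16.0]) * 1e-3

#: Default SANS momentum-transfer grid, 1/A.
DEFAULT_Q_GRID = np.linspace(0.01, 0.30, 48)


def default_physics(**overrides) -> PREPhysics:
    """Physics used for synthetic ground truths.

    tau_c = 81 ns at an 850 MHz field, with the standard nitroxide
    Solomon-Bloembergen constant so that quantifiable rates correspond to
    the usual 10-25 A methyl PRE window.
    """
    kw = dict(tau_hmqc=7.7e-3, tau_c=81e-9, omega=2 * np.pi * 850e6,
              K=K_SOLOMON_BLOEMBERGEN)
    kw.update(overrides)
    return PREPhysics(**kw)


# ---------------------------------------------------------------------------
# Structures


def make_toy_complex(n_chains: int = 3, residues_per_chain: int = 30,
                     seed: int = 0, ring_radius: float | None = None) -> Structure:
    """A ring of rigid pseudo-helical chains around a central cavity.

    Every residue is an isoleucine stub carrying backbone N/CA/C/O, a
    C-beta and one methyl carbon (CD1), which is all the downstream stages
    touch.  Deterministic for a given (parameters, seed).
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains")
    if residues_per_chain < 4:
        raise ValueError("need at least 4 residues per chain")
    rng = np.random.default_rng(seed)
    radius = ring_radius if ring_radius is not None else 10.0 + 2.0 * max(0, n_chains - 3)
    helix_r = 2.3
    rise = 1.5
    twist = np.deg2rad(100.0)

    cid, rid, rname, aname, elem, xyz, het = [], [], [], [], [], [], []
    chain_ids = [chr(ord("A") + k) for k in range(n_chains)]
    for k, cname in enumerate(chain_ids):
        phi = 2.0 * np.pi * k / n_chains
        centre = np.array([radius * np.cos(phi), radius * np.sin(phi), 0.0])
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(residues_per_chain):
            theta = phase + i * twist
            z = (i - (residues_per_chain - 1) / 2.0) * rise
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])
            tang = np.array([-np.sin(theta), np.cos(theta), 0.0])
            ca = centre + helix_r * radial + np.array([0.0, 0.0, z])
            # methyls and C-betas face the ring interior, where the
            # inter-chain interface (and the tag) lives
            outward = -centre / np.linalg.norm(centre)
            atoms = {
                "N": (ca - 0.9 * tang + np.array([0, 0, -0.6]), "N"),
                "CA": (ca, "C"),
                "C": (ca + 0.9 * tang + np.array([0, 0, 0.6]), "C"),
                "O": (ca + 0.9 * tang + 1.2 * radial + np.array([0, 0, 0.6]), "O"),
                "CB": (ca + 1.5 * outward, "C"),
                "CD1": (ca + 3.2 * outward + np.array([0, 0, 0.4]), "C"),
            }
            for name in ("N", "CA", "C", "O", "CB", "CD1"):
                pos, el = atoms[name]
                cid.append(cname)
                rid.append(i + 1)
                rname.append("ILE")
                aname.append(name)
                elem.append(el)
                xyz.append(pos + rng.normal(0.0, 0.05, 3))
                het.append(False)
    return Structure(
        chain_ids,
        np.asarray(cid, object), np.asarray(rid, int), np.asarray(rname, object),
        np.asarray(aname, object), np.asarray(elem, object),
        np.asarray(xyz, float), np.asarray(het, bool),
    )


def make_decoys(truth: Structure, n: int, displacement_scale: float,
                rotation_scale_deg: float, mobile_chains: Sequence[str],
                seed: int = 0, include_truth: bool = False) -> tuple[list[Structure], list[str]]:
    """Rigid-body perturbations of the mobile chains around the true pose.

    Each decoy translates the mobile subunit along a uniformly random
    direction by a magnitude drawn uniformly in [0.5, 1.5] x
    ``displacement_scale`` (A), and rotates it about a random axis through
    its centroid by an angle of uniformly drawn magnitude in [0.5, 1.5] x
    ``rotation_scale_deg`` with random sense -- mimicking the spread of
    rigid-body docking candidates around a pose without piling decoys onto
    the true solution.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    mobile = list(mobile_chains)
    if not mobile:
        raise ValueError("mobile chain set must be non-empty")
    rng = np.random.default_rng(seed)
    out: list[Structure] = []
    ids: list[str] = []
    if include_truth:
        out.append(truth.copy())
        ids.append("0")
    mask = np.isin(truth.chain_id, mobile)
    if not mask.any():
        raise ValueError(f"mobile chains {mobile} not present in structure")
    centroid = truth.coords[mask].mean(axis=0)
    for k in range(n):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = direction * displacement_scale * rng.uniform(0.5, 1.5)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rotation_scale_deg * rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0]))
        kmat = np.array([[0, -axis[2], axis[1]],
                         [axis[2], 0, -axis[0]],
                         [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(angle) * kmat + (1 - np.cos(angle)) * kmat @ kmat
        decoy = truth.copy()
        decoy.coords[mask] = (decoy.coords[mask] - centroid) @ rot.T + centroid + t
        out.append(decoy)
        ids.append(str(len(ids)))
    return out, ids


def default_tag_site(structure: Structure, chain: str, resid: int,
                     cloud_points: int = 1, seed: int = 0) -> TagSite:
    """Tag site anchored at a residue's C-beta.

    With one cloud point the electron sits 6 A beyond the C-beta, pointing
    away from the complex centroid the way a solvent-exposed nitroxide
    tether does; with more points, a seeded 5-9 A shell cloud.
    """
    idx = structure.atom_index(chain, resid, "CB")
    cb = structure.coords[idx]
    if cloud_points == 1:
        direction = cb - structure.coords.mean(axis=0)
        direction /= np.linalg.norm(direction)
        return TagSite.single_point(chain, resid, cb, cb + 6.0 * direction)
    return TagSite.shell_cloud(chain, resid, cb, n_points=cloud_points, seed=seed)


# ---------------------------------------------------------------------------
# PRE data


def _methyl_ids_and_xyz(structure: Structure,
                        chains: Sequence[str] | None = None) -> tuple[list[tuple[str, int, str]], np.ndarray]:
    sel = AtomSelection.methyl_carbon(chains=chains)
    keys = sel.keys(structure)
    xyz = structure.coords[sel.indices(structure)]
    return keys, xyz


def simulate_pre_gamma2(structure: Structure, tag: TagSite, physics: PREPhysics,
                        noise_frac: float = 0.0, seed: int = 0,
                        chains: Sequence[str] | None = None) -> list[PRERecord]:
    """Ground-truth PRE rates for every methyl carbon, optionally noisy.

    Gamma2 follows from the <r^-6>-averaged tag-cloud distance through the
    Solomon-Bloembergen relation; fractional Gaussian noise is applied
    multiplicatively with sigma_Gamma = noise_frac * Gamma2(true).
    """
    keys, xyz = _methyl_ids_and_xyz(structure, chains)
    if not keys:
        raise ValueError("structure has no methyl carbons")
    rng = np.random.default_rng(seed)
    d_eff = tag.r6_average_distance(xyz)
    out = []
    for mid, d in zip(keys, d_eff):
        g_true = distance_to_gamma2(float(d), physics)
        sigma = noise_frac * g_true
        g_obs = max(g_true + rng.normal(0.0, sigma), 1e-3) if noise_frac > 0 else g_true
        out.append(PRERecord(mid, ratio=np.nan, sigma_ratio=np.nan, gamma2=g_obs,
                             sigma_gamma2=sigma if sigma > 0 else 0.1 * g_true,
                             distance=float(d), klass="quantitative"))
    return out


def simulate_pre_dataset(structure: Structure, tag: TagSite, physics: PREPhysics,
                         r2h_range: tuple[float, float] = (40.0, 70.0),
                         r2hc_range: tuple[float, float] = (60.0, 100.0),
                         noise_frac: float = 0.02, seed: int = 0,
                         chains: Sequence[str] | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full synthetic PRE experiment: peak table + relaxation series + truth.

    For each methyl the true intensity ratio follows from Gamma2 and the
    per-methyl diamagnetic rates; volumes and line-widths are drawn so that
    heights reproduce the ratios; additive Gaussian spectral noise of
    ``noise_frac`` times the mean diamagnetic height perturbs both heights.
    Returns (peak table, relaxation table, ground-truth record).
    """
    keys, xyz = _methyl_ids_and_xyz(structure, chains)
    if not keys:
        raise ValueError("no methyl carbons found (is the tag site outside the structure?)")
    rng = np.random.default_rng(seed)
    d_eff = tag.r6_average_distance(xyz)
    n = len(keys)
    r2h = rng.uniform(*r2h_range, n)
    r2hc = rng.uniform(*r2hc_range, n)
    lwh_dia = rng.uniform(18.0, 25.0, n)
    lwc_dia = rng.uniform(25.0, 35.0, n)
    v_dia = rng.uniform(800.0, 1200.0, n)
    i_dia = v_dia / (lwh_dia * lwc_dia)
    gamma2 = np.array([distance_to_gamma2(float(d), physics) for d in d_eff])
    ratio = intensity_ratio_model(gamma2, r2h, r2hc, physics.tau_hmqc)
    # paramagnetic line broadening shows up in the 1H width
    lwh_para = lwh_dia + gamma2 / np.pi
    lwc_para = lwc_dia.copy()
    i_para = ratio * i_dia

    sigma = noise_frac * float(i_dia.mean())
    if noise_frac > 0:
        i_para_obs = i_para + rng.normal(0.0, sigma, n)
        i_dia_obs = i_dia + rng.normal(0.0, sigma, n)
    else:
        i_para_obs, i_dia_obs = i_para, i_dia

    peaks = pd.DataFrame({
        "methyl_id": [pio.methyl_id_str(m) for m in keys],
        "chain": [m[0] for m in keys],
        "resid": [m[1] for m in keys],
        "atom": [m[2] for m in keys],
        "V_para": i_para_obs * lwh_para * lwc_para,
        "LWH_para": lwh_para,
        "LWC_para": lwc_para,
        "sigma_para": sigma,
        "V_dia": i_dia_obs * lwh_dia * lwc_dia,
        "LWH_dia": lwh_dia,
        "LWC_dia": lwc_dia,
        "sigma_dia": sigma,
    })
    relax = simulate_relaxation_table(keys, r2h, r2hc, noise_frac=0.0, seed=seed + 1)
    truth = {
        "tag": {"chain": tag.chain, "resid": tag.resid},
        "tau_c_s": physics.tau_c,
        "K_cm6_s2": physics.K,
        "omega_rad_s": physics.omega,
        "tau_hmqc_s": physics.tau_hmqc,
        "noise_frac": noise_frac,
        "seed": seed,
        "methyls": {
            pio.methyl_id_str(m): {
                "distance_A": float(d), "gamma2_s": float(g), "ratio": float(r),
                "R2_diaH": float(a), "R2_diaHC": float(b),
            }
            for m, d, g, r, a, b in zip(keys, d_eff, gamma2, ratio, r2h, r2hc)
        },
    }
    return peaks, relax, truth


def simulate_relaxation_table(keys: Sequence[tuple[str, int, str]],
                              r2h: np.ndarray, r2hc: np.ndarray,
                              amplitude: float = 100.0, noise_frac: float = 0.0,
                              seed: int = 0) -> pd.DataFrame:
    """Mono-exponential decay series on the standard delay grids."""
    rng = np.random.default_rng(seed)
    rows = []
    for mid, rh, rhc in zip(keys, r2h, r2hc):
        for kind, delays, rate in (("diaH", DELAYS_DIAH, rh), ("diaHC", DELAYS_DIAHC, rhc)):
            h = amplitude * np.exp(-rate * delays)
            if noise_frac > 0:
                h = h + rng.normal(0.0, noise_frac * amplitude, len(h))
            for t, hh in zip(delays, h):
                rows.append((pio.methyl_id_str(mid), kind, t, hh))
    return pd.DataFrame(rows, columns=pio.RELAX_COLUMNS)


# ---------------------------------------------------------------------------
# SANS data


def simulate_sans(structure: Structure, scheme: LabelingScheme,
                  q_grid: np.ndarray | None = None, noise_frac: float = 0.03,
                  seed: int = 0) -> SANSCurve:
    """Noisy SANS curve from the bead-model Debye intensity.

    sigma = noise_frac * |I|, floored at 1e-6 * I(0); Gaussian perturbation.
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, float)
    beads = bead_model(structure, scheme)
    calc = debye_intensity(beads, q, scheme)
    i0 = float(beads.b.sum()) ** 2
    sigma = np.maximum(noise_frac * np.abs(calc.intensity), 1e-6 * max(i0, 1.0))
    rng = np.random.default_rng(seed)
    noisy = calc.intensity + (rng.normal(0.0, 1.0, len(q)) * sigma if noise_frac > 0 else 0.0)
    return SANSCurve(q, noisy, sigma, scheme=scheme, name=scheme.name or "sans")


# ---------------------------------------------------------------------------
# Whole-study generation (CLI `simulate`)


def generate_study(outdir: str | Path, n_chains: int = 3, residues_per_chain: int = 30,
                   n_decoys: int = 99, displacement_scale: float = 20.0,
                   rotation_scale_deg: float = 45.0, tag_resid: int | None = None,
                   pre_noise_frac: float = 0.02, sans_noise_frac: float = 0.03,
                   seed: int = 0) -> dict:
    """Write a self-contained synthetic study directory.

    Contents: complex.pdb (ground truth), decoys/*.pdb + manifest.csv,
    pre_peaks.csv, relaxation.csv, sans_<scheme>.dat, truth.json.  The tag
    sits on the first chain; the last chain is the mobile docking subunit.
    The two SANS contrasts make one chain nearly solvent-matched each, the
    standard contrast-variation design.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "decoys").mkdir(exist_ok=True)
    physics = default_physics()
    truth_structure = make_toy_complex(n_chains, residues_per_chain, seed=seed)
    write_structure(truth_structure, outdir / "complex.pdb")
    chains = truth_structure.chain_order
    mobile = [chains[-1]]
    tag_resid = tag_resid if tag_resid is not None else residues_per_chain // 2
    tag = default_tag_site(truth_structure, chains[0], tag_resid)

    peaks, relax, pre_truth = simulate_pre_dataset(
        truth_structure, tag, physics, noise_frac=pre_noise_frac, seed=seed,
        chains=mobile)
    pio.write_peak_table(peaks, outdir / "pre_peaks.csv")
    pio.write_relaxation_table(relax, outdir / "relaxation.csv")

    decoys, ids = make_decoys(truth_structure, n_decoys, displacement_scale,
                              rotation_scale_deg, mobile, seed=seed + 1,
                              include_truth=True)
    manifest = []
    for sid, d in zip(ids, decoys):
        p = outdir / "decoys" / f"decoy_{sid}.pdb"
        write_structure(d, p)
        manifest.append((sid, str(p.relative_to(outdir))))
    pd.DataFrame(manifest, columns=["structure_id", "path"]).to_csv(
        outdir / "manifest.csv", index=False)

    schemes = [
        LabelingScheme.make({c: (1.0 if c != mobile[0] else 0.0) for c in chains},
                            f_d2o=0.42, name="dVps_42"),
        LabelingScheme.make({c: 1.0 for c in chains}, f_d2o=0.0, name="dAll_0"),
    ]
    from .sans import write_sans_curve
    sans_files = []
    for k, scheme in enumerate(schemes):
        curve = simulate_sans(truth_structure, scheme, noise_frac=sans_noise_frac,
                              seed=seed + 100 + k)
        p = outdir / f"sans_{scheme.name}.dat"
        write_sans_curve(curve, p, header=f"scheme {scheme.name} f_d2o {scheme.f_d2o}")
        sans_files.append({"name": scheme.name, "path": p.name,
                           "f_d2o": scheme.f_d2o,
                           "deuteration": dict(scheme.deuteration)})

    truth = {
        "seed": seed,
        "n_chains": n_chains,
        "residues_per_chain": residues_per_chain,
        "mobile_chains": mobile,
        "reference_chains": [c for c in chains if c not in mobile],
        "displacement_scale_A": displacement_scale,
        "rotation_scale_deg": rotation_scale_deg,
        "sans_noise_frac": sans_noise_frac,
        "sans_datasets": sans_files,
        "pre": pre_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
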