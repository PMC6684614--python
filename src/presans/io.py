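"""Tabular file formats: peak tables, relaxation series, restraint lists.

A methyl id is written as ``chain:resid:atom`` (e.g. ``B:17:CD1``) wherever
it appears as a single CSV column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pre import DistanceRestraint, PeakQuantification, PREPhysics, RelaxationSeries

PEAK_COLUMNS = [
    "methyl_id", "chain", "resid", "atom",
    "V_para", "LWH_para", "LWC_para", "sigma_para",
    "V_dia", "LWH_dia", "LWC_dia", "sigma_dia",
]
RELAX_COLUMNS = ["methyl_id", "kind", "delay_s", "height"]


def methyl_id_str(methyl_id: tuple[str, int, str]) -> str:
    return f"{methyl_id[0]}:{methyl_id[1]}:{methyl_id[2]}"


def parse_methyl_id(s: str) -> tuple[str, int, str]:
    chain, resid, atom = s.split(":")
    return chain, int(resid), atom


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peak table missing columns {sorted(missing)}")
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=PEAK_COLUMNS)


def peak_pairs(df: pd.DataFrame) -> list[tuple[tuple[str, int, str], PeakQuantification, PeakQuantification]]:
    """Yield (methyl id, paramagnetic, diamagnetic) quantifications."""
    out = []
    for _, row in df.iterrows():
        mid = (str(row["chain"]), int(row["resid"]), str(row["atom"]))
        para = PeakQuantification(row["V_para"], row["LWH_para"], row["LWC_para"],
                                  row["sigma_para"])
        dia = PeakQuantification(row["V_dia"], row["LWH_dia"], row["LWC_dia"],
                                 row["sigma_dia"])
        out.append((mid, para, dia))
    return out


def read_relaxation_table(path: str | Path) -> dict[tuple[str, int, str], dict[str, RelaxationSeries]]:
    """Relaxation CSV -> {methyl id: {kind: series}}."""
    df = pd.read_csv(path)
    missing = set(RELAX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: relaxation table missing columns {sorted(missing)}")
    out: dict[tuple[str, int, str], dict[str, RelaxationSeries]] = {}
    for (mid_str, kind), grp in df.groupby(["methyl_id", "kind"], sort=False):
        mid = parse_methyl_id(str(mid_str))
        out.setdefault(mid, {})[str(kind)] = RelaxationSeries(
            grp["delay_s"].to_numpy(), grp["height"].to_numpy(), str(kind))
    return out


def write_relaxation_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False, columns=RELAX_COLUMNS)


def write_restraints(restraints: Iterable[DistanceRestraint], path: str | Path,
                     physics: PREPhysics | None = None) -> None:
    """Whitespace-columnar restraint list with a '#' header."""
    with open(path, "w") as fh:
        if physics is not None:
            fh.write(f"# tau_hmqc_s {physics.tau_hmqc:.6g}  tau_c_s {physics.tau_c:.6g}  "
                     f"omega_rad_s {physics.omega:.6g}  K_cm6_s2 {physics.K:.6g}\n")
        fh.write("# chainA residA atomA chainB residB atomB lower upper class\n")
        for r in restraints:
            fh.write(f"{r.chain_a} {r.resid_a} {r.atom_a} "
                     f"{r.chain_b} {r.resid_b} {r.atom_b} "
                     f"{r.lower:.3f} {r.upper:.3f} {r.klass}\n")


def read_restraints(path: str | Path) -> list[DistanceRestraint]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            out.append(DistanceRestraint(f[0], int(f[1]), f[2], f[3], int(f[4]), f[5],
                                         float(f[6]), float(f[7]), f[8]))
    return out


def median_rates(series_map: dict[tuple[str, int, str], dict[str, RelaxationSeries]],
                 fitter) -> dict[tuple[str, int, str], tuple[float, float]]:
    """Fit every (methyl, kind) series; return {methyl: (R2_diaH, R2_diaHC)}
    for methyls having both kinds."""
    rates: dict[tuple[str, int, str], tuple[float, float]] = {}
    for mid, kinds in series_map.items():
        if "diaH" in kinds and "diaHC" in kinds:
            rates[mid] = (fitter(kinds["diaH"]).rate, fitter(kinds["diaHC"]).rate)
    return rates
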