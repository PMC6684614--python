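"""End-to-end orchestration: quantify -> restrain -> score -> select.

These functions are the library surface behind the ``presans pipeline``
command; each stage can also be run on its own.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .pre import (
    DistanceRestraint,
    build_restraints,
    fit_exponential_decay,
    ratio_with_error,
)
from .sans import (
    LabelingScheme,
    SANSCurve,
    bead_model,
    chi2_fit,
    consensus_fitness,
    debye_intensity,
    normalize_chi2_set,
    read_sans_curve,
)
from .selection import (
    RestraintEnergyRecord,
    cluster_structures,
    find_center,
    flag_low_energy_outliers,
    restraint_energy,
    select_final_ensemble,
)
from .structures import Structure, read_structure
from .synthetic import default_tag_site

logger = logging.getLogger(__name__)


def quantify_peaks(cfg: RunConfig) -> tuple[list, dict]:
    """Peak + relaxation tables -> intensity-ratio records and per-methyl rates."""
    peaks = pio.read_peak_table(cfg.resolve(cfg.peaks_path))
    records = [ratio_with_error(para, dia, mid)
               for mid, para, dia in pio.peak_pairs(peaks)]
    series = pio.read_relaxation_table(cfg.resolve(cfg.relaxation_path))
    rates = pio.median_rates(series, fit_exponential_decay)
    logger.info("quantified %d methyls, %d with measured relaxation rates",
                len(records), len(rates))
    return records, rates


def derive_restraints(cfg: RunConfig, structure: Structure | None = None,
                      ) -> list[DistanceRestraint]:
    structure = structure if structure is not None else read_structure(
        cfg.resolve(cfg.complex_path), cfg.deuteration)
    records, rates = quantify_peaks(cfg)
    physics = cfg.physics()
    tag = default_tag_site(structure, cfg.tag_chain, cfg.tag_resid,
                           cloud_points=cfg.tag_cloud_points, seed=cfg.seed)
    restraints, pre_records = build_restraints(records, rates, physics, tag, structure)
    by_class: dict[str, int] = {}
    for r in pre_records:
        by_class[r.klass] = by_class.get(r.klass, 0) + 1
    logger.info("built %d restraints (%s)", len(restraints),
                ", ".join(f"{k}={v}" for k, v in sorted(by_class.items())))
    return restraints


def load_ensemble(cfg: RunConfig) -> tuple[list[Structure], list[str]]:
    manifest = pd.read_csv(cfg.resolve(cfg.manifest_path))
    structures, ids = [], []
    for _, row in manifest.iterrows():
        structures.append(read_structure(cfg.resolve(str(row["path"])), cfg.deuteration))
        ids.append(str(row["structure_id"]))
    if not structures:
        raise ValueError(f"empty ensemble manifest: {cfg.manifest_path}")
    return structures, ids


def sans_score_ensemble(structures: Sequence[Structure],
                        datasets: Sequence[tuple[LabelingScheme, SANSCurve]],
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-structure per-dataset chi^2 and the consensus fitness.

    Returns (chi2 matrix [structures x datasets], fitness vector).
    """
    if not datasets:
        raise ValueError("no SANS datasets to score against")
    chi2 = np.zeros((len(structures), len(datasets)))
    for j, (scheme, exp_curve) in enumerate(datasets):
        for i, s in enumerate(structures):
            calc = debye_intensity(bead_model(s, scheme), exp_curve.q, scheme)
            chi2[i, j], _ = chi2_fit(calc, exp_curve)
    norms = np.column_stack([normalize_chi2_set(chi2[:, j])
                             for j in range(chi2.shape[1])])
    return chi2, consensus_fitness(norms)


def load_sans_datasets(cfg: RunConfig) -> list[tuple[LabelingScheme, SANSCurve]]:
    out = []
    for ds in cfg.sans_datasets:
        scheme = LabelingScheme.make(dict(ds.deuteration), ds.f_d2o,
                                     cfg.exchange_efficiency, name=ds.name)
        curve = read_sans_curve(cfg.resolve(ds.path), q_units=cfg.q_units)
        if curve.sigma is None:
            raise ValueError(f"SANS dataset {ds.name!r} has no error column")
        out.append((scheme, curve))
    return out


def run_selection(cfg: RunConfig, restraints: Sequence[DistanceRestraint],
                  structure: Structure | None = None) -> dict:
    """Score, cluster and select an ensemble against restraints + SANS data.

    Writes report.csv and summary.json into the output directory and
    returns the summary.
    """
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = structure if structure is not None else read_structure(
        cfg.resolve(cfg.complex_path), cfg.deuteration)
    structures, ids = load_ensemble(cfg)
    energies = [restraint_energy(s, restraints) for s in structures]
    records = [RestraintEnergyRecord(i, e) for i, e in zip(ids, energies)]
    outliers = set(flag_low_energy_outliers(records))

    datasets = load_sans_datasets(cfg)
    chi2, fitness = sans_score_ensemble(structures, datasets)

    reference_chains = cfg.reference_chains or [c for c in structure.chain_order
                                                if c not in cfg.mobile_chains]
    mobile_chains = cfg.mobile_chains or [structure.chain_order[-1]]
    clusters = cluster_structures(structures, fitness, reference_chains, mobile_chains,
                                  structure_ids=ids, mode=cfg.cluster_mode,
                                  cutoff=cfg.cluster_cutoff)
    clusters = select_final_ensemble(clusters, fitness)
    selected_idx = np.flatnonzero(clusters.selected)
    center_id = None
    if len(selected_idx) >= 2:
        center_id = find_center([structures[i] for i in selected_idx],
                                [ids[i] for i in selected_idx])
    elif len(selected_idx) == 1:
        center_id = ids[selected_idx[0]]
    clusters.center_id = center_id

    report = pd.DataFrame({
        "structure_id": ids,
        "E_exp": energies,
        "ln_E": [r.ln_e for r in records],
        "outlier_flag": [i in outliers for i in ids],
    })
    for j, (scheme, _) in enumerate(datasets):
        report[f"chi2_{scheme.name or j}"] = chi2[:, j]
    report["fitness"] = fitness
    report["cluster"] = clusters.labels
    report["selected_flag"] = clusters.selected
    report_path = outdir / "report.csv"
    report.to_csv(report_path, index=False, float_format="%.6g")

    summary = {
        "n_structures": len(ids),
        "n_restraints": len(restraints),
        "n_outliers": len(outliers),
        "n_clusters": len(set(int(l) for l in clusters.labels)),
        "n_selected": int(clusters.selected.sum()),
        "reference_id": clusters.reference_id,
        "center_id": center_id,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    cfg.dump(outdir / "resolved_config.yaml")
    logger.info("selection summary: %s", summary)
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Full analysis on a study directory.

    Stages: quantify PRE peaks, build restraints, compute restraint
    energies and low-ln(E) outliers, score every candidate against every
    SANS contrast, cluster by o-RMSD around the best-fitness pose, select
    the final ensemble and its centre structure.
    """
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = read_structure(cfg.resolve(cfg.complex_path), cfg.deuteration)
    restraints = derive_restraints(cfg, structure)
    pio.write_restraints(restraints, outdir / "restraints.txt", cfg.physics())
    return run_selection(cfg, restraints, structure)
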