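"""End-to-end runs: RMSD phylogeny, interface report, ITC panel.

Each run writes its artifacts plus a manifest (inputs, parameters,
seed, package version) so that identical manifests imply identical
numeric outputs for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import itc as itc_mod
from . import structphylo
from .sasa_interface import (
    InterfaceReport,
    SASAParams,
    buried_surface,
    find_hbonds,
    find_salt_bridges,
    hotspot_burial,
)
from .structure_io import ResidueKey, Structure


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_manifest(out_dir: Path, name: str, payload: dict) -> None:
    payload = dict(payload)
    payload["package_version"] = __version__
    payload["timestamp"] = datetime.now(timezone.utc).isoformat()
    (out_dir / f"{name}_manifest.json").write_text(json.dumps(payload, indent=2,
                                                              default=str))


def run_phylo(
    alignment: str | Path,
    structure_map: dict[str, tuple[str | Path, str]],
    out_prefix: str | Path,
    linkage: str = "average",
) -> tuple[structphylo.DistanceMatrix, str]:
    """Alignment + structures → RMSD matrix CSV + newick tree + manifest."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    try:
        msa = structphylo.load_msa(alignment, structure_map)
    except Exception as exc:
        raise StageError("load_msa", exc) from exc
    try:
        matrix = structphylo.rmsd_matrix(msa)
    except Exception as exc:
        raise StageError("rmsd_matrix", exc) from exc
    # PDB coordinates carry 3 decimals, so rigid copies read back from disk
    # leave sub-millangstrom residuals; anything below 0.01 Å is degenerate
    if np.allclose(matrix.values, 0.0, atol=1e-2):
        import warnings

        warnings.warn("all pairwise distances are ~0; tree topology is arbitrary",
                      stacklevel=2)
    try:
        tree = structphylo.cluster(matrix, linkage=linkage)
        newick = structphylo.to_newick(tree)
    except Exception as exc:
        raise StageError("cluster", exc) from exc
    matrix.to_csv(out_prefix.with_suffix(".rmsd.csv"))
    out_prefix.with_suffix(".nwk").write_text(newick + "\n")
    _write_manifest(
        out_prefix.parent, out_prefix.name,
        {
            "analysis": "structure_phylogeny",
            "alignment": str(alignment),
            "structures": {k: [str(p), c] for k, (p, c) in structure_map.items()},
            "linkage": linkage,
        },
    )
    return matrix, newick


def interface_report(
    complex_structure: Structure,
    receptor_chains: list[str],
    peptide_chain: str,
    hotspot_residues: list[ResidueKey] | None = None,
    params: SASAParams | None = None,
    hbond_d_max: float = 3.5,
    hbond_angle_min: float = 90.0,
    salt_bridge_d_max: float = 4.0,
) -> InterfaceReport:
    """Combined buried-surface / H-bond / salt-bridge / hot-spot report."""
    params = params or SASAParams()
    part_a = set(receptor_chains)
    part_b = {peptide_chain}
    try:
        report = buried_surface(complex_structure, part_a, part_b, params)
    except Exception as exc:
        raise StageError("buried_surface", exc) from exc
    try:
        report.hbonds = find_hbonds(complex_structure, part_a, part_b,
                                    d_max=hbond_d_max, angle_min=hbond_angle_min)
        report.salt_bridges = find_salt_bridges(complex_structure, part_a, part_b,
                                                d_max=salt_bridge_d_max)
    except Exception as exc:
        raise StageError("contacts", exc) from exc
    if hotspot_residues:
        try:
            report.hotspots = hotspot_burial(
                complex_structure, part_a, peptide_chain, hotspot_residues, params
            )
        except Exception as exc:
            raise StageError("hotspot_burial", exc) from exc
    return report


def report_to_dict(report: InterfaceReport) -> dict:
    return {
        "schema_version": 1,
        "buried_total_A2": report.buried_total,
        "buried_per_partner_A2": list(report.buried_per_partner),
        "interface_area_pisa_A2": report.interface_area_pisa,
        "hbonds": [dataclasses.asdict(h) for h in report.hbonds],
        "salt_bridges": [dataclasses.asdict(s) for s in report.salt_bridges],
        "hotspots": [dataclasses.asdict(h) for h in report.hotspots],
    }


def run_interface(
    complex_structure: Structure,
    receptor_chains: list[str],
    peptide_chain: str,
    out_dir: str | Path,
    hotspot_residues: list[ResidueKey] | None = None,
    params: SASAParams | None = None,
) -> InterfaceReport:
    """Interface report → JSON + contacts CSV + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = interface_report(
        complex_structure, receptor_chains, peptide_chain,
        hotspot_residues=hotspot_residues, params=params,
    )
    (out_dir / "interface.json").write_text(
        json.dumps(report_to_dict(report), indent=2)
    )
    rows = [
        {"kind": "hbond", "atom_1": "/".join(map(str, h.donor)),
         "atom_2": "/".join(map(str, h.acceptor)), "distance_A": h.distance}
        for h in report.hbonds
    ] + [
        {"kind": "salt_bridge", "atom_1": "/".join(map(str, s.basic_atom)),
         "atom_2": "/".join(map(str, s.acidic_atom)), "distance_A": s.distance}
        for s in report.salt_bridges
    ]
    pd.DataFrame(rows, columns=["kind", "atom_1", "atom_2", "distance_A"]).to_csv(
        out_dir / "contacts.csv", index=False
    )
    _write_manifest(out_dir, "interface", {
        "analysis": "interface",
        "structure": complex_structure.id,
        "receptor_chains": receptor_chains,
        "peptide_chain": peptide_chain,
    })
    return report


def run_itc_panel(
    panel: dict[str, list[itc_mod.ITCExperiment]],
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Fit every replicate of every ligand; aggregate to a Kd ± SD table.

    Ligands whose replicates all come back flat are reported as ``NB``
    rows rather than dropped.
    """
    rows = []
    for ligand, replicates in panel.items():
        fits = [itc_mod.fit_single_site(exp) for exp in replicates]
        good = [f for f in fits if f.converged and not f.no_binding]
        if len(good) >= 2:
            mean_kd, sd_kd = itc_mod.aggregate_replicates(fits)
            rows.append({
                "ligand": ligand, "kd_nM": mean_kd, "kd_sd_nM": sd_kd,
                "N": float(np.mean([f.params.N for f in good])),
                "n_replicates": len(good), "verdict": "binding",
            })
        elif len(good) == 1:
            f = good[0]
            rows.append({
                "ligand": ligand, "kd_nM": f.kd_nM, "kd_sd_nM": float("nan"),
                "N": f.params.N, "n_replicates": 1, "verdict": "binding",
            })
        else:
            rows.append({
                "ligand": ligand, "kd_nM": float("nan"), "kd_sd_nM": float("nan"),
                "N": float("nan"), "n_replicates": 0, "verdict": "NB",
            })
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
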