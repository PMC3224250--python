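"""Shared plumbing for the numbered analysis drivers.

The drivers operate on a synthetic reference cohort written to
``scratch/cohort/`` as ordinary PDB files plus secondary-structure tables
and a manifest CSV — the same on-disk layout a study of real deposited
structures would use (one PDB per member, one DSSP-derived table, one
manifest row per pair).
"""

from __future__ import annotations

import csv
from pathlib import Path

from coldcore import compare, synthetic
from coldcore.structure_io import read_ss_table, read_structure, write_pdb, write_ss_table

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results" / "analysis"
COHORT_SEED = 11


def ensure_cohort(seed: int = COHORT_SEED) -> Path:
    """Write the reference cohort to scratch (if absent); return the manifest."""
    manifest = SCRATCH / "manifest.csv"
    if manifest.exists():
        return manifest
    SCRATCH.mkdir(parents=True, exist_ok=True)
    pairs, truth = synthetic.make_cohort(synthetic.CohortSpec(seed=seed))
    rows = []
    for p in pairs:
        psy_path = SCRATCH / f"{p.psy.id}.pdb"
        mes_path = SCRATCH / f"{p.mes.id}.pdb"
        ss_path = SCRATCH / f"{p.pair_id}_ss.csv"
        write_pdb(p.psy, psy_path)
        write_pdb(p.mes, mes_path)
        write_ss_table(p.ss, ss_path)
        rows.append(
            {
                "pair_id": p.pair_id,
                "psy_path": psy_path.name,
                "mes_path": mes_path.name,
                "psy_chain": "A",
                "mes_chain": "A",
                "psy_growth_temp": 4.0,
                "mes_growth_temp": 37.0,
                "ss_path": ss_path.name,
            }
        )
    truth.to_csv(SCRATCH / "truth.csv", index=False)
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def load_entries(manifest: Path) -> list[compare.CohortEntry]:
    """Read the cohort back from disk into pipeline entries."""
    entries = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            psy = read_structure(manifest.parent / row["psy_path"])
            mes = read_structure(manifest.parent / row["mes_path"])
            psy.growth_temp = float(row["psy_growth_temp"])
            mes.growth_temp = float(row["mes_growth_temp"])
            ss = read_ss_table(manifest.parent / row["ss_path"])
            entries.append(
                compare.CohortEntry(
                    pair_id=row["pair_id"],
                    psy=psy,
                    mes=mes,
                    psy_chain=row["psy_chain"],
                    mes_chain=row["mes_chain"],
                    ss_psy=ss,
                    ss_mes=ss,
                )
            )
    return entries


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
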