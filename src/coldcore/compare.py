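"""Cohort-level paired statistics and report assembly.

Because each psychrophile/mesophile pair shares an evolutionary origin and
(broadly) an environment, all cohort comparisons are *paired*: a classical
two-sided paired t-test on the per-pair differences, backed by an exact
sign (binomial) test on the direction of the differences.  Significance
defaults to α = 0.01 with no multiple-testing correction across probe
radii or metrics (a Bonferroni option exists but is off by default — a
deliberate, logged choice).

``run_cohort`` drives the full pipeline for a list of pairs: filtering,
Cα B-profile extraction and ΔB′ stratification, the void probe sweep,
cavity wall classification at the water-sized probe, and buried-water
counting; then assembles per-pair rows and cohort statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import yaml

from . import bflex, hydration, pairing, voids
from .structure_io import SSAnnotation, Structure, assign_radii


@dataclass
class TTestResult:
    t: float | None
    df: int
    p: float | None
    n: int
    mean_diff: float
    degenerate: bool = False


def paired_t(differences) -> TTestResult:
    """Two-sided paired t-test of mean difference against zero.

    Expects the per-pair differences; df = n − 1.  Zero variance is
    reported as a degenerate result instead of a p-value.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return TTestResult(None, n - 1, None, n, mean, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), n, mean)


@dataclass
class BinomialResult:
    n_positive: int
    n_informative: int
    p_two_sided: float | None
    p_one_sided: float | None
    all_ties: bool = False


def sign_binomial(differences, tie_tolerance: float = 0.0) -> BinomialResult:
    """Exact sign test: binomial(n_informative, ½) on the positive count.

    Ties (|d| ≤ ``tie_tolerance``) are dropped.  Both sidedness modes are
    reported: the one-sided p is for the direction "psychrophile greater".
    """
    d = np.asarray(differences, dtype=float)
    informative = d[np.abs(d) > tie_tolerance]
    if informative.size == 0:
        return BinomialResult(0, 0, None, None, all_ties=True)
    k = int((informative > 0).sum())
    n = int(informative.size)
    res_two = stats.binomtest(k, n, 0.5, alternative="two-sided")
    res_one = stats.binomtest(k, n, 0.5, alternative="greater")
    return BinomialResult(k, n, float(res_two.pvalue), float(res_one.pvalue))


def pearson_r2(x, y) -> float | None:
    """Squared Pearson correlation; None when either input has no variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


@dataclass
class CohortConfig:
    """Knobs of the cohort pipeline (units: Å for radii/spacing, Å³ volumes)."""

    probes: tuple[float, ...] = voids.PROBE_SWEEP
    grid_spacing: float = 0.5
    envelope_radius: float = 4.0
    include_pockets: bool = True
    lining_probe: float = 1.4
    alpha: float = 0.01
    bonferroni: bool = False
    water_radius: float = 1.4
    sasa_probe: float = 1.4
    sasa_points: int = 960
    normalization: str = "printed"
    min_residues: int = 150
    max_resolution: float = 2.5
    min_identity: float = 30.0
    force_include: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "probes" in data:
            data["probes"] = tuple(float(p) for p in data["probes"])
        return cls(**data)


@dataclass
class CohortEntry:
    """One candidate pair, fully in memory."""

    pair_id: str
    psy: Structure
    mes: Structure
    psy_chain: str = "A"
    mes_chain: str = "A"
    ss_psy: SSAnnotation | None = None
    ss_mes: SSAnnotation | None = None
    alignment: pairing.PairAlignment | None = None


@dataclass
class CohortResult:
    pair_table: pd.DataFrame  # one row per accepted pair
    structure_table: pd.DataFrame  # one row per structure per probe
    stats_table: pd.DataFrame  # one row per metric (and probe where relevant)
    ss_table: pd.DataFrame  # pooled per-SS-class ΔB′ distribution
    buried_r2: float | None
    rejected: list[tuple[str, list[str]]]
    skipped: list[tuple[str, str]]
    config: CohortConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pair_table.to_csv(outdir / "pairs.csv", index=False)
        self.structure_table.to_csv(outdir / "structures.csv", index=False)
        self.stats_table.to_csv(outdir / "cohort_stats.csv", index=False)
        self.ss_table.to_csv(outdir / "delta_b_by_ss.csv", index=False)
        meta = {
            "buried_r2": self.buried_r2,
            "rejected": [{"pair": p, "reasons": r} for p, r in self.rejected],
            "skipped": [{"pair": p, "reason": r} for p, r in self.skipped],
            "alpha": self.config.alpha,
        }
        (outdir / "cohort_meta.json").write_text(json.dumps(meta, indent=2))


def analyze_structure_voids(
    structure: Structure, config: CohortConfig
) -> tuple[list[dict], dict]:
    """Void summaries per probe plus the wall profile at the lining probe."""
    st = assign_radii(structure)
    rows = []
    lining_counts = None
    for probe in config.probes:
        vlist = voids.detect_voids(
            st,
            probe_radius=probe,
            grid_spacing=config.grid_spacing,
            envelope_radius=config.envelope_radius,
            include_pockets=config.include_pockets,
        )
        summary = voids.summarize_voids(vlist, probe)
        rows.append(
            {
                "structure_id": st.id,
                "probe_radius": probe,
                "n_voids": summary.n_voids,
                "n_pockets": summary.n_pockets,
                "n_cavities": summary.n_cavities,
                "total_void_volume": summary.total_void_volume,
                "pocket_volume": summary.pocket_volume,
                "cavity_volume": summary.cavity_volume,
                "vol_per_cav": summary.vol_per_cav,
            }
        )
        if abs(probe - config.lining_probe) < 1e-9:
            profile_counts = {cls: 0 for cls in voids.RESIDUE_CLASSES}
            for v in vlist:
                if v.kind != "cavity":
                    continue
                lining = voids.lining_residues(v, st, probe)
                prof = voids.classify_lining(lining)
                for cls, c in prof.counts.items():
                    profile_counts[cls] += c
            total = sum(profile_counts.values())
            lining_counts = {
                "counts": profile_counts,
                "freqs": (
                    {c: v / total for c, v in profile_counts.items()} if total else None
                ),
            }
    return rows, lining_counts or {"counts": None, "freqs": None}


def _member_metrics(structure: Structure, config: CohortConfig) -> tuple[list[dict], dict, int]:
    void_rows, lining = analyze_structure_voids(structure, config)
    st = assign_radii(structure)
    burial = hydration.count_buried_waters(
        st,
        probe_radius=config.sasa_probe,
        water_radius=config.water_radius,
        n_points=config.sasa_points,
    )
    return void_rows, lining, burial.count


def run_cohort(entries: list[CohortEntry], config: CohortConfig | None = None) -> CohortResult:
    """Run the full comparison pipeline over a cohort of candidate pairs.

    Pairs failing the acceptance filter are dropped (unless
    ``config.force_include``); a pair that errors mid-analysis is skipped
    with a logged reason.  Raises if no pair survives.
    """
    if not entries:
        raise ValueError("empty cohort")
    config = config or CohortConfig()

    pair_rows = []
    structure_rows = []
    all_deltas = []
    rejected: list[tuple[str, list[str]]] = []
    skipped: list[tuple[str, str]] = []

    for entry in entries:
        record = pairing.PairRecord(
            pair_id=entry.pair_id,
            psy=entry.psy,
            mes=entry.mes,
            psy_chain=entry.psy_chain,
            mes_chain=entry.mes_chain,
            alignment=entry.alignment,
        )
        record = pairing.filter_pair(
            record,
            min_residues=config.min_residues,
            max_resolution=config.max_resolution,
            min_identity=config.min_identity,
        )
        if not record.accepted and not config.force_include:
            rejected.append((entry.pair_id, record.rejection_reasons))
            continue
        try:
            row = {"pair_id": entry.pair_id, "identity": record.alignment.identity}
            # Flexibility.
            psy_prof = bflex.profile_from_structure(
                entry.psy, entry.psy_chain, mode=config.normalization
            )
            mes_prof = bflex.profile_from_structure(
                entry.mes, entry.mes_chain, mode=config.normalization
            )
            delta = bflex.delta_b(psy_prof, mes_prof, record.alignment)
            if entry.ss_psy is not None:
                all_deltas.append((delta, entry.ss_psy))
            row["n_delta_positions"] = len(delta)
            row["mean_delta_b"] = float(delta.delta.mean())
            # Voids & walls & waters.
            psy_voids, psy_lining, psy_buried = _member_metrics(entry.psy, config)
            mes_voids, mes_lining, mes_buried = _member_metrics(entry.mes, config)
            structure_rows.extend(psy_voids)
            structure_rows.extend(mes_voids)
            for pv, mv in zip(psy_voids, mes_voids):
                probe = pv["probe_radius"]
                for metric in (
                    "total_void_volume",
                    "pocket_volume",
                    "cavity_volume",
                    "n_voids",
                    "n_pockets",
                    "n_cavities",
                ):
                    row[f"d_{metric}_{probe:g}"] = pv[metric] - mv[metric]
                if pv["vol_per_cav"] is not None and mv["vol_per_cav"] is not None:
                    row[f"d_vol_per_cav_{probe:g}"] = (
                        pv["vol_per_cav"] - mv["vol_per_cav"]
                    )
                    row[f"psy_vol_per_cav_{probe:g}"] = pv["vol_per_cav"]
                    row[f"mes_vol_per_cav_{probe:g}"] = mv["vol_per_cav"]
                else:
                    row[f"d_vol_per_cav_{probe:g}"] = np.nan
                    row[f"psy_vol_per_cav_{probe:g}"] = np.nan
                    row[f"mes_vol_per_cav_{probe:g}"] = np.nan
            if psy_lining["freqs"] and mes_lining["freqs"]:
                for cls in voids.RESIDUE_CLASSES:
                    row[f"d_freq_{cls}"] = (
                        psy_lining["freqs"][cls] - mes_lining["freqs"][cls]
                    )
            else:
                for cls in voids.RESIDUE_CLASSES:
                    row[f"d_freq_{cls}"] = np.nan
            row["psy_buried_waters"] = psy_buried
            row["mes_buried_waters"] = mes_buried
            row["d_buried_waters"] = psy_buried - mes_buried
            pair_rows.append(row)
        except Exception as exc:  # noqa: BLE001 - one bad pair must not kill the run
            skipped.append((entry.pair_id, f"{type(exc).__name__}: {exc}"))

    if not pair_rows:
        raise RuntimeError(
            f"no pairs survived: {len(rejected)} rejected, {len(skipped)} failed"
        )
    pair_table = pd.DataFrame(pair_rows)
    structure_table = pd.DataFrame(structure_rows)
    stats_table = cohort_statistics(pair_table, config)

    # Residue keys can collide across pairs (every member uses chain "A"),
    # so ΔB′ values are pooled class-wise pair by pair.
    ss_table = _pooled_ss_table(all_deltas) if all_deltas else pd.DataFrame()

    buried_r2 = None
    if len(pair_table) >= 3:
        buried_r2 = pearson_r2(
            pair_table["psy_buried_waters"], pair_table["mes_buried_waters"]
        )
    return CohortResult(
        pair_table=pair_table,
        structure_table=structure_table,
        stats_table=stats_table,
        ss_table=ss_table,
        buried_r2=buried_r2,
        rejected=rejected,
        skipped=skipped,
        config=config,
    )


def _pooled_ss_table(all_deltas) -> pd.DataFrame:
    by_class: dict[str, list[float]] = {}
    for delta, ss in all_deltas:
        for d, key in zip(delta.delta, delta.psy_keys):
            by_class.setdefault(ss.get(key), []).append(float(d))
    rows = []
    for cls in sorted(by_class):
        x = np.array(by_class[cls])
        row = {"ss_class": cls, "n": int(x.size), "mean_delta": float(x.mean())}
        if x.size >= 3 and np.std(x) > 0:
            t, p = stats.ttest_1samp(x, 0.0)
            row["t"], row["p"] = float(t), float(p)
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_statistics(pair_table: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Paired t and sign tests for every difference column of the pair table."""
    metrics = [c for c in pair_table.columns if c.startswith("d_")]
    n_tests = len(metrics)
    rows = []
    for metric in metrics:
        d = pair_table[metric].dropna().to_numpy(dtype=float)
        row = {"metric": metric, "n": int(d.size)}
        if d.size >= 3:
            tt = paired_t(d)
            row.update(
                mean_diff=tt.mean_diff,
                t=tt.t,
                p_t=tt.p,
                degenerate=tt.degenerate,
            )
            sb = sign_binomial(d)
            row.update(
                n_positive=sb.n_positive,
                n_informative=sb.n_informative,
                p_binom_two=sb.p_two_sided,
                p_binom_one=sb.p_one_sided,
            )
            alpha = config.alpha / n_tests if config.bonferroni else config.alpha
            row["significant"] = tt.p is not None and tt.p < alpha
        else:
            row.update(
                mean_diff=float(d.mean()) if d.size else np.nan,
                t=None, p_t=None, degenerate=False, significant=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)
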