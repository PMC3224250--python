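"""Cα B-factor outlier filtering, normalization, and paired ΔB′ analysis.

Raw crystallographic B-values mix intrinsic atomic motion with crystal
lattice artifacts and refinement idiosyncrasies, so cross-structure
comparison needs two steps:

1. robust outlier removal with the modified z-score
   M_i = 0.6745 |X_i − median(X)| / MAD, flagging positions with M_i > 3.5
   (MAD is the median absolute deviation from the median);
2. normalization of the surviving values.  The default ("printed") mode
   divides each B_i by ⟨B²⟩, the mean of squared non-outlier B-values.
   Note this form is *not* invariant to a global rescaling of B; a
   conventional z-score mode is provided as an alternative.

For a psychrophile/mesophile pair, ΔB′_i = B′_i(psy) − B′_i(mes) is computed
at every aligned, non-gap position where neither member is an outlier.
Positive ΔB′ means the psychrophilic residue is the more flexible one.
ΔB′ distributions are then stratified by the DSSP class of the
psychrophilic residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import ResidueKey, SSAnnotation, Structure

MAD_SCALE = 0.6745
OUTLIER_CUTOFF = 3.5


class DegenerateProfileError(ValueError):
    pass


def detect_outliers(b_values) -> tuple[np.ndarray, bool]:
    """Flag B-value outliers with the modified z-score.

    Returns ``(mask, degenerate)`` where ``mask`` is True at outlier
    positions.  A profile with MAD = 0 is degenerate: the statistic is
    undefined there, so nothing is flagged and the flag is returned to the
    caller (real Cα profiles essentially never have MAD = 0).
    """
    x = np.asarray(b_values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D profile with at least 4 B-values")
    med = np.median(x)
    abs_dev = np.abs(x - med)
    mad = np.median(abs_dev)
    if mad == 0.0:
        return np.zeros(x.size, dtype=bool), True
    m = MAD_SCALE * abs_dev / mad
    return m > OUTLIER_CUTOFF, False


@dataclass
class BProfile:
    """Per-residue Cα B-values with outlier mask and normalized values."""

    values: np.ndarray  # raw B (Å²)
    outlier_mask: np.ndarray  # True = outlier, excluded from normalization
    norm_constant: float  # ⟨B²⟩ (printed mode) or σ (zscore mode)
    normalized: np.ndarray  # B′, defined at every position (outliers flagged)
    mode: str = "printed"
    degenerate: bool = False
    residue_keys: list[ResidueKey] = field(default_factory=list)

    def __len__(self) -> int:
        return int(self.values.size)


def normalize_b(
    b_values,
    outlier_mask=None,
    mode: str = "printed",
    residue_keys: list[ResidueKey] | None = None,
) -> BProfile:
    """Normalize a B-value profile after outlier removal.

    ``printed`` mode: B′_i = B_i / ⟨B²⟩ with ⟨B²⟩ the mean of B_i² over
    non-outlier positions.  ``zscore`` mode: B′_i = (B_i − mean) / sd over
    non-outlier positions.  Outlier positions still receive a B′ value but
    stay flagged in the mask and never enter the normalization constant.
    """
    x = np.asarray(b_values, dtype=float)
    degenerate = False
    if outlier_mask is None:
        outlier_mask, degenerate = detect_outliers(x)
    mask = np.asarray(outlier_mask, dtype=bool)
    kept = x[~mask]
    if kept.size == 0:
        raise DegenerateProfileError("all positions flagged as outliers")
    if mode == "printed":
        norm = float(np.mean(kept**2))
        if norm <= 0:
            raise DegenerateProfileError("⟨B²⟩ is not positive")
        normalized = x / norm
    elif mode == "zscore":
        mu, sd = float(np.mean(kept)), float(np.std(kept, ddof=1))
        if sd == 0:
            raise DegenerateProfileError("zero variance profile")
        norm = sd
        normalized = (x - mu) / sd
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return BProfile(
        values=x,
        outlier_mask=mask,
        norm_constant=norm,
        normalized=normalized,
        mode=mode,
        degenerate=degenerate,
        residue_keys=list(residue_keys) if residue_keys else [],
    )


def profile_from_structure(
    structure: Structure, chain: str, mode: str = "printed"
) -> BProfile:
    """Build a normalized Cα B-profile for one chain of a structure."""
    b, keys = [], []
    for a in structure.atoms:
        if a.chain_id == chain and a.atom_name == "CA" and not a.is_water:
            b.append(a.b_factor)
            keys.append(a.residue_key)
    if not b:
        raise ValueError(f"{structure.id}: chain {chain!r} has no Cα atoms")
    return normalize_b(b, mode=mode, residue_keys=keys)


@dataclass
class DeltaBProfile:
    """Aligned ΔB′ values: one entry per usable (non-gap, non-outlier) position."""

    delta: np.ndarray
    psy_keys: list[ResidueKey]
    mes_keys: list[ResidueKey]

    def __len__(self) -> int:
        return int(self.delta.size)


def delta_b(psy: BProfile, mes: BProfile, alignment) -> DeltaBProfile:
    """Compute ΔB′_i = B′_i(psy) − B′_i(mes) over an alignment.

    ``alignment`` is a :class:`coldcore.pairing.PairAlignment`; its
    ``pairs`` attribute maps psychrophile profile indices to mesophile
    profile indices for non-gap columns.  Positions flagged as outliers in
    either member are dropped.
    """
    deltas, pk, mk = [], [], []
    for i, j in alignment.pairs:
        if psy.outlier_mask[i] or mes.outlier_mask[j]:
            continue
        deltas.append(psy.normalized[i] - mes.normalized[j])
        pk.append(psy.residue_keys[i] if psy.residue_keys else ("", i, ""))
        mk.append(mes.residue_keys[j] if mes.residue_keys else ("", j, ""))
    if not deltas:
        raise ValueError("alignment leaves no usable (non-gap, non-outlier) positions")
    return DeltaBProfile(np.array(deltas), pk, mk)


def delta_table(delta: DeltaBProfile, ss: SSAnnotation | None = None) -> pd.DataFrame:
    """Per-aligned-position ΔB′ table (the flexibility-map view of a pair)."""
    rows = []
    for d, pk, mk in zip(delta.delta, delta.psy_keys, delta.mes_keys):
        rows.append(
            {
                "psy_chain": pk[0], "psy_seq": pk[1], "psy_icode": pk[2],
                "mes_chain": mk[0], "mes_seq": mk[1], "mes_icode": mk[2],
                "delta_b": float(d),
                "ss": ss.get(pk) if ss is not None else "-",
            }
        )
    return pd.DataFrame(rows)


def _boxplot_stats(x: np.ndarray) -> dict:
    """Quartiles plus 1.5·IQR whisker-outliers (standard boxplot convention)."""
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = x[(x < lo) | (x > hi)]
    return {
        "q1": q1,
        "median": med,
        "q3": q3,
        "whisker_low": float(x[x >= lo].min()),
        "whisker_high": float(x[x <= hi].max()),
        "n_box_outliers": int(out.size),
    }


def stratify_by_ss(
    delta: DeltaBProfile,
    ss: SSAnnotation,
    min_positions: int = 3,
) -> pd.DataFrame:
    """Per-DSSP-class ΔB′ distribution table.

    Each ΔB′ value is attributed to the secondary-structure class of the
    *psychrophilic* residue.  Rows carry the position count, mean,
    boxplot summary, and a two-sided one-sample t-test of mean ΔB′ against
    zero (suppressed below ``min_positions``).  Class counts sum to the
    number of scored aligned positions.
    """
    by_class: dict[str, list[float]] = {}
    for d, key in zip(delta.delta, delta.psy_keys):
        by_class.setdefault(ss.get(key), []).append(float(d))
    rows = []
    for cls in sorted(by_class):
        x = np.array(by_class[cls])
        row = {"ss_class": cls, "n": int(x.size), "mean_delta": float(x.mean())}
        row.update(_boxplot_stats(x))
        if x.size >= min_positions and np.std(x) > 0:
            t, p = stats.ttest_1samp(x, 0.0)
            row["t"], row["p"] = float(t), float(p)
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ss_mismatch_rate(delta: DeltaBProfile, ss_psy: SSAnnotation, ss_mes: SSAnnotation) -> float:
    """Fraction of scored positions where the two members' DSSP classes differ."""
    if len(delta) == 0:
        return 0.0
    mismatch = sum(
        1
        for pk, mk in zip(delta.psy_keys, delta.mes_keys)
        if ss_psy.get(pk) != ss_mes.get(mk)
    )
    return mismatch / len(delta)
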