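"""Homolog pair construction: sequences, alignment, thermal classes, filters.

The cohort design pairs one psychrophilic enzyme with one mesophilic
homolog.  Pairs are admitted when both members have at least 150 residues,
crystal resolution of 2.5 Å or better, at least 30% pairwise sequence
identity, and thermal classes (psychrophile, mesophile) by organism growth
temperature: [0, 20) °C psychrophile, [20, 45) mesophile, [45, 100]
thermophile.

Alignments are global (Needleman–Wunsch, BLOSUM62, gap open −11 / extend
−1, via Biopython's PairwiseAligner).  An externally computed alignment —
e.g. from a structure-superposition program — can be supplied as aligned
FASTA and is used verbatim, with identity recomputed from its columns.
Identity is counted over aligned columns, excluding double gaps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.PDBData import protein_letters_3to1_extended as _3TO1

from .structure_io import ResidueKey, Structure


class PairingError(ValueError):
    pass


def three_to_one(residue_name: str) -> str:
    """3-letter -> 1-letter residue code; modified residues map to their parent
    (e.g. MSE -> M), anything unknown maps to X."""
    one = _3TO1.get(residue_name.upper(), "X")
    return one if len(one) == 1 and one.isalpha() else "X"


def extract_sequence(structure: Structure, chain: str) -> str:
    """One-letter amino-acid sequence of a chain, in residue order."""
    keys = amino_residue_keys(structure, chain)
    if not keys:
        raise PairingError(f"{structure.id}: chain {chain!r} has no amino-acid residues")
    names = {}
    for a in structure.atoms:
        if a.chain_id == chain and not a.is_water:
            names.setdefault(a.residue_key, a.residue_name)
    return "".join(three_to_one(names[k]) for k in keys)


def amino_residue_keys(structure: Structure, chain: str) -> list[ResidueKey]:
    """Residue keys of non-water residues of a chain, in atom order."""
    seen: dict[ResidueKey, None] = {}
    for a in structure.atoms:
        if a.chain_id == chain and not a.is_water:
            seen.setdefault(a.residue_key, None)
    return list(seen)


@dataclass
class PairAlignment:
    """A gapped pairwise alignment plus the derived position map."""

    aligned_a: str
    aligned_b: str
    pairs: list[tuple[int, int]]  # (index in seq a, index in seq b) per non-gap column
    identity: float  # percent over aligned (non-double-gap) columns

    @property
    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[int, int]:
        return {j: i for i, j in self.pairs}


def _alignment_from_gapped(ga: str, gb: str) -> PairAlignment:
    if len(ga) != len(gb):
        raise PairingError("aligned sequences differ in length")
    pairs, ident, cols = [], 0, 0
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        gap_a, gap_b = ca == "-", cb == "-"
        if gap_a and gap_b:
            continue
        cols += 1
        if not gap_a and not gap_b:
            pairs.append((ia, ib))
            if ca.upper() == cb.upper():
                ident += 1
        if not gap_a:
            ia += 1
        if not gap_b:
            ib += 1
    if cols == 0:
        raise PairingError("empty alignment")
    return PairAlignment(ga, gb, pairs, 100.0 * ident / cols)


_ALIGNER: PairwiseAligner | None = None


def _aligner() -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = PairwiseAligner(
            mode="global",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-11.0,
            extend_gap_score=-1.0,
        )
    return _ALIGNER


def align_pair(seq_a: str, seq_b: str) -> PairAlignment:
    """Globally align two sequences and return the alignment + identity."""
    if not seq_a or not seq_b:
        raise PairingError("cannot align empty sequences")
    aln = _aligner().align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return _alignment_from_gapped(ga, gb)


def write_alignment_fasta(
    aln: PairAlignment, path: str | Path, names: tuple[str, str] = ("psy", "mes")
) -> None:
    """Write the gapped alignment as aligned FASTA (2 records)."""
    with open(path, "w") as fh:
        fh.write(f">{names[0]}\n{aln.aligned_a}\n>{names[1]}\n{aln.aligned_b}\n")


def read_alignment_fasta(path: str | Path) -> PairAlignment:
    """Read an externally computed pairwise alignment (aligned FASTA, 2 records)."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 2:
        raise PairingError(f"{path}: expected exactly 2 aligned records, got {len(recs)}")
    return _alignment_from_gapped(str(recs[0].seq), str(recs[1].seq))


def classify_thermal(growth_temp: float | None) -> str:
    """Growth temperature (°C) -> thermal class.

    Boundary convention: [0, 20) psychrophile, [20, 45) mesophile,
    [45, 100] thermophile; anything outside (or missing) is unknown.
    """
    if growth_temp is None:
        return "unknown"
    t = float(growth_temp)
    if 0 <= t < 20:
        return "psychrophile"
    if 20 <= t < 45:
        return "mesophile"
    if 45 <= t <= 100:
        return "thermophile"
    return "unknown"


@dataclass
class PairRecord:
    """One candidate psychrophile/mesophile pair with its acceptance state."""

    pair_id: str
    psy: Structure
    mes: Structure
    psy_chain: str = "A"
    mes_chain: str = "A"
    alignment: PairAlignment | None = None
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.rejection_reasons


def filter_pair(
    pair: PairRecord,
    min_residues: int = 150,
    max_resolution: float = 2.5,
    min_identity: float = 30.0,
) -> PairRecord:
    """Apply the cohort acceptance gates, appending rejection reasons.

    The resolution gate is inclusive (≤ 2.5 Å): reference cohorts contain
    entries at exactly 2.5 Å.  The filter is monotone — it only ever adds
    reasons, never removes them.
    """
    reasons = pair.rejection_reasons
    for role, st, chain in (("psy", pair.psy, pair.psy_chain), ("mes", pair.mes, pair.mes_chain)):
        n = st.n_residues(chain)
        if n < min_residues:
            reasons.append(f"{role}: {n} residues < {min_residues}")
        if st.resolution is None:
            reasons.append(f"{role}: resolution unknown")
        elif st.resolution > max_resolution:
            reasons.append(f"{role}: resolution {st.resolution:.2f} Å > {max_resolution}")
    if pair.alignment is None:
        try:
            pair.alignment = align_pair(
                extract_sequence(pair.psy, pair.psy_chain),
                extract_sequence(pair.mes, pair.mes_chain),
            )
        except PairingError as exc:
            reasons.append(f"alignment failed: {exc}")
    if pair.alignment is not None and pair.alignment.identity < min_identity:
        reasons.append(
            f"identity {pair.alignment.identity:.1f}% < {min_identity:.0f}%"
        )
    psy_cls = pair.psy.thermal_class
    mes_cls = pair.mes.thermal_class
    if psy_cls == "unknown" and pair.psy.growth_temp is not None:
        psy_cls = classify_thermal(pair.psy.growth_temp)
    if mes_cls == "unknown" and pair.mes.growth_temp is not None:
        mes_cls = classify_thermal(pair.mes.growth_temp)
    if (psy_cls, mes_cls) != ("psychrophile", "mesophile"):
        reasons.append(f"thermal classes ({psy_cls}, {mes_cls}) != (psychrophile, mesophile)")
    return pair


def read_manifest(path: str | Path) -> list[dict]:
    """Read a cohort manifest CSV.

    Columns: pair_id, psy_path, mes_path, psy_chain, mes_chain,
    psy_growth_temp, mes_growth_temp, and optionally ss_psy_path,
    ss_mes_path, alignment_path.
    """
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise PairingError(f"{path}: empty manifest")
    return rows
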