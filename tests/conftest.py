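"""Shared fixtures: hand-written text-format files and small structures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from coldcore.structure_io import AtomRecord, Structure

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

THREE_ATOM_PDB = """\
HEADER    HYDROLASE                               01-JAN-00   TEST
REMARK   2 RESOLUTION.    1.70 ANGSTROMS.
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.973  1.00 14.50           C
END
"""

WATER_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 10.00           C
HETATM    2  O   HOH A 101       5.000   0.000   0.000  1.00 30.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AMET A   1       1.000   0.000   0.000  0.60 12.00           C
ATOM      2  CA BMET A   1       1.200   0.000   0.000  0.40 15.00           C
ATOM      3  CA ASER A   2       4.000   0.000   0.000  0.50 11.00           C
ATOM      4  CA BSER A   2       4.300   0.000   0.000  0.50 13.00           C
END
"""

HET_MIX_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 11.00           C
HETATM    3 FE   HEM A 201       8.000   0.000   0.000  1.00 20.00          FE
HETATM    4  O   HOH A 301      12.000   0.000   0.000  1.00 30.00           O
HETATM    5  O   HOH A 302      15.000   0.000   0.000  1.00 31.00           O
END
"""

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 11.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00 10.00           C
ATOM      2  CA  GLY A   2      12.800   9.000   9.000  1.00 11.00           C
ENDMDL
END
"""


def write_pdb_text(tmp_path, text, name="fixture.pdb"):
    path = tmp_path / name
    path.write_text(text)
    return path


def make_dssp_text(entries) -> str:
    """Build a classic-format DSSP file from (resseq, chain, aa, ss) tuples."""
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "REFERENCE ...",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    for i, (resseq, chain, aa, ss) in enumerate(entries, start=1):
        line = list(" " * 120)
        line[0:5] = f"{i:5d}"
        line[5:10] = f"{resseq:5d}"
        line[10] = " "
        line[11] = chain
        line[13] = aa
        line[16] = ss if ss != "-" else " "
        line[34:38] = f"{0:4d}"
        line[38:45] = f"{0:7d}"
        line[46:50] = f"{0.0:4.1f}"
        line[50:56] = f"{0:6d}"
        line[57:61] = f"{0.0:4.1f}"
        line[61:67] = f"{0:6d}"
        line[68:72] = f"{0.0:4.1f}"
        line[72:78] = f"{0:6d}"
        line[79:83] = f"{0.0:4.1f}"
        line[103:109] = f"{0.0:6.1f}"
        line[109:115] = f"{0.0:6.1f}"
        lines.append("".join(line))
    return "\n".join(lines) + "\n"


def micro_chain(
    n_residues: int,
    chain: str = "A",
    resnames=None,
    b_values=None,
    resolution: float = 1.8,
    growth_temp: float | None = None,
    thermal_class: str = "unknown",
    structure_id: str = "micro",
) -> Structure:
    """A minimal Cα-only chain for pairing/filter tests."""
    atoms = []
    for i in range(n_residues):
        name = resnames[i] if resnames else "ALA"
        atoms.append(
            AtomRecord(
                serial=i + 1,
                atom_name="CA",
                element="C",
                alt_loc="",
                residue_name=name,
                chain_id=chain,
                residue_seq=i + 1,
                insertion_code="",
                coords=np.array([3.8 * i, 0.0, 0.0]),
                occupancy=1.0,
                b_factor=float(b_values[i]) if b_values is not None else 20.0,
                is_hetero=False,
                is_water=False,
                vdw_radius=1.7,
            )
        )
    return Structure(
        id=structure_id,
        atoms=atoms,
        resolution=resolution,
        thermal_class=thermal_class,
        growth_temp=growth_temp,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
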