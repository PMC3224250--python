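"""Van der Waals radius sets.

The default set is Bondi's (1964) compilation, the most widely used
consistent table of atomic van der Waals radii.  Geometry downstream
(voids, SASA) only needs heavy-atom radii for the elements that occur in
protein crystal structures; anything else can be served by an explicit
fallback radius if the caller enables one.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RadiusSet:
    """A named element -> van der Waals radius (Å) lookup.

    ``by_atom_name`` allows overriding specific PDB atom names (e.g. to
    distinguish carbonyl from aliphatic carbons); it is empty in the
    default set.  ``fallback`` is used for unknown elements when set,
    otherwise lookup raises :class:`KeyError`.
    """

    name: str
    by_element: dict[str, float]
    by_atom_name: dict[str, float] = field(default_factory=dict)
    fallback: float | None = None

    def lookup(self, element: str, atom_name: str = "") -> float:
        if atom_name and atom_name in self.by_atom_name:
            return self.by_atom_name[atom_name]
        el = element.strip().upper()
        if el in self.by_element:
            return self.by_element[el]
        if self.fallback is not None:
            return self.fallback
        raise KeyError(element)


#: Bondi, A. (1964) J. Phys. Chem. 68, 441-451.
BONDI = RadiusSet(
    name="bondi",
    by_element={
        "H": 1.20,
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
        "P": 1.80,
        "F": 1.47,
        "CL": 1.75,
        "BR": 1.85,
        "I": 1.98,
        "SE": 1.90,
        "ZN": 1.39,
        "CU": 1.40,
        "FE": 1.50,
        "MG": 1.73,
        "NA": 2.27,
        "K": 2.75,
        "CA": 2.31,
        "MN": 1.50,
        "NI": 1.63,
    },
)

DEFAULT_RADII = BONDI
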