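"""Residue templates: heavy-atom graphs for the 20 standard amino acids.

The templates live in ``assets/residue_templates.json`` (documented there).
Each residue is stored in its free-acid form — backbone N, CA, C, carbonyl O
and hydroxyl OXT plus side chain — with integer bond orders. Hydrogens are
not part of the template; the peptide builder adds them to fill standard
valences after the chain has been assembled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files

__all__ = [
    "AMINO_ACIDS",
    "ResidueTemplate",
    "residue_template",
    "standard_valence",
    "three_letter_code",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ResidueTemplate:
    """Heavy-atom template of one residue in free-acid form."""

    name: str  # three-letter code
    atoms: tuple[tuple[str, str], ...]  # (atom name, element)
    bonds: tuple[tuple[str, str, int], ...]  # (name, name, order)

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atoms)


@lru_cache(maxsize=1)
def _load() -> dict:
    text = files("sspr").joinpath("assets/residue_templates.json").read_text()
    return json.loads(text)


def standard_valence(element: str) -> int:
    """Standard valence used for explicit-hydrogen completion."""
    try:
        return _load()["valence"][element]
    except KeyError:
        raise ValueError(f"no standard valence for element {element!r}") from None


def three_letter_code(one_letter: str) -> str:
    try:
        return _load()["one_letter"][one_letter]
    except KeyError:
        raise ValueError(f"non-standard residue code {one_letter!r}") from None


@lru_cache(maxsize=32)
def residue_template(one_letter: str) -> ResidueTemplate:
    """Return the template for a one-letter residue code.

    Raises ``ValueError`` for anything outside the 20 standard codes.
    """
    name = three_letter_code(one_letter)
    raw = _load()["residues"][name]
    atoms = tuple((a, el) for a, el in raw["atoms"].items())
    bonds = tuple((a, b, int(order)) for a, b, order in raw["bonds"])
    return ResidueTemplate(name=name, atoms=atoms, bonds=bonds)
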