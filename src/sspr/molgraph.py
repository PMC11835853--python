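"""Peptide windows and their molecular graphs.

A substitution is characterised by a short peptide cut from the protein
sequence, centred on the substituted residue. The window is turned into an
explicit-hydrogen molecular graph by chaining residue templates with peptide
bonds; the graph (not the sequence) is what the descriptor machinery sees.

Conventions: neutral free termini (H2N-…-COOH), fixed side-chain protonation
states as documented in the residue template file, 1-based protein positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .templates import AMINO_ACIDS, residue_template, standard_valence

__all__ = [
    "ProteinRecord",
    "PeptideWindow",
    "MolGraph",
    "SDFParseError",
    "extract_peptide_window",
    "build_molecular_graph",
    "read_fasta",
    "read_sdf",
    "write_sdf",
]

MIN_WINDOW = 5
MAX_WINDOW = 31


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with gene-level metadata.

    ``disease_frequency`` is the population frequency of the associated
    disease, used by the benign-by-frequency supplementation rule.
    """

    gene: str
    sequence: str
    disease_frequency: float | None = None
    omim_id: str | None = None
    uniprot_id: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.gene}: sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.gene}: non-standard residue code(s) {sorted(bad)!r}"
            )
        if self.disease_frequency is not None and not (
            0.0 < self.disease_frequency < 1.0
        ):
            raise ValueError(
                f"{self.gene}: disease_frequency must lie in (0, 1), "
                f"got {self.disease_frequency!r}"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """A peptide cut around a substitution, with the substitution applied.

    ``residues[center_offset]`` is the alternate residue; ``source_span`` is
    the 1-based inclusive span of the window in the parent protein.
    """

    residues: str
    center_offset: int
    source_span: tuple[int, int]
    length_config: int


class MolGraph:
    """Undirected labelled molecular graph with explicit hydrogens.

    Atoms are integer-id'd element labels; bonds are unordered atom-id pairs
    carrying an integer order. Descriptor generation uses only the
    bonded-neighbour relation; orders exist so SD files stay chemically sane.
    """

    def __init__(self) -> None:
        self._elements: list[str] = []
        self._adj: list[list[int]] = []
        self._orders: dict[tuple[int, int], int] = {}

    # -- construction -------------------------------------------------
    def add_atom(self, element: str) -> int:
        self._elements.append(element)
        self._adj.append([])
        return len(self._elements) - 1

    def add_bond(self, a: int, b: int, order: int = 1) -> None:
        if a == b:
            raise ValueError(f"self-loop on atom {a}")
        key = (min(a, b), max(a, b))
        if key in self._orders:
            raise ValueError(f"duplicate bond {key}")
        for i in key:
            if not 0 <= i < len(self._elements):
                raise ValueError(f"unknown atom id {i}")
        self._orders[key] = order
        self._adj[a].append(b)
        self._adj[b].append(a)

    @classmethod
    def from_atoms_bonds(
        cls,
        elements: Sequence[str],
        bonds: Iterable[tuple[int, int] | tuple[int, int, int]],
    ) -> "MolGraph":
        g = cls()
        for el in elements:
            g.add_atom(el)
        for bond in bonds:
            a, b, *rest = bond
            g.add_bond(a, b, rest[0] if rest else 1)
        return g

    # -- inspection ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self._elements)

    @property
    def atoms(self) -> list[tuple[int, str]]:
        return list(enumerate(self._elements))

    @property
    def bonds(self) -> set[tuple[int, int]]:
        return set(self._orders)

    def element(self, atom_id: int) -> str:
        try:
            return self._elements[atom_id]
        except IndexError:
            raise ValueError(f"unknown atom id {atom_id}") from None

    def neighbors(self, atom_id: int) -> list[int]:
        return self._adj[atom_id]

    def bond_order(self, a: int, b: int) -> int:
        return self._orders[(min(a, b), max(a, b))]

    def degree(self, atom_id: int) -> int:
        return len(self._adj[atom_id])

    def element_counts(self) -> Counter:
        return Counter(self._elements)

    def heavy_atom_ids(self) -> list[int]:
        return [i for i, el in enumerate(self._elements) if el != "H"]

    def is_connected(self) -> bool:
        if not self._elements:
            return True
        seen = {0}
        stack = [0]
        while stack:
            for n in self._adj[stack.pop()]:
                if n not in seen:
                    seen.add(n)
                    stack.append(n)
        return len(seen) == self.n_atoms

    def relabel(self, perm: Sequence[int]) -> "MolGraph":
        """Return an isomorphic copy with atom ``i`` renamed ``perm[i]``."""
        if sorted(perm) != list(range(self.n_atoms)):
            raise ValueError("perm must be a permutation of the atom ids")
        inv = [0] * self.n_atoms
        for old, new in enumerate(perm):
            inv[new] = old
        g = MolGraph()
        for new in range(self.n_atoms):
            g.add_atom(self._elements[inv[new]])
        for (a, b), order in self._orders.items():
            g.add_bond(perm[a], perm[b], order)
        return g


# ---------------------------------------------------------------------------
# peptide windows
# ---------------------------------------------------------------------------

def extract_peptide_window(
    protein: ProteinRecord, pos: int, alt: str, pl: int
) -> PeptideWindow:
    """Cut the length-``pl`` peptide around position ``pos`` and apply ``alt``.

    Interior positions get ``(pl - 1) / 2`` residues on each side. Near an
    edge the deficit is borrowed from the other side so the window keeps its
    full length; only when the protein itself is shorter than ``pl`` is the
    whole (substituted) sequence returned.
    """
    if pl % 2 == 0 or not MIN_WINDOW <= pl <= MAX_WINDOW:
        raise ValueError(
            f"peptide length must be odd and in [{MIN_WINDOW}, {MAX_WINDOW}], got {pl}"
        )
    seq = protein.sequence
    if not 1 <= pos <= len(seq):
        raise ValueError(
            f"position {pos} outside {protein.gene} (length {len(seq)})"
        )
    if alt not in AMINO_ACIDS:
        raise ValueError(f"non-standard alternate residue {alt!r}")
    ref = seq[pos - 1]
    if alt == ref:
        raise ValueError(
            f"{protein.gene} position {pos}: alternate equals reference "
            f"({ref!r}); substitution is synonymous"
        )

    half = (pl - 1) // 2
    start = pos - half
    end = pos + half
    if start < 1:
        end = min(len(seq), end + (1 - start))
        start = 1
    if end > len(seq):
        start = max(1, start - (end - len(seq)))
        end = len(seq)
    residues = seq[start - 1 : end]
    offset = pos - start
    residues = residues[:offset] + alt + residues[offset + 1 :]
    return PeptideWindow(
        residues=residues,
        center_offset=offset,
        source_span=(start, end),
        length_config=pl,
    )


# ---------------------------------------------------------------------------
# molecular graphs
# ---------------------------------------------------------------------------

def build_molecular_graph(window: PeptideWindow | str) -> MolGraph:
    """Build the explicit-hydrogen molecular graph of a peptide.

    Residue templates are chained with C'-N peptide bonds (each join drops
    the leaving residue's hydroxyl OXT); hydrogens are then added until every
    heavy atom reaches its standard valence, counting bond orders.
    """
    residues = window.residues if isinstance(window, PeptideWindow) else window
    if not residues:
        raise ValueError("empty peptide")
    for aa in residues:
        residue_template(aa)  # raises for non-standard codes
    return _assemble(residues)


def _assemble(residues: str) -> MolGraph:
    graph = MolGraph()
    prev_c: int | None = None
    n_res = len(residues)
    for i, aa in enumerate(residues):
        tmpl = residue_template(aa)
        terminal = i == n_res - 1
        ids: dict[str, int] = {}
        for name, el in tmpl.atoms:
            if name == "OXT" and not terminal:
                continue  # the peptide bond displaces the hydroxyl
            ids[name] = graph.add_atom(el)
        for a, b, order in tmpl.bonds:
            if "OXT" in (a, b) and not terminal:
                continue
            graph.add_bond(ids[a], ids[b], order)
        if prev_c is not None:
            graph.add_bond(prev_c, ids["N"], 1)
        prev_c = ids["C"]
    # explicit hydrogens up to standard valence
    for atom_id, el in list(graph.atoms):
        used = sum(
            graph.bond_order(atom_id, n) for n in graph.neighbors(atom_id)
        )
        missing = standard_valence(el) - used
        if missing < 0:
            raise ValueError(
                f"valence overflow on atom {atom_id} ({el}): {used}"
            )
        for _ in range(missing):
            h = graph.add_atom("H")
            graph.add_bond(atom_id, h, 1)
    return graph


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source) -> dict[str, str]:
    """Read protein sequences keyed by record id (gene symbol)."""
    from Bio import SeqIO

    if hasattr(source, "read"):
        handle = source
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(handle, "fasta")}
    with open(source) as handle:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(handle, "fasta")}


# ---------------------------------------------------------------------------
# MDL SD files (V2000)
# ---------------------------------------------------------------------------

class SDFParseError(ValueError):
    """Raised when an SD file record cannot be parsed."""


def write_sdf(
    graphs: Sequence[MolGraph],
    tags: Sequence[dict] | None,
    sink: TextIO | str,
) -> None:
    """Write graphs as V2000 molfile records with zero 2D coordinates.

    ``tags`` supplies one dict of SD data fields per record (or ``None``).
    """
    if tags is None:
        tags = [{} for _ in graphs]
    if len(tags) != len(graphs):
        raise ValueError("one tag dict per graph required")
    own = isinstance(sink, str)
    out = open(sink, "w") if own else sink
    try:
        for graph, fields in zip(graphs, tags):
            _write_record(graph, fields, out)
    finally:
        if own:
            out.close()


def _write_record(graph: MolGraph, fields: dict, out: TextIO) -> None:
    n_atoms, n_bonds = graph.n_atoms, len(graph.bonds)
    if n_atoms > 999 or n_bonds > 999:
        raise ValueError("V2000 molfiles cap atom/bond counts at 999")
    name = str(fields.get("name", ""))
    out.write(f"{name}\n  sspr\n\n")
    out.write(f"{n_atoms:>3}{n_bonds:>3}  0  0  0  0  0  0  0  0999 V2000\n")
    for _, el in graph.atoms:
        out.write(
            f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {el:<3} 0  0  0  0  0  0  0  0  0  0  0  0\n"
        )
    for a, b in sorted(graph.bonds):
        order = graph.bond_order(a, b)
        out.write(f"{a + 1:>3}{b + 1:>3}{order:>3}  0\n")
    out.write("M  END\n")
    for key, value in fields.items():
        if key == "name":
            continue
        out.write(f">  <{key}>\n{value}\n\n")
    out.write("$$$$\n")


def read_sdf(source) -> list[tuple[MolGraph, dict]]:
    """Parse a V2000 SD file written by :func:`write_sdf` (or compatible)."""
    own = isinstance(source, str)
    handle = open(source) if own else source
    try:
        text = handle.read()
    finally:
        if own:
            handle.close()
    records: list[tuple[MolGraph, dict]] = []
    blocks = [b for b in text.split("$$$$\n") if b.strip()]
    for idx, block in enumerate(blocks):
        try:
            records.append(_parse_record(block))
        except (IndexError, ValueError) as exc:
            raise SDFParseError(f"record {idx}: {exc}") from None
    return records


def _parse_record(block: str) -> tuple[MolGraph, dict]:
    lines = block.splitlines()
    if len(lines) < 4:
        raise ValueError("truncated header")
    counts = lines[3]
    if "V2000" not in counts:
        raise ValueError(f"not a V2000 counts line: {counts!r}")
    n_atoms = int(counts[0:3])
    n_bonds = int(counts[3:6])
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ValueError(
            f"counts line promises {n_atoms} atoms / {n_bonds} bonds "
            "but the block is shorter"
        )
    graph = MolGraph()
    for line in lines[4 : 4 + n_atoms]:
        element = line[31:34].strip()
        if not element:
            raise ValueError(f"atom line without element: {line!r}")
        graph.add_atom(element)
    for line in lines[4 + n_atoms : 4 + n_atoms + n_bonds]:
        a = int(line[0:3]) - 1
        b = int(line[3:6]) - 1
        order = int(line[6:9])
        graph.add_bond(a, b, order)
    fields: dict[str, str] = {}
    name = lines[0].strip()
    if name:
        fields["name"] = name
    rest = lines[4 + n_atoms + n_bonds :]
    i = 0
    while i < len(rest):
        line = rest[i]
        if line.startswith(">"):
            key = line[line.find("<") + 1 : line.rfind(">")]
            values = []
            i += 1
            while i < len(rest) and rest[i].strip() != "":
                values.append(rest[i])
                i += 1
            fields[key] = "\n".join(values)
        i += 1
    return graph, fields
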