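"""Multilevel neighborhoods-of-atoms (MNA) descriptors.

An MNA descriptor describes an atom together with everything reachable within
``level`` covalent bonds. Level 0 is the bare element label; level ``k`` is

    label(d1,d2,...,dn)

where ``d1..dn`` are the level-``k-1`` descriptors of all bonded neighbours
(hydrogens included as neighbours, never as centres), sorted
lexicographically. The descriptor is canonical: it does not depend on the
order in which atoms or bonds were entered.

Because the recursion revisits the atom it came from, a rendered descriptor
string grows roughly like (mean degree)**level — a level-15 descriptor of a
peptide graph expands to megabytes. Descriptor *sets* therefore carry compact
canonical keys: the exact text whenever it is short, otherwise a
'#'-prefixed blake2b hash of the canonical form. Keys are deterministic
functions of descriptor content, so they agree across graphs, processes and
serialisation round trips; rendered texts remain available through
:func:`mna_descriptor` and :func:`descriptor_strings`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .molgraph import MolGraph

__all__ = [
    "MNADescriptor",
    "DescriptorSet",
    "MODEL_LEVELS",
    "mna_descriptor",
    "descriptor_set",
    "descriptor_sets",
    "descriptor_strings",
    "dump_descriptors",
]

#: Descriptor levels used for model building (testing may use any level >= 0).
MODEL_LEVELS = range(5, 16)

#: Keys longer than this are replaced by a content hash.
_TEXT_KEY_MAX = 96


@dataclass(frozen=True)
class MNADescriptor:
    """One canonical descriptor: its rendered text and its level."""

    text: str
    level: int


@dataclass(frozen=True)
class DescriptorSet:
    """The unique canonical descriptors of one graph at one level.

    ``items`` holds canonical keys (short descriptors verbatim, long ones
    content-hashed); see the module docstring.
    """

    level: int
    items: frozenset[str]

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("descriptor level must be >= 0")
        if not self.items:
            raise ValueError("descriptor set of an empty graph")


def _hash_key(label: str, child_keys: Sequence[str]) -> str:
    h = hashlib.blake2b(digest_size=16)
    h.update(label.encode())
    for key in child_keys:
        h.update(b"\x00")
        h.update(key.encode())
    return "#" + h.hexdigest()


def _level_tables(graph: MolGraph, max_level: int):
    """Per-level canonical ranks, keys and rendered lengths for every atom.

    Ranks order the distinct descriptors of one level exactly as their
    rendered strings would sort; they drive child ordering. Keys are the
    cross-graph canonical identities. The invariant making rank comparison
    exact is that no rendered descriptor of a level is a proper prefix of
    another at the same level, and ')' < ',' in ASCII, so tuple comparison of
    (label, child ranks) reproduces string comparison.
    """
    n = graph.n_atoms
    if n == 0:
        raise ValueError("empty graph")
    labels = [graph.element(i) for i in range(n)]
    adj = [graph.neighbors(i) for i in range(n)]

    uniq0 = sorted(set(labels))
    rank = [[uniq0.index(l) for l in labels]]
    keys = [list(labels)]
    lengths = [[len(l) for l in labels]]

    for _ in range(max_level):
        prev_rank, prev_key, prev_len = rank[-1], keys[-1], lengths[-1]
        sigs = []
        for i in range(n):
            children = sorted(prev_rank[j] for j in adj[i])
            sigs.append((labels[i], tuple(children)))
        order = {sig: r for r, sig in enumerate(sorted(set(sigs)))}
        rank.append([order[s] for s in sigs])
        new_keys, new_lens = [], []
        for i in range(n):
            child_ids = sorted(adj[i], key=prev_rank.__getitem__)
            child_keys = [prev_key[j] for j in child_ids]
            # rendered length: label + parens + children + commas
            length = len(labels[i]) + 2 + sum(prev_len[j] for j in child_ids)
            length += max(0, len(child_ids) - 1)
            if length <= _TEXT_KEY_MAX and all(
                not k.startswith("#") for k in child_keys
            ):
                key = f"{labels[i]}({','.join(child_keys)})"
            else:
                key = _hash_key(labels[i], child_keys)
            new_keys.append(key)
            new_lens.append(length)
        keys.append(new_keys)
        lengths.append(new_lens)
    return rank, keys, lengths


def _render(graph: MolGraph, atom_id: int, level: int, rank) -> str:
    """Fully render one descriptor text (exponential in ``level``)."""
    label = graph.element(atom_id)
    if level == 0:
        return label
    children = sorted(graph.neighbors(atom_id), key=rank[level - 1].__getitem__)
    inner = ",".join(_render(graph, j, level - 1, rank) for j in children)
    return f"{label}({inner})"


def mna_descriptor(graph: MolGraph, atom_id: int, level: int) -> MNADescriptor:
    """The canonical level-``level`` descriptor of one non-hydrogen atom.

    Returns the fully rendered text; intended for inspection and testing at
    small levels (rendering is exponential in ``level``).
    """
    if level < 0:
        raise ValueError("descriptor level must be >= 0")
    element = graph.element(atom_id)  # raises for unknown ids
    if element == "H":
        raise ValueError("hydrogen atoms are never descriptor centres")
    rank, _, _ = _level_tables(graph, level)
    return MNADescriptor(text=_render(graph, atom_id, level, rank), level=level)


def descriptor_sets(
    graph: MolGraph, levels: Iterable[int]
) -> dict[int, DescriptorSet]:
    """Descriptor sets for several levels in one canonicalisation pass."""
    levels = sorted(set(levels))
    if not levels:
        return {}
    if levels[0] < 0:
        raise ValueError("descriptor level must be >= 0")
    _, keys, _ = _level_tables(graph, levels[-1])
    heavy = graph.heavy_atom_ids()
    if not heavy:
        raise ValueError("graph has no non-hydrogen atoms")
    return {
        lv: DescriptorSet(level=lv, items=frozenset(keys[lv][i] for i in heavy))
        for lv in levels
    }


def descriptor_set(graph: MolGraph, level: int) -> DescriptorSet:
    """Unique canonical descriptors over all non-hydrogen centres."""
    return descriptor_sets(graph, [level])[level]


def descriptor_strings(graph: MolGraph, level: int) -> frozenset[str]:
    """Fully rendered descriptor texts (use at small levels only)."""
    rank, _, _ = _level_tables(graph, level)
    return frozenset(
        _render(graph, i, level, rank) for i in graph.heavy_atom_ids()
    )


def dump_descriptors(
    graph: MolGraph, levels: Iterable[int], sink: TextIO
) -> None:
    """Write ``level<TAB>count<TAB>text`` lines for debugging/golden files.

    Counts are the number of non-hydrogen centres sharing the descriptor.
    """
    levels = sorted(set(levels))
    rank, _, _ = _level_tables(graph, levels[-1]) if levels else ([], [], [])
    for lv in levels:
        texts: dict[str, int] = {}
        for i in graph.heavy_atom_ids():
            t = _render(graph, i, lv, rank)
            texts[t] = texts.get(t, 0) + 1
        for t in sorted(texts):
            sink.write(f"{lv}\t{texts[t]}\t{t}\n")
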