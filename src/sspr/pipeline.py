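"""Composing the stages: variants -> windows -> graphs -> descriptor sets."""

from __future__ import annotations

from typing import Callable, Sequence

from .bayes import ModelConfig
from .data import Variant
from .mna import DescriptorSet, descriptor_set
from .molgraph import (
    MolGraph,
    ProteinRecord,
    build_molecular_graph,
    extract_peptide_window,
)

__all__ = ["variant_graph", "make_examples", "make_provider"]


def variant_graph(protein: ProteinRecord, variant: Variant, pl: int) -> MolGraph:
    """Molecular graph of the substituted peptide window of one variant."""
    window = extract_peptide_window(protein, variant.position, variant.alt, pl)
    return build_molecular_graph(window)


def make_examples(
    protein: ProteinRecord,
    variants: Sequence[Variant],
    config: ModelConfig,
) -> list[tuple[DescriptorSet, str]]:
    """Labelled descriptor sets for the classifier (unknown labels excluded)."""
    examples = []
    for v in variants:
        if v.label == "unknown":
            continue
        graph = variant_graph(protein, v, config.pl)
        examples.append((descriptor_set(graph, config.level), v.label))
    return examples


def make_provider(
    protein: ProteinRecord, variants: Sequence[Variant]
) -> Callable[[int], list[tuple[MolGraph, str]]]:
    """Per-window-length dataset provider for the grid search."""
    labelled = [v for v in variants if v.label != "unknown"]

    def provider(pl: int) -> list[tuple[MolGraph, str]]:
        return [(variant_graph(protein, v, pl), v.label) for v in labelled]

    return provider
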