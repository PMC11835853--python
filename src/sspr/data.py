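"""Variant tables, curation rules, and a synthetic data generator.

Curation follows two rules: variants without a clinical label are relabelled
benign when their population allele frequency strictly exceeds the frequency
of the disease ("benign by frequency", the B+ class), and a training set
should contain at least 75 labelled missense variants.

The synthetic generator emulates a ClinVar/gnomAD-style extract for one
protein: a random sequence, missense variants whose ground-truth labels come
from a plantable rule (substitution falls inside a functional motif *and*
introduces a damaging residue type), optional label noise, and allele
frequencies drawn so that truly benign variants tend to exceed the disease
frequency while pathogenic ones stay rare.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bayes import BENIGN, PATHOGENIC
from .molgraph import ProteinRecord
from .templates import AMINO_ACIDS

__all__ = [
    "UNKNOWN",
    "MIN_LABELED_VARIANTS",
    "Variant",
    "SyntheticSpec",
    "load_variants",
    "load_gene_config",
    "supplement_benign",
    "gate_min_variants",
    "generate_synthetic",
]

UNKNOWN = "unknown"

#: Minimum labelled (pathogenic + benign) variants for a trainable gene.
MIN_LABELED_VARIANTS = 75

_REQUIRED_COLUMNS = ["gene", "position", "ref", "alt", "label"]


@dataclass(frozen=True)
class Variant:
    """One missense substitution with an optional clinical label."""

    gene: str
    position: int  # 1-based
    ref: str
    alt: str
    label: str = UNKNOWN
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(
                f"{self.gene} p.{self.ref}{self.position}{self.alt}: "
                "not a missense change (ref == alt)"
            )
        for residue in (self.ref, self.alt):
            if residue not in AMINO_ACIDS:
                raise ValueError(f"non-standard residue code {residue!r}")
        if self.label not in (PATHOGENIC, BENIGN, UNKNOWN):
            raise ValueError(f"unknown label {self.label!r}")
        if self.allele_frequency is not None and not (
            0.0 <= self.allele_frequency <= 1.0
        ):
            raise ValueError(
                f"allele_frequency must lie in [0, 1], got {self.allele_frequency!r}"
            )


def load_variants(
    table, proteins: Mapping[str, ProteinRecord] | Mapping[str, str]
) -> list[Variant]:
    """Read and validate a variant CSV against the protein sequences.

    Expected header: ``gene,position,ref,alt,label,allele_frequency`` (the
    frequency column may be absent or empty; empty labels mean unknown).
    Rows failing the missense, alphabet or reference-match checks are dropped
    with a row-indexed warning; duplicate (gene, position, alt) rows keep the
    first occurrence. Missing required columns raise ``ValueError``.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table lacks column(s) {missing}")
    sequences = {
        g: (p.sequence if isinstance(p, ProteinRecord) else p)
        for g, p in proteins.items()
    }
    variants: list[Variant] = []
    seen: set[tuple[str, int, str]] = set()
    for row_idx, row in enumerate(df.itertuples(index=False)):
        try:
            gene = str(row.gene)
            if gene not in sequences:
                raise ValueError(f"unknown gene {gene!r}")
            position = int(row.position)
            seq = sequences[gene]
            if not 1 <= position <= len(seq):
                raise ValueError(
                    f"position {position} outside {gene} (length {len(seq)})"
                )
            ref = str(row.ref)
            if ref != seq[position - 1]:
                raise ValueError(
                    f"reference residue {ref!r} disagrees with the {gene} "
                    f"sequence ({seq[position - 1]!r} at position {position})"
                )
            label = getattr(row, "label", None)
            label = UNKNOWN if label is None or pd.isna(label) or label == "" else str(label)
            af = getattr(row, "allele_frequency", None)
            af = None if af is None or pd.isna(af) else float(af)
            variant = Variant(
                gene=gene,
                position=position,
                ref=ref,
                alt=str(row.alt),
                label=label,
                allele_frequency=af,
            )
        except ValueError as exc:
            warnings.warn(f"row {row_idx}: rejected ({exc})", stacklevel=2)
            continue
        key = (variant.gene, variant.position, variant.alt)
        if key in seen:
            warnings.warn(
                f"row {row_idx}: duplicate {key}, keeping first occurrence",
                stacklevel=2,
            )
            continue
        seen.add(key)
        variants.append(variant)
    return variants


def load_gene_config(source) -> dict[str, dict]:
    """Read the per-gene registry CSV.

    Columns: ``gene,disease_frequency`` plus optional ``omim_id,uniprot_id``.
    """
    df = pd.read_csv(source, dtype={"omim_id": str, "uniprot_id": str})
    if "gene" not in df.columns or "disease_frequency" not in df.columns:
        raise ValueError("gene config needs columns gene,disease_frequency")
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        entry = {"disease_frequency": float(row.disease_frequency)}
        for key in ("omim_id", "uniprot_id"):
            value = getattr(row, key, None)
            entry[key] = None if value is None or pd.isna(value) else str(value)
        out[str(row.gene)] = entry
    return out


def supplement_benign(
    variants: Iterable[Variant], disease_frequency: float
) -> list[Variant]:
    """Relabel unknown variants benign when AF strictly exceeds the disease
    frequency (the B+ rule); everything else is returned unchanged.

    Unknown variants without an allele frequency stay unknown (warned).
    """
    if not 0.0 < disease_frequency < 1.0:
        raise ValueError(
            f"disease_frequency must lie in (0, 1), got {disease_frequency!r}"
        )
    out = []
    for v in variants:
        if v.label != UNKNOWN:
            out.append(v)
            continue
        if v.allele_frequency is None:
            warnings.warn(
                f"{v.gene} p.{v.ref}{v.position}{v.alt}: unlabelled variant "
                "without allele frequency stays unknown",
                stacklevel=2,
            )
            out.append(v)
        elif v.allele_frequency > disease_frequency:
            out.append(
                Variant(
                    gene=v.gene,
                    position=v.position,
                    ref=v.ref,
                    alt=v.alt,
                    label=BENIGN,
                    allele_frequency=v.allele_frequency,
                )
            )
        else:
            out.append(v)
    return out


def gate_min_variants(
    variants: Iterable[Variant], minimum: int = MIN_LABELED_VARIANTS
) -> bool:
    """True when the labelled (pathogenic + benign) count reaches ``minimum``.

    Advisory in the library (the trainer decides whether to enforce it).
    """
    n = sum(v.label in (PATHOGENIC, BENIGN) for v in variants)
    if n < minimum:
        warnings.warn(
            f"only {n} labelled variants (< {minimum}); models trained on "
            "this set may be unreliable",
            stacklevel=2,
        )
        return False
    return True


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

_ALPHABET = "".join(sorted(AMINO_ACIDS))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic gene.

    The pathogenicity rule: a substitution is truly pathogenic iff its
    position falls inside ``motif_span`` (1-based, inclusive) *and* the
    alternate residue belongs to ``damaging`` — a functional motif whose
    disruption by chemically drastic residue types causes disease. The
    default damaging set is every residue outside the conservative
    small-aliphatic/hydroxyl group {A, S, T, V, I, L, M}: inside a functional
    motif only conservative replacements are tolerated. Labels are
    then flipped with probability ``label_noise`` (annotation error).
    Allele frequencies: truly benign variants are drawn log-uniformly from
    ``benign_af_range`` (above a typical rare-disease frequency), pathogenic
    ones from ``pathogenic_af_range``. ``unknown_fraction`` masks that share
    of benign-labelled variants to "unknown" so the frequency-supplementation
    rule has work to do.
    """

    seq_length: int = 120
    motif_span: tuple[int, int] = (41, 71)
    damaging: frozenset[str] = frozenset("CDEFGHKNPQRWY")
    n_variants: int = 200
    label_noise: float = 0.0
    seed: int = 0
    gene: str = "SYN1"
    disease_frequency: float = 1e-5
    benign_af_range: tuple[float, float] = (1e-4, 1e-2)
    pathogenic_af_range: tuple[float, float] = (1e-9, 1e-6)
    unknown_fraction: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.motif_span
        if not 1 <= lo <= hi <= self.seq_length:
            raise ValueError(f"motif span {self.motif_span} outside the sequence")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError(
                f"label_noise must lie in [0, 0.5), got {self.label_noise!r}"
            )
        if self.n_variants < 2:
            raise ValueError("need at least 2 variants")
        if self.n_variants > self.seq_length * 19:
            raise ValueError(
                f"cannot draw {self.n_variants} distinct substitutions from a "
                f"{self.seq_length}-residue sequence"
            )
        if not self.damaging <= AMINO_ACIDS:
            raise ValueError("damaging residues must be standard amino acids")
        if not 0.0 <= self.unknown_fraction <= 1.0:
            raise ValueError("unknown_fraction must lie in [0, 1]")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def generate_synthetic(spec: SyntheticSpec) -> tuple[ProteinRecord, list[Variant]]:
    """Generate one protein and its variant set; fully seeded, reproducible."""
    rng = np.random.default_rng(spec.seed)
    seq = "".join(rng.choice(list(_ALPHABET), size=spec.seq_length))
    protein = ProteinRecord(
        gene=spec.gene,
        sequence=seq,
        disease_frequency=spec.disease_frequency,
    )
    # distinct (position, alternate) pairs, uniform over the 19 non-reference
    # residues at each position
    flat = rng.choice(
        spec.seq_length * 19, size=spec.n_variants, replace=False
    )
    lo, hi = spec.motif_span
    variants: list[Variant] = []
    for code in sorted(int(c) for c in flat):
        position = code // 19 + 1
        ref = seq[position - 1]
        alternates = [a for a in _ALPHABET if a != ref]
        alt = alternates[code % 19]
        truly_pathogenic = lo <= position <= hi and alt in spec.damaging
        label = PATHOGENIC if truly_pathogenic else BENIGN
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = BENIGN if label == PATHOGENIC else PATHOGENIC
        af_range = (
            spec.pathogenic_af_range if truly_pathogenic else spec.benign_af_range
        )
        af = _log_uniform(rng, *af_range)
        if (
            label == BENIGN
            and spec.unknown_fraction > 0
            and rng.random() < spec.unknown_fraction
        ):
            label = UNKNOWN
        variants.append(
            Variant(
                gene=spec.gene,
                position=position,
                ref=ref,
                alt=alt,
                label=label,
                allele_frequency=af,
            )
        )
    return protein, variants
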