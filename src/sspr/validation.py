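"""Model validation: IAP (ROC AUC), cross-validation, grid search, metrics.

IAP — the probability that a randomly drawn positive example outscores a
randomly drawn negative one, ties counted half — is numerically the
tie-corrected ROC AUC and is the quantity every cross-validation scheme here
reports. Leave-one-out uses an exact decrement path: the held-out example's
descriptors are removed from the global counts before scoring, which
reproduces a full retrain of the scorer without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from . import bayes
from .bayes import BENIGN, PATHOGENIC, ModelConfig
from .mna import DescriptorSet, descriptor_sets
from .molgraph import MolGraph

__all__ = [
    "DEFAULT_PLS",
    "DEFAULT_LEVELS",
    "CVResult",
    "GridResult",
    "iap",
    "loo_auc",
    "loo_predictions",
    "kfold_auc",
    "grid_search",
    "classification_metrics",
    "grid_report_csv",
]

#: Canonical model-selection axes: 14 odd window lengths x 11 levels = 154.
DEFAULT_PLS = tuple(range(5, 32, 2))
DEFAULT_LEVELS = tuple(range(5, 16))


@dataclass(frozen=True)
class CVResult:
    auc: float
    scheme: str
    per_example_scores: tuple[tuple[int, float, str], ...]  # (id, S, label)


@dataclass(frozen=True)
class GridResult:
    cells: dict[tuple[int, int], float]  # (pl, level) -> AUC_LOO
    best: tuple[int, int]
    n_cells: int
    invalid: frozenset[tuple[int, int]] = frozenset()


def iap(scored: Sequence[tuple[float, int]]) -> float:
    """Tie-corrected pairwise win probability == ROC AUC.

    ``scored`` pairs each score with a binary label (1 positive, 0 negative).
    Computed from average ranks, which equals the brute-force pairwise count
    (wins + half ties) / (n_pos * n_neg) exactly.
    """
    if not scored:
        raise ValueError("no scored examples")
    scores = np.asarray([s for s, _ in scored], dtype=float)
    labels = np.asarray([l for _, l in scored], dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("IAP needs at least one example of each label")
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _labels_to_binary(label: str) -> int:
    return 1 if label == PATHOGENIC else 0


def loo_auc(
    examples: Sequence[tuple[DescriptorSet, str]], config: ModelConfig
) -> CVResult:
    """Leave-one-out AUC via exact count decrements.

    Each example is scored by the model trained on the remaining n-1
    examples; removing one example only decrements the descriptor counts it
    contributed, so the held-out score can be computed from the full-data
    counts without refitting. Equality with a naive retrain is exact.
    """
    labels = [label for _, label in examples]
    n_path = sum(l == PATHOGENIC for l in labels)
    n_ben = len(labels) - n_path
    if n_path < 2 or n_ben < 2:
        raise ValueError(
            "leave-one-out needs at least 2 examples per class "
            f"(got {n_path} pathogenic, {n_ben} benign)"
        )
    model = bayes.fit(examples, config)
    min_count = config.min_count
    per_example = []
    for idx, (dset, label) in enumerate(examples):
        is_path = label == PATHOGENIC
        total = 0.0
        for d in sorted(dset.items):  # fixed order: bit-reproducible sums
            nd = model.n_d[d] - 1  # this example always contains d
            if nd < min_count:
                continue
            ndp = model.n_d_path.get(d, 0) - is_path
            total += (2 * ndp - nd) / (nd + 2)
        per_example.append((idx, total / len(dset.items), label))
    auc = iap([(s, _labels_to_binary(l)) for _, s, l in per_example])
    return CVResult(auc=auc, scheme="loo", per_example_scores=tuple(per_example))


def loo_predictions(
    examples: Sequence[tuple[DescriptorSet, str]], config: ModelConfig
) -> list[tuple[int, "bayes.Prediction", str]]:
    """Out-of-fold Pa/Pi/Confidence for every example (leave-one-out).

    Unlike :func:`loo_auc`, the full Pa/Pi computation needs the held-out
    model's training-score ECDFs, so each example's model is refit from the
    remaining n-1 examples. Quadratic in n; intended for reporting
    threshold-0 classification metrics, not for grid search.
    """
    out = []
    for i, (dset, label) in enumerate(examples):
        rest = [ex for j, ex in enumerate(examples) if j != i]
        model = bayes.fit(rest, config)
        out.append((i, bayes.predict(model, dset), label))
    return out


def _canonical_order(examples: Sequence[tuple[DescriptorSet, str]]) -> list[int]:
    """Input-order-independent ordering of example indices."""
    return sorted(
        range(len(examples)),
        key=lambda i: (examples[i][1], tuple(sorted(examples[i][0].items))),
    )


def kfold_auc(
    examples: Sequence[tuple[DescriptorSet, str]],
    k: int,
    seed: int,
    config: ModelConfig,
) -> CVResult:
    """Stratified k-fold AUC over pooled out-of-fold scores.

    Folds come from a seeded shuffle of a canonical (input-order-independent)
    sort of the examples, stratified by class, so the result depends only on
    the example multiset and the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = [label for _, label in examples]
    for cls in (PATHOGENIC, BENIGN):
        if sum(l == cls for l in labels) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
    rng = np.random.default_rng(seed)
    fold_of = [0] * len(examples)
    order = _canonical_order(examples)
    for cls in (PATHOGENIC, BENIGN):
        members = [i for i in order if examples[i][1] == cls]
        perm = rng.permutation(len(members))
        for slot, m in enumerate(perm):
            fold_of[members[m]] = slot % k
    per_example = []
    for fold in range(k):
        train = [ex for i, ex in enumerate(examples) if fold_of[i] != fold]
        model = bayes.fit(train, config)
        for i, (dset, label) in enumerate(examples):
            if fold_of[i] == fold:
                per_example.append((i, bayes.score(model, dset), label))
    per_example.sort()
    auc = iap([(s, _labels_to_binary(l)) for _, s, l in per_example])
    return CVResult(
        auc=auc,
        scheme=f"kfold(k={k}, seed={seed})",
        per_example_scores=tuple(per_example),
    )


def grid_search(
    examples_by_pl: Callable[[int], Sequence[tuple[MolGraph, str]]],
    pls: Iterable[int] = DEFAULT_PLS,
    levels: Iterable[int] = DEFAULT_LEVELS,
    min_count: int = 1,
) -> GridResult:
    """Leave-one-out AUC for every (window length, level) cell.

    ``examples_by_pl`` supplies, for each window length, the labelled
    molecular graphs; descriptors for all levels are derived in one pass per
    graph. Cells whose dataset violates the LOO preconditions are marked
    invalid and excluded from the argmax. Ties break toward the smaller
    window, then the smaller level.
    """
    pls = sorted(set(pls))
    levels = sorted(set(levels))
    if not pls or not levels:
        raise ValueError("empty grid")
    cells: dict[tuple[int, int], float] = {}
    invalid: set[tuple[int, int]] = set()
    for pl in pls:
        data = list(examples_by_pl(pl))
        multi = [(descriptor_sets(g, levels), label) for g, label in data]
        for level in levels:
            config = ModelConfig(pl=pl, level=level, min_count=min_count)
            examples = [(dsets[level], label) for dsets, label in multi]
            try:
                cells[(pl, level)] = loo_auc(examples, config).auc
            except ValueError:
                invalid.add((pl, level))
    if not cells:
        raise ValueError("every grid cell was invalid")
    best = min(cells, key=lambda c: (-cells[c], c[0], c[1]))
    return GridResult(
        cells=cells,
        best=best,
        n_cells=len(cells) + len(invalid),
        invalid=frozenset(invalid),
    )


def classification_metrics(
    confidences: Sequence[float],
    labels: Sequence[str] | Sequence[int],
    threshold: float = 0.0,
) -> dict[str, float]:
    """Balanced accuracy, Matthews correlation and F-measure at a threshold.

    Positive prediction means confidence strictly above ``threshold`` (the
    natural cut for Pa - Pi is 0). MCC is defined as 0 when any confusion
    marginal vanishes; F is 0 when precision + recall is 0.
    """
    y = [
        l if isinstance(l, (int, np.integer)) else _labels_to_binary(l)
        for l in labels
    ]
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    pred = [1 if c > threshold else 0 for c in confidences]
    tp = sum(p and t for p, t in zip(pred, y))
    tn = sum((not p) and (not t) for p, t in zip(pred, y))
    fp = sum(p and (not t) for p, t in zip(pred, y))
    fn = sum((not p) and t for p, t in zip(pred, y))
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    ba = (tpr + tnr) / 2
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tpr
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {"BA": float(ba), "MCC": float(mcc), "F": float(f)}


def grid_report_csv(result: GridResult) -> str:
    """The grid as CSV: ``pl,level,auc_loo,valid`` (sorted by pl, level)."""
    lines = ["pl,level,auc_loo,valid"]
    keys = sorted(set(result.cells) | set(result.invalid))
    for pl, level in keys:
        if (pl, level) in result.invalid:
            lines.append(f"{pl},{level},,false")
        else:
            lines.append(f"{pl},{level},{result.cells[(pl, level)]!r},true")
    return "\n".join(lines) + "\n"


def plot_grid(result: GridResult, path: str) -> None:
    """Heatmap of AUC over the (window length, level) grid (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pls = sorted({pl for pl, _ in set(result.cells) | set(result.invalid)})
    levels = sorted({lv for _, lv in set(result.cells) | set(result.invalid)})
    mat = np.full((len(levels), len(pls)), np.nan)
    for (pl, lv), auc in result.cells.items():
        mat[levels.index(lv), pls.index(pl)] = auc
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(mat, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(pls)), pls)
    ax.set_yticks(range(len(levels)), levels)
    ax.set_xlabel("peptide length")
    ax.set_ylabel("MNA level")
    fig.colorbar(im, ax=ax, label="AUC (leave-one-out)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
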