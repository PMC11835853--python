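"""PASS-style naive-Bayes classifier over descriptor sets.

Training counts, per descriptor ``d``, how many examples contain ``d``
(``n_d``) and how many of those are pathogenic (``n_d_path``). A query's raw
score is the arithmetic mean of the Laplace-smoothed per-descriptor evidence

    S = mean over d of (2 * (n_d_path + 1) / (n_d + 2) - 1)

so descriptors never seen in training contribute exactly 0 and
``S`` lies in (-1, 1). Pa and Pi are tie-corrected class-conditional ECDF
functionals of ``S`` against the stored training scores:

    Pa = P(score of a random pathogenic training example < S)
    Pi = P(score of a random benign training example > S)

with ties counted half. ``Confidence = Pa - Pi``; a positive value classifies
the substitution as pathogenic. Relabelling the two classes negates every
confidence exactly (the smoothing and the ECDF tie rule are symmetric).
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

from .mna import DescriptorSet

__all__ = [
    "PATHOGENIC",
    "BENIGN",
    "ModelConfig",
    "SSPRModel",
    "Prediction",
    "fit",
    "score",
    "predict",
    "dump_model",
    "load_model",
]

PATHOGENIC = "pathogenic"
BENIGN = "benign"


@dataclass(frozen=True)
class ModelConfig:
    """Model hyper-parameters: window length, descriptor level, optional
    minimum descriptor support (descriptors seen fewer than ``min_count``
    times count as unseen)."""

    pl: int
    level: int
    min_count: int = 1


@dataclass
class SSPRModel:
    config: ModelConfig
    n_path: int
    n_ben: int
    n_d: dict[str, int]
    n_d_path: dict[str, int]
    score_path: list[float]  # sorted training scores, pathogenic examples
    score_ben: list[float]  # sorted training scores, benign examples


@dataclass(frozen=True)
class Prediction:
    pa: float
    pi: float
    confidence: float
    score: float


def _check_example(dset: DescriptorSet, label: str, level: int) -> None:
    if label not in (PATHOGENIC, BENIGN):
        raise ValueError(f"label must be {PATHOGENIC!r} or {BENIGN!r}, got {label!r}")
    if dset.level != level:
        raise ValueError(
            f"mixed descriptor levels: model at {level}, example at {dset.level}"
        )


def fit(
    examples: Sequence[tuple[DescriptorSet, str]], config: ModelConfig
) -> SSPRModel:
    """Train a model from ``(descriptor set, label)`` pairs.

    Requires at least one example of each class and a uniform descriptor
    level. Duplicate descriptors within one example cannot occur (sets).
    """
    n_d: dict[str, int] = {}
    n_d_path: dict[str, int] = {}
    n_path = n_ben = 0
    for dset, label in examples:
        _check_example(dset, label, config.level)
        is_path = label == PATHOGENIC
        n_path += is_path
        n_ben += not is_path
        for d in dset.items:
            n_d[d] = n_d.get(d, 0) + 1
            if is_path:
                n_d_path[d] = n_d_path.get(d, 0) + 1
    if n_path == 0 or n_ben == 0:
        raise ValueError(
            "single-class training set: need at least one pathogenic and "
            f"one benign example (got {n_path} pathogenic, {n_ben} benign)"
        )
    model = SSPRModel(
        config=config,
        n_path=n_path,
        n_ben=n_ben,
        n_d=n_d,
        n_d_path=n_d_path,
        score_path=[],
        score_ben=[],
    )
    for dset, label in examples:
        s = score(model, dset)
        (model.score_path if label == PATHOGENIC else model.score_ben).append(s)
    model.score_path.sort()
    model.score_ben.sort()
    return model


def score(model: SSPRModel, dset: DescriptorSet) -> float:
    """Mean smoothed evidence of the query's descriptors (in (-1, 1))."""
    if dset.level != model.config.level:
        raise ValueError(
            f"descriptor level {dset.level} does not match model level "
            f"{model.config.level}"
        )
    if not dset.items:
        raise ValueError("empty descriptor set")
    n_d, n_d_path = model.n_d, model.n_d_path
    min_count = model.config.min_count
    total = 0.0
    # sorted iteration keeps the float summation order independent of the
    # process hash seed, so scores are bit-reproducible across runs
    for d in sorted(dset.items):
        nd = n_d.get(d, 0)
        if nd < min_count:
            continue  # treated as unseen: contributes 0
        # (2*(ndp+1)/(nd+2) - 1) written with an integer numerator so that
        # swapping the class labels negates each term exactly.
        total += (2 * n_d_path.get(d, 0) - nd) / (nd + 2)
    return total / len(dset.items)


def _ecdf_below(sorted_scores: list[float], s: float) -> tuple[int, int]:
    lo = bisect_left(sorted_scores, s)
    hi = bisect_right(sorted_scores, s)
    return lo, hi - lo  # strictly-below count, tie count


def predict(model: SSPRModel, dset: DescriptorSet) -> Prediction:
    """Pa/Pi/Confidence for one query."""
    s = score(model, dset)
    below_p, ties_p = _ecdf_below(model.score_path, s)
    pa = (below_p + 0.5 * ties_p) / model.n_path
    below_b, ties_b = _ecdf_below(model.score_ben, s)
    above_b = model.n_ben - below_b - ties_b
    pi = (above_b + 0.5 * ties_b) / model.n_ben
    return Prediction(pa=pa, pi=pi, confidence=pa - pi, score=s)


# ---------------------------------------------------------------------------
# serialisation — versioned JSON, bit-exact reload
# ---------------------------------------------------------------------------

_FORMAT = "sspr-model/1"


def dump_model(model: SSPRModel) -> str:
    payload = {
        "format": _FORMAT,
        "config": {
            "pl": model.config.pl,
            "level": model.config.level,
            "min_count": model.config.min_count,
        },
        "n_path": model.n_path,
        "n_ben": model.n_ben,
        "counts": {d: [model.n_d[d], model.n_d_path.get(d, 0)] for d in model.n_d},
        "score_path": model.score_path,
        "score_ben": model.score_ben,
    }
    return json.dumps(payload, sort_keys=True)


def load_model(text: str) -> SSPRModel:
    payload = json.loads(text)
    if payload.get("format") != _FORMAT:
        raise ValueError(f"unsupported model format {payload.get('format')!r}")
    counts = payload["counts"]
    return SSPRModel(
        config=ModelConfig(**payload["config"]),
        n_path=payload["n_path"],
        n_ben=payload["n_ben"],
        n_d={d: v[0] for d, v in counts.items()},
        n_d_path={d: v[1] for d, v in counts.items() if v[1]},
        score_path=payload["score_path"],
        score_ben=payload["score_ben"],
    )
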