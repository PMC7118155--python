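"""Sequential backward selection (SBS) of texture features.

SBS is a greedy top-down wrapper: starting from the full feature set, each
stage evaluates every single-feature removal with the criterion -- here the
mean pairwise LOOCV classification accuracy over all class pairs, with equal
weight per pair -- and commits the removal with the highest criterion.  The
search terminates when the best candidate removal would strictly decrease
the criterion, i.e. removing another feature would increase classification
error; removals that leave the criterion unchanged are allowed, favouring
smaller sets.  Ties between equally good removals are broken by removing
the feature that appears earliest in the fixed catalog order, making the
trace deterministic and independent of sample ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

from .classify import loocv_binary
from .features import FeatureMatrix

__all__ = [
    "SbsStage",
    "SelectionTrace",
    "sbs_select",
    "pairwise_loocv_evaluator",
    "all_class_pairs",
]

Evaluator = Callable[[tuple[str, ...]], float]


@dataclass(frozen=True)
class SbsStage:
    active: tuple[str, ...]
    removed: str | None
    criterion: float


@dataclass(frozen=True)
class SelectionTrace:
    """Full record of an SBS run: one stage per committed removal."""

    stages: tuple[SbsStage, ...]
    final_set: tuple[str, ...]
    criterion_curve: tuple[tuple[int, float], ...]  # (n_features, criterion)

    @property
    def final_criterion(self) -> float:
        return self.stages[-1].criterion

    def to_json(self, path=None) -> str:
        payload = {
            "stages": [
                {"active": list(s.active), "removed": s.removed, "criterion": s.criterion}
                for s in self.stages
            ],
            "final_set": list(self.final_set),
            "criterion_curve": [[n, c] for n, c in self.criterion_curve],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def all_class_pairs(labels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """All unordered class pairs in first-appearance order (6 for 4 classes)."""
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return tuple(combinations(seen, 2))


def pairwise_loocv_evaluator(
    matrix: FeatureMatrix,
    class_pairs: Sequence[tuple[str, str]] | None = None,
    gamma="scale",
    C: float = 1.0,
) -> Evaluator:
    """Build the SBS criterion: mean pairwise LOOCV accuracy of the RBF-SVM.

    Each class pair is classified with its own LOOCV (the second label of
    the pair is the null-hypothesis group) and the accuracies are averaged
    with equal weight per pair, not per sample.
    """
    if class_pairs is None:
        class_pairs = all_class_pairs(matrix.labels)
    present = set(matrix.labels)
    for a, b in class_pairs:
        if a not in present or b not in present:
            raise ValueError(f"class pair ({a!r}, {b!r}) not present in the data")

    def evaluate(feature_subset: tuple[str, ...]) -> float:
        sub = matrix.select_features(feature_subset)
        accs = []
        for a, b in class_pairs:
            pair = sub.restrict_labels((a, b))
            try:
                _, measures, _ = loocv_binary(pair, positive_label=b, gamma=gamma, C=C)
            except Exception as exc:
                raise RuntimeError(
                    f"LOOCV evaluation failed for pair ({a!r}, {b!r}) "
                    f"on feature subset {feature_subset}: {exc}"
                ) from exc
            accs.append(measures.accuracy)
        return float(sum(accs) / len(accs))

    return evaluate


def sbs_select(
    features: FeatureMatrix | Sequence[str],
    class_pairs: Sequence[tuple[str, str]] | None = None,
    evaluator: Evaluator | None = None,
    min_features: int = 1,
) -> SelectionTrace:
    """Run sequential backward selection and return its full trace.

    ``features`` is either a :class:`FeatureMatrix` (the default evaluator
    is then the mean pairwise LOOCV accuracy over ``class_pairs``) or a
    plain feature-name sequence when a custom ``evaluator`` is injected.
    The evaluator maps a feature-name tuple to its criterion value; it must
    be deterministic.
    """
    if isinstance(features, FeatureMatrix):
        names = features.feature_names
        if evaluator is None:
            evaluator = pairwise_loocv_evaluator(features, class_pairs)
    else:
        names = tuple(features)
        if evaluator is None:
            raise ValueError("an evaluator is required when features is a name sequence")
    if len(names) < 2:
        raise ValueError("SBS needs at least 2 active features to start")
    if not 1 <= min_features < len(names):
        raise ValueError("min_features must be in [1, n_features)")

    active = list(names)
    criterion = evaluator(tuple(active))
    stages = [SbsStage(tuple(active), None, criterion)]
    curve = [(len(active), criterion)]
    while len(active) > min_features:
        best_crit, best_feature = -1.0, None
        for f in active:  # active keeps catalog order => earliest-first tie-break
            candidate = tuple(x for x in active if x != f)
            crit = evaluator(candidate)
            if crit > best_crit:
                best_crit, best_feature = crit, f
        if best_crit < criterion:
            break  # any removal would increase classification error
        active.remove(best_feature)
        criterion = best_crit
        stages.append(SbsStage(tuple(active), best_feature, criterion))
        curve.append((len(active), criterion))
    return SelectionTrace(
        stages=tuple(stages), final_set=tuple(active), criterion_curve=tuple(curve)
    )
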