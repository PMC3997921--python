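"""Dataset-level mining of ACTIVATING features and classification metrics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .assessment import Predictor, interpret
from .chem_io import Structure
from .config import RunConfig
from .fragmentation import Fragment
from .network import ACTIVE, Assessment

__all__ = [
    "ClassificationCounts",
    "Metrics",
    "MinedFeature",
    "MiningError",
    "coverage",
    "metrics",
    "mine_activating",
]


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class MinedFeature:
    """Aggregated statistics for one fragment key across a dataset."""

    key: str
    occurrence: int
    n_activating: int
    experimental_signal: float
    model_accuracy: float

    def __post_init__(self):
        if self.n_activating > self.occurrence:
            raise MiningError("n_activating cannot exceed occurrence")
        for value in (self.experimental_signal, self.model_accuracy):
            if not 0.0 <= value <= 1.0:
                raise MiningError("signal and accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class ClassificationCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise MiningError("counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity and balanced accuracy; ``None`` marks an
    undefined metric (zero denominator), not an error."""

    sen: Optional[float]
    spec: Optional[float]
    bac: Optional[float]


def metrics(c: ClassificationCounts) -> Metrics:
    sen = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    bac = (sen + spec) / 2 if sen is not None and spec is not None else None
    return Metrics(sen=sen, spec=spec, bac=bac)


def coverage(n_in_domain: int, n_total: int) -> float:
    """Applicability-domain coverage as a percentage."""
    if n_total <= 0:
        raise MiningError("n_total must be positive")
    if not 0 <= n_in_domain <= n_total:
        raise MiningError("n_in_domain must lie in [0, n_total]")
    return n_in_domain / n_total * 100.0


def mine_activating(
    structures: Sequence[Structure],
    labels: Sequence[int],
    model: Predictor,
    config: Optional[RunConfig] = None,
    min_occurrence: int = 5,
    min_activating: int = 5,
    library=None,
) -> list[MinedFeature]:
    """Interpret every structure and aggregate per-fragment-key assessments.

    ``occurrence`` counts structures whose network contains the key;
    ``n_activating`` counts structures where it was assessed ACTIVATING.
    Both thresholds are strict (``>``).  Signal is the fraction of
    experimentally active supporters; accuracy the fraction of correct final
    predictions among them.
    """
    if not structures:
        raise MiningError("empty dataset")
    if len(structures) != len(labels):
        raise MiningError("structures and labels differ in length")
    config = config or RunConfig()
    if config.approach != "fragment":
        raise MiningError("mining requires the fragment approach")
    present: dict[str, list[int]] = {}
    activating: dict[str, int] = {}
    meta: dict[int, tuple[bool, bool]] = {}
    for i, (s, label) in enumerate(zip(structures, labels)):
        summary, net = interpret(s, model, config, library=library)
        keys = set()
        act_keys = set()
        for node in net.nodes:
            if isinstance(node.payload, Fragment):
                keys.add(node.payload.key)
                if node.assessment is Assessment.ACTIVATING:
                    act_keys.add(node.payload.key)
        meta[i] = (bool(label), (summary.final_prediction == ACTIVE) == bool(label))
        for key in keys:
            present.setdefault(key, []).append(i)
        for key in act_keys:
            activating[key] = activating.get(key, 0) + 1

    mined = []
    for key, supporters in present.items():
        occ = len(supporters)
        n_act = activating.get(key, 0)
        if occ <= min_occurrence or n_act <= min_activating:
            continue
        n_active = sum(1 for i in supporters if meta[i][0])
        n_correct = sum(1 for i in supporters if meta[i][1])
        mined.append(
            MinedFeature(
                key=key,
                occurrence=occ,
                n_activating=n_act,
                experimental_signal=n_active / occ,
                model_accuracy=n_correct / occ,
            )
        )
    return sorted(mined, key=lambda f: (-f.n_activating, -f.occurrence, f.key))


def mined_features_to_tsv(features: Sequence[MinedFeature], path: str | Path) -> None:
    lines = ["key\toccurrence\tn_activating\tsignal\taccuracy"]
    for f in features:
        lines.append(
            f"{f.key}\t{f.occurrence}\t{f.n_activating}"
            f"\t{f.experimental_signal:.4f}\t{f.model_accuracy:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
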