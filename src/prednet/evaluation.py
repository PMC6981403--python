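"""Train/test splitting and AUC scoring of per-target models.

One 70/30 split is drawn per stratum and reused across every target, so
test AUCs are comparable between models fitted on the same subjects.
AUC uses the rank-statistic (Mann-Whitney) form with midrank ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class SplitConfig:
    train_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")


@dataclass
class ModelEvaluation:
    """Outcome of one per-target fit: AUC or the reason it was skipped."""

    target: str
    auc: float | None
    n_train: int
    n_test: int
    skipped: bool = False
    reason: str = ""


def train_test_split(n: int, config: SplitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform partition into ``round(train_frac * n)`` train rows.

    Returns sorted, disjoint, exhaustive (train, test) index arrays.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train = int(round(config.train_frac * n))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    perm = np.random.default_rng(config.seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative, ties = 1/2.

    Computed as the Mann-Whitney rank statistic with midranks:
    ``(sum of positive ranks - n_pos*(n_pos+1)/2) / (n_pos * n_neg)``.
    Raises ``ValueError`` when the labels hold a single class.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single-class labels: AUC undefined")
    ranks = rankdata(scores)  # midranks
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
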