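"""Model evaluation: AUC, TSS, repeated-split cross-validation, map agreement.

AUC is computed as the exact Mann-Whitney rank statistic (probability that
a random presence outscores a random contrast point, ties counted 1/2) —
no ROC-curve discretization. TSS is maximized over candidate binarization
thresholds (all distinct observed scores plus midpoints between adjacent
distinct scores), reporting the smallest threshold attaining the maximum.
Cross-validation repeats a seeded 75/25 split of presences and contrast
points, refits, and scores the held-out quarter, mirroring the
repeated-resampling design used throughout the SDM literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone

from .grids import SuitabilityMap

__all__ = ["auc", "tss", "cross_validate", "map_correlation", "EvaluationResult"]


def auc(presence_scores, absence_scores) -> float:
    """Exact rank-based AUC with ties counted one half.

    Equals the probability that a randomly chosen presence score exceeds a
    randomly chosen absence score, plus half the probability of a tie.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, a]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * a.size))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2
    return np.sort(np.concatenate([distinct, mids]))


def tss(presence_scores, absence_scores) -> tuple[float, float]:
    """Maximum true skill statistic and its binarization threshold.

    ``TSS(t) = sensitivity(t) + specificity(t) - 1`` with a prediction
    counted positive when ``score >= t``. The maximum is taken over all
    distinct observed scores plus midpoints between adjacent distinct
    scores; on ties the smallest threshold is reported.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = _candidate_thresholds(np.concatenate([p, a]))
    sens = (p[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (a[None, :] < thresholds[:, None]).mean(axis=1)
    values = sens + spec - 1
    best = np.max(values)
    t = thresholds[int(np.argmax(values))]  # argmax returns first (smallest)
    return float(best), float(t)


@dataclass
class EvaluationResult:
    """Cross-validation summary for one species x algorithm."""

    per_rep: list[tuple[float, float]]  # (auc, tss) per repetition
    n_reps: int
    split_fraction: float
    seed: int
    n_skipped: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r[0] for r in self.per_rep]))

    @property
    def sd_auc(self) -> float:
        return float(np.std([r[0] for r in self.per_rep], ddof=1))

    @property
    def mean_tss(self) -> float:
        return float(np.mean([r[1] for r in self.per_rep]))

    @property
    def sd_tss(self) -> float:
        return float(np.std([r[1] for r in self.per_rep], ddof=1))

    def to_dict(self) -> dict:
        return {
            "per_rep": [list(r) for r in self.per_rep],
            "mean_auc": self.mean_auc, "sd_auc": self.sd_auc,
            "mean_tss": self.mean_tss, "sd_tss": self.sd_tss,
            "n_reps": self.n_reps, "n_skipped": self.n_skipped,
            "split_fraction": self.split_fraction, "seed": self.seed,
        }


def cross_validate(estimator, presence_env, contrast_env, n_reps: int = 50,
                   split_fraction: float = 0.75, seed: int = 0,
                   clamp: bool | None = None) -> EvaluationResult:
    """Repeated random-split cross-validation of one estimator.

    Each repetition draws a seeded random split of the presences and the
    contrast points together (``split_fraction`` to training, remainder to
    test), refits a clone of ``estimator`` on the training portion, scores
    the held-out points, and records (AUC, TSS). Failed repetitions are
    skipped and counted; more than 20% failures raises.
    """
    P = np.asarray(presence_env, dtype=float)
    C = np.asarray(contrast_env, dtype=float)
    n_p_train = int(round(split_fraction * len(P)))
    n_c_train = int(round(split_fraction * len(C)))
    if not (0 < n_p_train < len(P)):
        raise ValueError(
            f"{len(P)} presences leave no test point at split {split_fraction}"
        )
    if not (0 < n_c_train < len(C)):
        raise ValueError(
            f"{len(C)} contrast points leave no test point at split {split_fraction}"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    per_rep: list[tuple[float, float]] = []
    n_skipped = 0
    for _ in range(n_reps):
        ip = rng.permutation(len(P))
        ic = rng.permutation(len(C))
        Xtr = np.vstack([P[ip[:n_p_train]], C[ic[:n_c_train]]])
        ytr = np.concatenate([np.ones(n_p_train, dtype=int),
                              np.zeros(n_c_train, dtype=int)])
        try:
            model = clone(estimator).fit(Xtr, ytr)
            sp = model.predict_suitability(P[ip[n_p_train:]], clamp=clamp)
            sc = model.predict_suitability(C[ic[n_c_train:]], clamp=clamp)
            per_rep.append((auc(sp, sc), tss(sp, sc)[0]))
        except Exception:
            n_skipped += 1
    if n_skipped > 0.2 * n_reps:
        raise RuntimeError(
            f"cross-validation failed in {n_skipped}/{n_reps} repetitions"
        )
    return EvaluationResult(per_rep=per_rep, n_reps=len(per_rep),
                            split_fraction=split_fraction, seed=seed,
                            n_skipped=n_skipped)


def map_correlation(map_a: SuitabilityMap, map_b: SuitabilityMap) -> float:
    """Pearson correlation between two suitability maps.

    Computed over cells valid (non-NaN) in both maps; the maps must share
    geometry and both must vary over the joint cells.
    """
    if map_a.geometry != map_b.geometry:
        raise ValueError("maps have different geometries")
    joint = map_a.valid_mask & map_b.valid_mask
    if joint.sum() < 2:
        raise ValueError("fewer than 2 jointly valid cells")
    a = map_a.values[joint]
    b = map_b.values[joint]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: a map is constant")
    return float(np.corrcoef(a, b)[0, 1])
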