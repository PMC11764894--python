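"""Template-based classification and the LOOCV template-cycling protocol.

Every ordered pair of one negative and one positive trial serves once as
the (negative template, positive template) benchmark; all remaining trials
are classified by whichever template their BREM is more similar to, and the
per-pair confusion counts are aggregated into a subject-level mean and
standard deviation over the ``n_neg * n_pos`` pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .brem import (BREM, DEFAULT_REGION_MAP, MONTAGE_32, RegionMap,
                   build_brem, fuse_region)
from .entropies import EntropyConfig
from .rhythms import EEGSignal
from .similarity import ORIENTATIONS, SimilarityConfig, score

__all__ = [
    "POSITIVE", "NEGATIVE", "Trial", "TrialSet", "PairRecord",
    "EvaluationReport", "GridSearchResult", "label_from_rating",
    "segment_trial", "accuracy", "classify_by_template",
    "loocv_template_evaluation", "loocv_from_scores", "pairwise_similarity",
    "grid_search_best",
    "anova_feature_screen",
]

logger = logging.getLogger(__name__)

POSITIVE = "positive"  # HA / HV, rating >= 5
NEGATIVE = "negative"  # LA / LV, rating < 5


def label_from_rating(rating: float) -> str:
    """Map a 1-9 rating to a class label: >= 5 is positive (HA/HV)."""
    return POSITIVE if rating >= 5 else NEGATIVE


@dataclass
class Trial:
    """One labeled trial: per-channel signals plus its class label."""

    trial_id: str
    channels: dict[str, EEGSignal]
    label: str
    rating: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}")
        if not self.channels:
            raise ValueError("trial has no channels")

    def signal(self, channel: str) -> EEGSignal:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(
                f"trial {self.trial_id!r} has no channel {channel!r}; "
                f"available: {sorted(self.channels)}") from None


@dataclass
class TrialSet:
    """A subject's labeled trials for one emotional dimension."""

    subject: str
    trials: list[Trial]
    dimension: str = "arousal"

    def __post_init__(self) -> None:
        if self.dimension not in ("arousal", "valence"):
            raise ValueError("dimension must be 'arousal' or 'valence'")
        fss = {sig.fs for t in self.trials for sig in t.channels.values()}
        if len(fss) > 1:
            raise ValueError(f"inconsistent sampling rates: {sorted(fss)}")

    @property
    def fs(self) -> float:
        return next(iter(self.trials[0].channels.values())).fs

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def indices(self, label: str) -> list[int]:
        return [i for i, t in enumerate(self.trials) if t.label == label]


@dataclass
class PairRecord:
    pos_template_id: str
    neg_template_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    ties: int = 0


@dataclass
class EvaluationReport:
    """Per-template-pair confusion records plus subject-level aggregates."""

    records: list[PairRecord]
    mean_accuracy: float
    sd_accuracy: float
    n_pairs: int
    tie_count: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pairs != len(self.records):
            raise ValueError("n_pairs does not match record count")
        if not 0.0 <= self.mean_accuracy <= 1.0:
            raise ValueError("mean accuracy must lie in [0, 1]")


@dataclass
class GridSearchResult:
    channel: str
    segment_start: float
    mean_accuracy: float
    grid: dict[tuple[str, float], float] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.channel, self.segment_start, self.mean_accuracy))


def segment_trial(signal: EEGSignal, window_s: float,
                  start_s: float) -> EEGSignal:
    """Extract the non-overlapping segment ``[start_s, start_s + window_s)``.

    ``start_s`` must sit on the window grid (a multiple of ``window_s``)
    and the segment must fit inside the trial.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if start_s < 0:
        raise ValueError("start_s must be nonnegative")
    ratio = start_s / window_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"start_s={start_s} is not a multiple of window_s={window_s}")
    i0 = int(round(start_s * signal.fs))
    i1 = int(round((start_s + window_s) * signal.fs))
    if i1 > len(signal):
        raise ValueError(
            f"segment {start_s}-{start_s + window_s}s exceeds trial "
            f"duration {signal.duration:g}s")
    return EEGSignal(samples=signal.samples[i0:i1], fs=signal.fs,
                     channel=signal.channel, trial_id=signal.trial_id,
                     t0=start_s)


def accuracy(tp: int, fp: int, fn: int, tn: int) -> float:
    """``(TP + TN) / (TP + FP + FN + TN)``."""
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    return (tp + tn) / total


def _decide(s_pos: float, s_neg: float, higher_wins: bool) -> tuple[str, bool]:
    """Pick the class of the more similar template; ties go positive."""
    if s_pos == s_neg:
        return POSITIVE, True
    if higher_wins:
        return (POSITIVE, False) if s_pos > s_neg else (NEGATIVE, False)
    return (POSITIVE, False) if s_pos < s_neg else (NEGATIVE, False)


def classify_by_template(test, pos_template, neg_template, method: str,
                         cfg: SimilarityConfig = SimilarityConfig()) -> str:
    """Label a test BREM by its more similar template (ties -> positive)."""
    s_pos = score(test, pos_template, method, cfg)
    s_neg = score(test, neg_template, method, cfg)
    label, tie = _decide(s_pos.value, s_neg.value,
                         s_pos.higher_is_more_similar)
    if tie:
        logger.debug("similarity tie (%s = %g); predicting positive",
                     method, s_pos.value)
    return label


def _trial_matrix(trial: Trial, window_s: float, start_s: float,
                  channel: str | None, region: str | None,
                  entropy_cfg: EntropyConfig,
                  region_map: RegionMap):
    if (channel is None) == (region is None):
        raise ValueError("specify exactly one of channel or region")
    if channel is not None:
        seg = segment_trial(trial.signal(channel), window_s, start_s)
        return build_brem(seg, entropy_cfg)
    brems = []
    for ch in region_map.channels(region):
        if ch in trial.channels:
            seg = segment_trial(trial.signal(ch), window_s, start_s)
            brems.append(build_brem(seg, entropy_cfg))
    if not brems:
        raise ValueError(
            f"trial {trial.trial_id!r} has no channels in region {region!r}")
    return fuse_region(brems, region, region_map)


def _pairwise_scores(matrices: list, method: str,
                     sim_cfg: SimilarityConfig) -> np.ndarray:
    n = len(matrices)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = score(matrices[i], matrices[j], method,
                                      sim_cfg).value
    return S


def loocv_from_scores(S: np.ndarray, labels: list[str], ids: list[str],
                      higher_wins: bool) -> tuple[list[PairRecord], int]:
    """Run the template-cycling protocol on a precomputed score matrix.

    ``S[i, j]`` is the similarity score between trials ``i`` and ``j``.
    Exposed separately so permutation/null analyses can reshuffle labels
    without recomputing BREMs or similarities.
    """
    labels = list(labels)
    pos_idx = [i for i, l in enumerate(labels) if l == POSITIVE]
    neg_idx = [i for i, l in enumerate(labels) if l == NEGATIVE]
    if not pos_idx or not neg_idx:
        raise ValueError("need at least one positive and one negative trial")
    if len(labels) < 3:
        raise ValueError("empty test set: need at least 3 trials")
    records: list[PairRecord] = []
    tie_total = 0
    for j in neg_idx:
        for i in pos_idx:
            tp = fp = fn = tn = ties = 0
            for k in range(len(labels)):
                if k == i or k == j:
                    continue
                pred, tie = _decide(S[k, i], S[k, j], higher_wins)
                ties += tie
                if labels[k] == POSITIVE:
                    if pred == POSITIVE:
                        tp += 1
                    else:
                        fn += 1
                else:
                    if pred == POSITIVE:
                        fp += 1
                    else:
                        tn += 1
            records.append(PairRecord(
                pos_template_id=ids[i], neg_template_id=ids[j],
                tp=tp, fp=fp, fn=fn, tn=tn,
                accuracy=accuracy(tp, fp, fn, tn), ties=ties))
            tie_total += ties
    return records, tie_total


def _aggregate(records: list[PairRecord], tie_count: int,
               config: dict) -> EvaluationReport:
    accs = np.array([r.accuracy for r in records])
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return EvaluationReport(records=records,
                            mean_accuracy=float(accs.mean()),
                            sd_accuracy=sd, n_pairs=len(records),
                            tie_count=tie_count, config=config)


def pairwise_similarity(
        trials: TrialSet, method: str, window_s: float,
        channel: str | None = None, region: str | None = None,
        segment_start_s: float = 0.0,
        entropy_cfg: EntropyConfig = EntropyConfig(),
        sim_cfg: SimilarityConfig = SimilarityConfig(),
        region_map: RegionMap = DEFAULT_REGION_MAP) -> np.ndarray:
    """Symmetric matrix of similarity scores between all trials' BREMs.

    This is the expensive half of :func:`loocv_template_evaluation`;
    label-permutation analyses can reuse it across shuffles.
    """
    matrices = [_trial_matrix(t, window_s, segment_start_s, channel, region,
                              entropy_cfg, region_map)
                for t in trials.trials]
    return _pairwise_scores(matrices, method, sim_cfg)


def loocv_template_evaluation(
        trials: TrialSet, method: str, window_s: float,
        channel: str | None = None, region: str | None = None,
        segment_start_s: float = 0.0,
        entropy_cfg: EntropyConfig = EntropyConfig(),
        sim_cfg: SimilarityConfig = SimilarityConfig(),
        region_map: RegionMap = DEFAULT_REGION_MAP) -> EvaluationReport:
    """Exhaustive template-cycling evaluation of one subject.

    Each of the ``n_neg * n_pos`` (negative, positive) template pairs
    classifies every remaining trial; the two template trials are excluded
    from testing for their own pair only.
    """
    S = pairwise_similarity(trials, method, window_s, channel, region,
                            segment_start_s, entropy_cfg, sim_cfg,
                            region_map)
    higher_wins = ORIENTATIONS[method.upper()] == "similarity"
    ids = [t.trial_id for t in trials.trials]
    records, ties = loocv_from_scores(S, trials.labels, ids, higher_wins)
    config = {"method": method.upper(), "window_s": window_s,
              "channel": channel, "region": region,
              "segment_start_s": segment_start_s,
              "subject": trials.subject, "dimension": trials.dimension}
    return _aggregate(records, ties, config)


def _montage_sorted(channels: list[str]) -> list[str]:
    def key(ch):
        return (MONTAGE_32.index(ch) if ch in MONTAGE_32 else len(MONTAGE_32),
                ch)
    return sorted(channels, key=key)


def grid_search_best(trials: TrialSet, method: str, window_s: float,
                     candidate_channels: list[str],
                     entropy_cfg: EntropyConfig = EntropyConfig(),
                     sim_cfg: SimilarityConfig = SimilarityConfig()) -> GridSearchResult:
    """Evaluate every (channel, non-overlapping segment) cell and return the
    argmax of mean accuracy.

    Ties break deterministically: first channel in montage order, then the
    earliest segment.
    """
    if not candidate_channels:
        raise ValueError("need at least one candidate channel")
    duration = min(t.signal(candidate_channels[0]).duration
                   for t in trials.trials)
    n_segments = int(duration // window_s)
    if n_segments < 1:
        raise ValueError(
            f"no {window_s}s segment fits in a {duration:g}s trial")
    best: tuple[str, float, float] | None = None
    grid: dict[tuple[str, float], float] = {}
    for ch in _montage_sorted(candidate_channels):
        for k in range(n_segments):
            start = k * window_s
            report = loocv_template_evaluation(
                trials, method, window_s, channel=ch,
                segment_start_s=start, entropy_cfg=entropy_cfg,
                sim_cfg=sim_cfg)
            grid[(ch, start)] = report.mean_accuracy
            if best is None or report.mean_accuracy > best[2]:
                best = (ch, start, report.mean_accuracy)
    return GridSearchResult(channel=best[0], segment_start=best[1],
                            mean_accuracy=best[2], grid=grid)


def anova_feature_screen(feature_values, labels) -> tuple[float, float]:
    """One-way two-group ANOVA of a single feature against binary labels.

    Returns ``(F, p)``; p-values are unadjusted for multiple testing.  With
    zero within-group variance in both groups the result degenerates to
    ``(0, 1)`` for equal means or ``(inf, 0)`` otherwise, with a log notice.
    """
    values = np.asarray(feature_values, dtype=np.float64)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) != 2:
        raise ValueError("labels must form exactly two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 observations per group")
    if all(np.ptp(g) == 0 for g in groups):
        logger.warning("zero within-group variance in both groups; "
                       "degenerate ANOVA result")
        if groups[0][0] == groups[1][0]:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
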