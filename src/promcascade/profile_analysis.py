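"""Per-position DDS profiles of classifier outcome groups and their statistics.

Records are partitioned into true/false positives/negatives by a chosen
cascade stage, each group gets a position-wise mean stability profile (the
diagnostic that localizes discriminative signal at the −10 and −35 boxes),
and group differences are tested on per-sequence mean DDS: Shapiro–Wilk for
normality of the pooled means, a Kruskal–Wallis omnibus across groups, and a
pairwise post-hoc (Tukey HSD by default, for fidelity with the original
analysis; rank-based Dunn as the distribution-free alternative).  Each
sequence contributes one observation (its mean DDS), so the tests are not
inflated by within-sequence correlation; the per-position profiles are
descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cascade_model import PredictionRecord
from .errors import DataError

GROUPS = ("TP", "TN", "FP", "FN")


def profile_positions(width: int) -> np.ndarray:
    """Promoter coordinates of dinucleotide steps: step i (1-based) at i − (width+1),
    so a 59-step profile spans −59..−1 with the −10 box at step −10."""
    return np.arange(1, width + 1) - (width + 1)


def outcome_groups(
    predictions: Sequence[PredictionRecord],
    labels: Mapping[str, int],
    stage: str = "stage1",
) -> dict[str, list[str]]:
    """Exhaustive, disjoint TP/TN/FP/FN partition by the chosen stage's labels.

    ``stage`` is ``"stage1"`` (the default, matching the error-profile
    diagnostic) or ``"final"``.  Raises KeyError for a prediction whose id has
    no true label.
    """
    if stage not in ("stage1", "final"):
        raise ValueError(f"stage must be 'stage1' or 'final', got {stage!r}")
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    for rec in predictions:
        truth = labels[rec.id]  # KeyError on unlabeled id is intentional
        pred = rec.stage1_label if stage == "stage1" else rec.final_label
        if truth == 1:
            groups["TP" if pred == 1 else "FN"].append(rec.id)
        else:
            groups["FP" if pred == 1 else "TN"].append(rec.id)
    return groups


@dataclass
class GroupProfile:
    group: str
    mean_profile: np.ndarray          # position-wise mean DDS, length = feature width
    n: int
    per_sequence_means: np.ndarray    # one mean DDS per sequence

    @property
    def positions(self) -> np.ndarray:
        return profile_positions(len(self.mean_profile))


def group_profiles(
    groups: Mapping[str, Sequence[str]],
    features: np.ndarray,
    ids: Sequence[str],
) -> list[GroupProfile]:
    """Position-wise mean DDS per outcome group (empty groups are omitted)."""
    features = np.asarray(features, dtype=np.float64)
    row_of = {sid: i for i, sid in enumerate(ids)}
    out: list[GroupProfile] = []
    for group, members in groups.items():
        if not members:
            continue
        rows = features[[row_of[m] for m in members]]
        out.append(
            GroupProfile(
                group=group,
                mean_profile=rows.mean(axis=0),
                n=len(members),
                per_sequence_means=rows.mean(axis=1),
            )
        )
    return out


def profiles_to_frame(profiles: Sequence[GroupProfile]) -> pd.DataFrame:
    """Long-format table: position, group, mean_dds, n."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {"position": p.positions, "group": p.group, "mean_dds": p.mean_profile, "n": p.n}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    p_raw: float
    p_adjusted: float
    method: str


@dataclass
class GroupComparison:
    normality_statistic: float
    normality_p: float
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult]
    posthoc_method: str


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> list[PairwiseResult]:
    """Dunn's rank-based post-hoc with tie correction and Holm adjustment."""
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in names:
        n_g = len(samples[g])
        mean_ranks[g] = float(ranks[start : start + n_g].mean())
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1))) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1 / len(samples[a]) + 1 / len(samples[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        raw.append((a, b, p))
    # Holm step-down adjustment
    order = np.argsort([p for _, _, p in raw])
    m = len(raw)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * raw[idx][2]))
        adjusted[idx] = running
    return [
        PairwiseResult(a, b, p, adjusted[i], "dunn")
        for i, (a, b, p) in enumerate(raw)
    ]


def _tukey_pairwise(samples: dict[str, np.ndarray]) -> list[PairwiseResult]:
    names = list(samples)
    res = stats.tukey_hsd(*(samples[g] for g in names))
    out = []
    for i, j in combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        # Tukey's HSD p-value is family-wise adjusted by construction
        out.append(PairwiseResult(names[i], names[j], p, p, "tukey"))
    return out


def compare_groups(
    per_group_means: Mapping[str, np.ndarray],
    posthoc: str = "tukey",
) -> GroupComparison:
    """Normality + omnibus + pairwise post-hoc over per-sequence mean DDS.

    ``posthoc`` is ``"tukey"`` (default) or ``"dunn"``.  Groups with fewer
    than 3 members make the tests undefined and raise :class:`DataError`.
    """
    samples = {g: np.asarray(v, dtype=np.float64) for g, v in per_group_means.items() if len(v)}
    if len(samples) < 2:
        raise DataError("need at least two non-empty groups")
    for g, v in samples.items():
        if len(v) < 3:
            raise DataError(f"group {g} has {len(v)} members; tests need >= 3")
    if posthoc not in ("tukey", "dunn"):
        raise ValueError(f"posthoc must be 'tukey' or 'dunn', got {posthoc!r}")
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        # degenerate: every observation identical — no evidence of any difference
        sw_stat, sw_p = float("nan"), float("nan")
        kw_stat, kw_p = 0.0, 1.0
        pairwise = [
            PairwiseResult(a, b, 1.0, 1.0, posthoc) for a, b in combinations(samples, 2)
        ]
        return GroupComparison(sw_stat, sw_p, kw_stat, kw_p, pairwise, posthoc)
    sw_stat, sw_p = stats.shapiro(pooled)
    kw_stat, kw_p = stats.kruskal(*samples.values())
    pairwise = _tukey_pairwise(samples) if posthoc == "tukey" else _dunn_pairwise(samples)
    return GroupComparison(
        normality_statistic=float(sw_stat),
        normality_p=float(sw_p),
        omnibus_statistic=float(kw_stat),
        omnibus_p=float(kw_p),
        pairwise=pairwise,
        posthoc_method=posthoc,
    )
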