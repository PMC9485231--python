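"""Pairwise correlations and correlation-based ensemble detection.

Ensembles are groups of ≥ 3 co-active neurons found on the pairwise Pearson
correlation matrix of one subvolume: average-linkage hierarchical clustering
supplies small (3–5 neuron) high-correlation seeds, a greedy pass grows each
seed by repeatedly adding the neuron with the highest mean correlation to
the current members while the mean within-ensemble correlation stays above
a threshold (twice the 99.5th percentile of all pairwise correlations),
redundant ensembles with ≥ 75% overlap are merged when the union still
clears the threshold, and undersized ensembles are discarded.  A "touch
ensemble" has ≥ 50% touch-classified members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import NeuronRecord, Trial, total_frames
from .encoding import NeuronClass

MIN_ENSEMBLE_SIZE = 3
SEED_SIZE_RANGE = (3, 5)
MERGE_OVERLAP = 0.75
THRESHOLD_PERCENTILE = 99.5
THRESHOLD_CAP = 0.99


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with its neuron ordering.

    ``valid`` flags neurons with nonzero variance over the unmasked frames;
    correlations involving an invalid neuron are recorded as NaN and
    excluded from percentile computations.
    """

    neuron_ids: list[int]
    matrix: np.ndarray
    mask_kind: str = "all-time"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.neuron_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match neuron ordering")
        if self.valid is None:
            self.valid = ~np.all(np.isnan(self.matrix), axis=1)

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        vals = self.matrix[iu]
        return vals[~np.isnan(vals)]


@dataclass
class Ensemble:
    """A detected ensemble: members, mean within correlation, touch flag."""

    members: frozenset[int]
    mean_correlation: float
    touch: bool | None = None
    composition: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def nontouch_time_mask(
    trials: list[Trial],
    frame_rate_hz: float,
    n_frames: int | None = None,
    pre_s: float = 1.0,
    post_s: float = 10.0,
) -> np.ndarray:
    """Boolean mask of frames outside all touch epochs.

    Frames from 1 s before to 10 s after any touch are excluded (mask
    False); overlapping exclusion windows are unioned.
    """
    if n_frames is None:
        n_frames = total_frames(trials)
    mask = np.ones(n_frames, dtype=bool)
    pre = int(round(pre_s * frame_rate_hz))
    post = int(round(post_s * frame_rate_hz))
    for t in trials:
        for ev in t.touches:
            lo = max(ev.onset_frame - pre, 0)
            hi = min(ev.onset_frame + post, n_frames)
            mask[lo:hi] = False
    return mask


def correlation_matrix(
    neurons: list[NeuronRecord],
    mask: np.ndarray | None = None,
    mask_kind: str = "all-time",
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over the unmasked frames.

    Zero-variance traces are flagged invalid and their correlations are
    NaN (undefined-and-excluded) rather than 0.
    """
    if len(neurons) < 2:
        raise ValueError("need at least 2 neurons")
    traces = np.stack([nr.dff for nr in neurons])
    if mask is not None:
        if int(np.sum(mask)) < 2:
            raise ValueError("fewer than 2 unmasked frames")
        traces = traces[:, np.asarray(mask, dtype=bool)]
    sd = traces.std(axis=1)
    valid = sd > 0
    corr = np.full((len(neurons), len(neurons)), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(traces[valid])
        idx = np.flatnonzero(valid)
        corr[np.ix_(idx, idx)] = sub
    corr[np.diag_indices(len(neurons))] = 1.0
    return CorrelationMatrix(
        neuron_ids=[nr.neuron_id for nr in neurons],
        matrix=corr, mask_kind=mask_kind, valid=valid,
    )


def detection_threshold(corr: CorrelationMatrix) -> float:
    """Twice the 99.5th percentile of all pairwise correlations, capped.

    The cap at 0.99 keeps the criterion satisfiable on strongly correlated
    populations where twice the percentile would exceed 1.
    """
    vals = corr.offdiag_values()
    if vals.size == 0:
        return 0.0
    thr = 2.0 * float(np.percentile(vals, THRESHOLD_PERCENTILE))
    return min(thr, THRESHOLD_CAP)


def _mean_mutual_corr(matrix: np.ndarray, idx: list[int]) -> float:
    if len(idx) < 2:
        return np.nan
    sub = matrix[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    if np.any(np.isnan(vals)):
        return np.nan
    return float(vals.mean())


def seed_clusters(
    corr: CorrelationMatrix, threshold: float | None = None
) -> list[list[int]]:
    """Small high-correlation seed groups from hierarchical clustering.

    Average-linkage clustering on distance 1 − r; every cluster of the
    dendrogram with 3–5 members whose mean mutual correlation exceeds the
    detection threshold is kept, discarding seeds strictly contained in
    another passing seed.  Returned as lists of matrix indices.
    """
    if threshold is None:
        threshold = detection_threshold(corr)
    valid_idx = np.flatnonzero(corr.valid)
    if valid_idx.size < MIN_ENSEMBLE_SIZE:
        return []
    mat = corr.matrix[np.ix_(valid_idx, valid_idx)]
    dist = 1.0 - mat
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")

    # enumerate every dendrogram node's member set
    n = valid_idx.size
    node_members: list[list[int]] = [[i] for i in range(n)]
    for a, b, _, _ in Z:
        node_members.append(node_members[int(a)] + node_members[int(b)])
    lo, hi = SEED_SIZE_RANGE
    passing = []
    for members in node_members:
        if lo <= len(members) <= hi:
            mc = _mean_mutual_corr(mat, members)
            if not np.isnan(mc) and mc >= threshold:
                passing.append(frozenset(members))
    # drop seeds strictly contained in another passing seed
    keep = [
        s for s in passing
        if not any(s < other for other in passing)
    ]
    out = [sorted(int(valid_idx[i]) for i in s) for s in set(keep)]
    out.sort()
    return out


def grow_ensemble(
    seed: list[int], corr: CorrelationMatrix, threshold: float
) -> Ensemble:
    """Greedily grow a seed while the mean within correlation stays high.

    At each step the candidate with the highest mean correlation to the
    current members is considered (ties broken by lower matrix index); it
    joins if the grown ensemble's mean within correlation remains >= the
    threshold, otherwise growth stops.  Membership is reported as neuron
    ids.
    """
    members = sorted(seed)
    mat = corr.matrix
    mc = _mean_mutual_corr(mat, members)
    if np.isnan(mc) or mc < threshold:
        raise ValueError("seed mean correlation below threshold")
    candidates = set(np.flatnonzero(corr.valid)) - set(members)
    while candidates:
        cand = sorted(candidates)
        with np.errstate(invalid="ignore"):
            mean_to_members = np.array(
                [np.nanmean(mat[c, members]) for c in cand]
            )
        best_pos = int(np.argmax(mean_to_members))  # argmax takes first: lower id wins ties
        best = cand[best_pos]
        new_members = sorted(members + [best])
        new_mc = _mean_mutual_corr(mat, new_members)
        if np.isnan(new_mc) or new_mc < threshold:
            break
        members = new_members
        mc = new_mc
        candidates.discard(best)
    return Ensemble(
        members=frozenset(corr.neuron_ids[i] for i in members),
        mean_correlation=mc,
    )


def ensemble_overlap(a: Ensemble, b: Ensemble) -> float:
    """|a ∩ b| / |a ∪ b| (Jaccard overlap of memberships)."""
    union = a.members | b.members
    if not union:
        raise ValueError("both ensembles are empty")
    return len(a.members & b.members) / len(union)


def merge_ensembles(
    ensembles: list[Ensemble], corr: CorrelationMatrix, threshold: float
) -> list[Ensemble]:
    """Merge heavily overlapping ensembles; drop undersized ones.

    Pairs with overlap >= 75% are merged iff the union's mean within
    correlation still clears the threshold; applied iteratively to a fixed
    point, then ensembles with < 3 members are discarded.
    """
    id_to_idx = {nid: i for i, nid in enumerate(corr.neuron_ids)}
    seen: dict[frozenset, Ensemble] = {}
    for e in ensembles:  # drop exact duplicates, keep first
        seen.setdefault(e.members, e)
    pool = list(seen.values())
    changed = True
    while changed:
        changed = False
        pool.sort(key=lambda e: sorted(e.members))
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                a, b = pool[i], pool[j]
                if a.members == b.members:
                    pool.pop(j)
                    changed = True
                    break
                if ensemble_overlap(a, b) >= MERGE_OVERLAP:
                    union = sorted(a.members | b.members)
                    mc = _mean_mutual_corr(
                        corr.matrix, [id_to_idx[n] for n in union]
                    )
                    if not np.isnan(mc) and mc >= threshold:
                        pool[i] = Ensemble(frozenset(union), mc)
                        pool.pop(j)
                        changed = True
                        break
            if changed:
                break
    return [e for e in pool if len(e) >= MIN_ENSEMBLE_SIZE]


def detect_ensembles(
    neurons: list[NeuronRecord],
    mask: np.ndarray | None = None,
    mask_kind: str = "all-time",
    threshold: float | None = None,
) -> tuple[list[Ensemble], CorrelationMatrix, float]:
    """Full detector: correlations -> seeds -> growth -> merge."""
    corr = correlation_matrix(neurons, mask=mask, mask_kind=mask_kind)
    if threshold is None:
        threshold = detection_threshold(corr)
    seeds = seed_clusters(corr, threshold)
    grown = [grow_ensemble(s, corr, threshold) for s in seeds]
    merged = merge_ensembles(grown, corr, threshold)
    return merged, corr, threshold


def label_touch_ensembles(
    ensembles: list[Ensemble], classes: dict[int, NeuronClass]
) -> list[Ensemble]:
    """Flag touch ensembles (>= 50% touch members) and record composition."""
    out = []
    for e in ensembles:
        labels = [classes[n].label for n in e.members]
        n = len(labels)
        comp = {
            cls: labels.count(cls) / n
            for cls in ("non-touch", "uSW", "bSW", "MW")
        }
        touch_frac = 1.0 - comp["non-touch"]
        out.append(
            Ensemble(
                members=e.members, mean_correlation=e.mean_correlation,
                touch=touch_frac >= 0.5, composition=comp,
            )
        )
    return out


def class_pair_mean_correlation(
    corr: CorrelationMatrix, classes: dict[int, NeuronClass], label: str
) -> float:
    """Mean pairwise correlation among neurons of one class.

    Unidirectional single-whisker neurons are grouped by subtype
    (whisker × direction) and the subtype means averaged; bidirectional
    neurons are grouped by whisker; multi-whisker neurons are pooled.
    """
    idx_of = {nid: i for i, nid in enumerate(corr.neuron_ids)}
    members = [
        nid for nid in corr.neuron_ids
        if nid in classes and classes[nid].label == label
    ]
    if label == "uSW":
        groups = {}
        for nid in members:
            key = (classes[nid].whisker, classes[nid].direction)
            groups.setdefault(key, []).append(nid)
    elif label == "bSW":
        groups = {}
        for nid in members:
            groups.setdefault(classes[nid].whisker, []).append(nid)
    else:
        groups = {None: members}
    means = []
    for grp in groups.values():
        if len(grp) < 2:
            continue
        mc = _mean_mutual_corr(corr.matrix, [idx_of[n] for n in grp])
        if not np.isnan(mc):
            means.append(mc)
    return float(np.mean(means)) if means else np.nan
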