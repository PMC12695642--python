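"""Synapse detectability evaluation.

Two procedures: a dendrite-centric census (multi-pass node annotations merged
by single-link clustering, matched across modalities by Euclidean distance,
with leftover tags clustered into confusion "hotspots") and a randomized-ROI
confidence-score task (annotator QC, cleaning, binarization at a score cut,
confusion matrix and P/R/F1/F-beta).

All positions are in nanometres.  "Cross-correlation" between annotators is
interpreted as the Pearson correlation of their score vectors, applied as a
strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import ScoreArray

__all__ = [
    "NodeAnnotation",
    "SynapseCensus",
    "ConfusionSummary",
    "build_census",
    "match_detections",
    "find_hotspots",
    "clean_scores",
    "captcha_confusion",
    "dendrite_report",
]

MODALITY_EM = "em"
MODALITY_PXCT = "pxct"


@dataclass(frozen=True)
class NodeAnnotation:
    position: tuple[float, float, float]  # (z, y, x) nm
    pass_index: int  # 1..3
    annotator_id: str = "a0"
    modality: str = MODALITY_EM
    dendrite_id: int | None = None

    def __post_init__(self):
        if self.pass_index not in (1, 2, 3):
            raise ValueError("pass_index must be in {1, 2, 3}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


@dataclass
class CensusEntry:
    centroid: np.ndarray  # (3,) nm
    member_nodes: list[NodeAnnotation]
    first_pass_detected: int
    dendrite_id: int | None = None


@dataclass
class SynapseCensus:
    entries: list[CensusEntry]
    merge_radius: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def centroids(self) -> np.ndarray:
        if not self.entries:
            return np.empty((0, 3))
        return np.stack([e.centroid for e in self.entries])


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    beta: float = 2.0
    precision: float | None = field(init=False)
    recall: float | None = field(init=False)
    f1: float | None = field(init=False)
    f_beta: float | None = field(init=False)
    precision_undefined: bool = field(init=False, default=False)

    def __post_init__(self):
        tp, fp, fn = self.tp, self.fp, self.fn
        if tp + fp == 0:
            self.precision = None
            self.precision_undefined = True
        else:
            self.precision = tp / (tp + fp)
        self.recall = tp / (tp + fn) if tp + fn > 0 else None
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            self.f1 = None
            self.f_beta = None
        else:
            self.f1 = 2.0 * p * r / (p + r)
            b2 = self.beta ** 2
            self.f_beta = (1.0 + b2) * p * r / (b2 * p + r)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f_beta": self.f_beta,
            "beta": self.beta,
            "precision_undefined": self.precision_undefined,
        }


# ---------------------------------------------------------------------------
# clustering


def _single_link_clusters(points: np.ndarray, radius: float) -> list[np.ndarray]:
    """Union-find single-link clustering of points within ``radius`` (<=)."""
    n = len(points)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    return [np.nonzero(roots == r)[0] for r in np.unique(roots)]


def build_census(nodes: list[NodeAnnotation], merge_radius_nm: float = 300.0) -> SynapseCensus:
    """Merge annotation nodes within ``merge_radius_nm`` into census entries.

    Nodes seeded at most the merge radius apart (single-link) point to the
    same synapse; the entry centroid is the mean member position and
    ``first_pass_detected`` the minimum pass index among members.
    """
    if merge_radius_nm <= 0:
        raise ValueError("merge_radius must be > 0")
    if not nodes:
        return SynapseCensus(entries=[], merge_radius=merge_radius_nm)
    positions = np.array([n.position for n in nodes], dtype=float)
    entries = []
    for idx in _single_link_clusters(positions, merge_radius_nm):
        members = [nodes[i] for i in sorted(idx)]
        dendrites = {m.dendrite_id for m in members if m.dendrite_id is not None}
        entries.append(
            CensusEntry(
                centroid=positions[idx].mean(axis=0),
                member_nodes=members,
                first_pass_detected=min(m.pass_index for m in members),
                dendrite_id=next(iter(dendrites)) if len(dendrites) == 1 else None,
            )
        )
    entries.sort(key=lambda e: tuple(e.centroid))
    return SynapseCensus(entries=entries, merge_radius=merge_radius_nm)


def match_detections(
    census: SynapseCensus,
    query_nodes: list[NodeAnnotation],
    radius_nm: float = 300.0,
) -> tuple[np.ndarray, list[NodeAnnotation], list[int | None]]:
    """Match query nodes against census centroids by Euclidean distance.

    A census entry is "detected" iff at least one query node lies within
    ``radius_nm`` of its centroid.  Returns (detected flags per entry,
    unmatched query nodes, detection pass per entry -- the minimum pass index
    among its matching nodes, or None).
    """
    if radius_nm <= 0:
        raise ValueError("radius must be > 0")
    detected = np.zeros(len(census.entries), dtype=bool)
    detect_pass: list[int | None] = [None] * len(census.entries)
    if not query_nodes:
        return detected, [], detect_pass
    qpos = np.array([n.position for n in query_nodes], dtype=float)
    matched_query = np.zeros(len(query_nodes), dtype=bool)
    centroids = census.centroids
    if len(centroids):
        from scipy.spatial import cKDTree

        tree = cKDTree(qpos)
        for e_idx, c in enumerate(centroids):
            hits = tree.query_ball_point(c, radius_nm)
            if hits:
                detected[e_idx] = True
                detect_pass[e_idx] = min(query_nodes[q].pass_index for q in hits)
                matched_query[hits] = True
    unmatched = [q for q, used in zip(query_nodes, matched_query) if not used]
    return detected, unmatched, detect_pass


def find_hotspots(
    unmatched_nodes: list[NodeAnnotation],
    radius_nm: float = 300.0,
    min_tags: int = 2,
) -> list[dict]:
    """Single-link clusters of unmatched tags with >= ``min_tags`` members."""
    if min_tags < 2:
        raise ValueError("min_tags must be >= 2")
    if not unmatched_nodes:
        return []
    positions = np.array([n.position for n in unmatched_nodes], dtype=float)
    hotspots = []
    for idx in _single_link_clusters(positions, radius_nm):
        if len(idx) >= min_tags:
            hotspots.append(
                {
                    "centroid": positions[idx].mean(axis=0),
                    "size": int(len(idx)),
                    "members": [unmatched_nodes[i] for i in sorted(idx)],
                }
            )
    hotspots.sort(key=lambda h: tuple(h["centroid"]))
    return hotspots


# ---------------------------------------------------------------------------
# captcha-style ROI task


def clean_scores(
    score_array: ScoreArray | np.ndarray,
    min_xcorr: float = 0.4,
) -> tuple[np.ndarray, np.ndarray, list[int], np.ndarray]:
    """Annotator QC and region cleanup.

    Drops annotators whose ground-truth-modality score vector has a Pearson
    correlation strictly below ``min_xcorr`` with the mean of the other
    annotators, then drops regions with any missing (0) response among the
    retained annotators in either modality.

    Returns (cleaned scores, retained region indices, dropped annotator
    indices, retained annotator indices).
    """
    scores = score_array.scores if isinstance(score_array, ScoreArray) else np.asarray(score_array)
    if not np.isin(scores, [0, 1, 2, 3, 4]).all():
        raise ValueError("scores must take values in {0..4}")
    n_regions, n_annot, _ = scores.shape
    em = scores[:, :, 0].astype(float)

    # iteratively drop the single worst annotator below threshold, so one
    # rogue annotator cannot poison the reference average of the others
    dropped: list[int] = []
    retained = list(range(n_annot))
    while len(retained) >= 2:
        corrs = {}
        for a in retained:
            others = [b for b in retained if b != a]
            ref = em[:, others].mean(axis=1)
            vec = em[:, a]
            if vec.std() == 0 or ref.std() == 0:
                corrs[a] = 0.0
            else:
                corrs[a] = float(np.corrcoef(vec, ref)[0, 1])
        worst = min(corrs, key=corrs.get)
        if corrs[worst] < min_xcorr:
            dropped.append(worst)
            retained.remove(worst)
        else:
            break
    kept_annot = np.array(retained, dtype=int)
    if kept_annot.size < 2:
        raise ValueError("fewer than 2 annotators remain after QC")

    sub = scores[:, kept_annot, :]
    region_ok = (sub != 0).all(axis=(1, 2))
    kept_regions = np.nonzero(region_ok)[0]
    return sub[kept_regions], kept_regions, dropped, kept_annot


def captcha_confusion(
    cleaned_scores: np.ndarray,
    cut: float = 2.5,
    beta: float = 2.0,
) -> tuple[ConfusionSummary, np.ndarray]:
    """Confusion matrix for the ROI task plus the 4x4 score-vs-score table.

    Per region the mean score per modality is computed; the ground-truth
    (index 0) binarization at ``cut`` (>= cut means "synapse") is the
    reference and the evaluated modality (index 1) the prediction.  The 4x4
    table counts regions by rounded mean score (ties away from zero) in both
    modalities.
    """
    scores = np.asarray(cleaned_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no regions to score")
    if not 1.0 < cut < 4.0:
        raise ValueError("cut must lie in (1, 4)")
    mean_em = scores[:, :, 0].mean(axis=1)
    mean_px = scores[:, :, 1].mean(axis=1)
    ref = mean_em >= cut
    pred = mean_px >= cut
    tp = int(np.sum(ref & pred))
    fp = int(np.sum(~ref & pred))
    fn = int(np.sum(ref & ~pred))
    tn = int(np.sum(~ref & ~pred))
    summary = ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn, beta=beta)

    # nearest integer, ties away from zero
    em_bin = np.clip(np.floor(mean_em + 0.5).astype(int), 1, 4)
    px_bin = np.clip(np.floor(mean_px + 0.5).astype(int), 1, 4)
    table = np.zeros((4, 4), dtype=int)
    for e, p in zip(em_bin, px_bin):
        table[e - 1, p - 1] += 1
    return summary, table


# ---------------------------------------------------------------------------
# dendrite-centric report


def dendrite_report(
    em_nodes: list[NodeAnnotation],
    px_nodes: list[NodeAnnotation],
    merge_radius: float = 300.0,
) -> dict:
    """Per-pass discovery and cross-modality detection accounting.

    Builds the ground-truth census from the EM nodes, matches the X-ray nodes
    against it, and tabulates: per-pass census fractions, the matched
    detection fraction (pooled and per dendrite), and per-pass fractions of
    the matched detections.  Percentages are rounded to the nearest integer.
    """
    census = build_census(em_nodes, merge_radius)
    n_census = len(census)
    em_pass = np.array([e.first_pass_detected for e in census.entries], dtype=int)

    detected, unmatched, detect_pass = match_detections(census, px_nodes, merge_radius)
    n_detected = int(detected.sum())
    px_pass = np.array([p for p in detect_pass if p is not None], dtype=int)

    def pct(k, n):
        return int(np.floor(100.0 * k / n + 0.5)) if n else None

    per_dendrite = {}
    dendrites = sorted({e.dendrite_id for e in census.entries if e.dendrite_id is not None})
    for d in dendrites:
        idx = [i for i, e in enumerate(census.entries) if e.dendrite_id == d]
        per_dendrite[d] = {
            "n_census": len(idx),
            "n_detected": int(detected[idx].sum()),
            "detected_fraction": float(detected[idx].mean()) if idx else None,
        }

    report = {
        "census_size": n_census,
        "em_first_pass_count": int(np.sum(em_pass == 1)),
        "em_first_pass_pct": pct(int(np.sum(em_pass == 1)), n_census),
        "em_third_pass_count": int(np.sum(em_pass == 3)),
        "em_third_pass_pct": pct(int(np.sum(em_pass == 3)), n_census),
        "matched_detections": n_detected,
        "detected_fraction_pooled": (n_detected / n_census) if n_census else None,
        "px_first_pass_count": int(np.sum(px_pass == 1)),
        "px_first_pass_pct": pct(int(np.sum(px_pass == 1)), n_detected),
        "px_later_pass_count": int(np.sum(px_pass >= 2)),
        "px_later_pass_pct": pct(int(np.sum(px_pass >= 2)), n_detected),
        "n_unmatched_px_nodes": len(unmatched),
        "per_dendrite": per_dendrite,
    }
    return report
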