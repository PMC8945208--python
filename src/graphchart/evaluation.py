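"""Evaluation harness: ROC/AUC, threshold metrics, ablations, reader scores.

AUC is computed with the midrank Mann–Whitney estimator (the pairwise
probability that an abnormal video outscores a normal one, ties counted
half), which matters here because examiner scores are heavily tied.  The
examiner score combines a binary decision ``d`` (−1 normal, +1 abnormal)
with a confidence ``c`` in 1..5 as ``(d*c + 5) / 10``, mapping onto
{0.0,...,0.4} ∪ {0.6,...,1.0}; 0.5 is unattainable, so the 0.5 decision
threshold separates the two decisions cleanly.

Summary statistics (mean / SD / median / min–max) follow the reporting
layout of multi-seed ablation and reader-study tables; SD is the
population-style descriptive standard deviation (ddof=0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .geometry import DEFAULT_BUFFER_RADIUS
from .model import ABLATION_VARIANTS, GraphChartEncoder
from .screening import score_collection
from .synthetic import SyntheticDataset
from .timeline import BarcodeTimeline

__all__ = [
    "HumanRating",
    "ScoredVideo",
    "ROCResult",
    "AblationResult",
    "gamma_human",
    "roc_auc",
    "threshold_metrics",
    "summary_stats",
    "run_ablation",
    "pick_median_run",
    "compare_examiner_sets",
]


@dataclass(frozen=True)
class HumanRating:
    """One examiner call on one video: decision d (−1/+1), confidence c (1–5)."""

    d: int
    c: int

    def __post_init__(self) -> None:
        if self.d not in (-1, 1):
            raise ValueError(f"decision d must be -1 or +1, got {self.d}")
        if self.c not in (1, 2, 3, 4, 5):
            raise ValueError(f"confidence c must be an integer 1..5, got {self.c}")


@dataclass(frozen=True)
class ScoredVideo:
    """A video with its ground-truth label (0 normal / 1 abnormal) and score."""

    video_id: str
    label: int
    score: float

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def gamma_human(rating: HumanRating | int, c: int | None = None) -> float:
    """Examiner abnormality score ``(d*c + 5) / 10``.

    Accepts a :class:`HumanRating` or the pair ``(d, c)`` directly.
    """
    if not isinstance(rating, HumanRating):
        d = rating
        if int(d) != d or int(c) != c:
            raise ValueError("decision and confidence must be integers")
        rating = HumanRating(int(d), int(c))
    return (rating.d * rating.c + 5) / 10


def _labels_scores(videos) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(videos, pd.DataFrame):
        labels = videos["label"].to_numpy()
        if labels.dtype == object:
            labels = (labels == "abnormal").astype(int)
        return labels.astype(int), videos["score"].to_numpy(float)
    vids = list(videos)
    if vids and isinstance(vids[0], ScoredVideo):
        return (
            np.array([v.label for v in vids]),
            np.array([v.score for v in vids], dtype=float),
        )
    raise TypeError("expected a DataFrame with label/score or ScoredVideo list")


def roc_auc(videos) -> ROCResult:
    """AUC (midrank Mann–Whitney) plus the ROC curve of a scored collection.

    ``videos`` is a DataFrame with ``label``/``score`` columns or a list of
    :class:`ScoredVideo`.  Both classes must be present.
    """
    labels, scores = _labels_scores(videos)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")
    ranks = rankdata(scores)  # midranks
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr)


def threshold_metrics(videos, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, FPR, recall, precision, F1 at a hard decision threshold.

    Predicted abnormal iff ``score > threshold`` (strict: a score exactly at
    the boundary counts normal).  With zero predicted positives, precision
    (and F1) are undefined; they are reported as 0 with
    ``precision_undefined`` flagged and a warning emitted.
    """
    labels, scores = _labels_scores(videos)
    if labels.sum() in (0, len(labels)):
        raise ValueError("threshold metrics need both classes present")
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    recall = tp / (tp + fn)
    fpr = fp / (fp + tn)
    undefined = (tp + fp) == 0
    if undefined:
        warnings.warn("no predicted positives: precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (tp + tn) / len(labels),
        "fpr": fpr,
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "precision_undefined": bool(undefined),
    }


def summary_stats(values) -> dict[str, float]:
    """mean / SD (ddof=0) / median / min / max of a value collection."""
    v = np.asarray(list(values), dtype=float)
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=0)),
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
    }


@dataclass
class AblationResult:
    """Per-variant AUC summary plus the raw per-run records."""

    table: pd.DataFrame
    records: list[dict]

    def run_aucs(self, variant: str) -> list[float]:
        return [r["auc"] for r in self.records if r["variant"] == variant]


def run_ablation(
    dataset: SyntheticDataset,
    seeds=(0, 1, 2, 3, 4),
    variants: dict[tuple[bool, bool], str] | None = None,
    encoder_params: dict | None = None,
    buffer_radius: float = DEFAULT_BUFFER_RADIUS,
    keep_encoders: bool = False,
) -> AblationResult:
    """Train/score every (variant, seed) cell and summarise test AUCs.

    For each combination of cascade wiring x view-proxy loss and each seed,
    an encoder is trained on the normal-only training split, the test split
    is scored against its own maximum-area diagram, and the AUC recorded.
    The table reports mean/SD/median/min/max per variant over seeds.
    """
    variants = variants or ABLATION_VARIANTS
    encoder_params = encoder_params or {}
    records: list[dict] = []
    for (use_cascade, use_proxy), name in variants.items():
        for seed in seeds:
            enc = GraphChartEncoder(
                use_cascade=use_cascade,
                use_view_proxy=use_proxy,
                random_state=seed,
                **encoder_params,
            ).fit(dataset.train)
            scored = score_collection(enc, dataset.test, buffer_radius)
            rec = {
                "variant": name,
                "use_cascade": use_cascade,
                "use_view_proxy": use_proxy,
                "seed": seed,
                "auc": roc_auc(scored).auc,
                "ideal_latents": enc.ideal_latents_,
                "proxy_distances": enc.proxy_distances_,
                "initial_proxy_distances": enc.initial_proxy_distances_,
            }
            if keep_encoders:
                rec["encoder"] = enc
            records.append(rec)
    rows = []
    for name in variants.values():
        stats = summary_stats([r["auc"] for r in records if r["variant"] == name])
        rows.append({"variant": name, **stats})
    return AblationResult(table=pd.DataFrame(rows).set_index("variant"), records=records)


def pick_median_run(result: AblationResult, variant: str = "cascade+proxy") -> dict:
    """Model-picking policy for deployment: the run with the median AUC.

    Among the (typically five) seeded runs of a variant, returns the record
    whose AUC is the middle of the sorted list (the lower middle for an
    even count) — a robust choice that avoids both lucky and unlucky seeds.
    """
    recs = [r for r in result.records if r["variant"] == variant]
    if not recs:
        raise ValueError(f"no runs recorded for variant {variant!r}")
    recs = sorted(recs, key=lambda r: r["auc"])
    return recs[(len(recs) - 1) // 2]


# ---- reader-study harness -----------------------------------------------

_RATING_COLS = {"examiner_id", "group", "block", "video_id", "d", "c"}


def _examiner_frame(ratings: pd.DataFrame, labels: dict[str, int]) -> pd.DataFrame:
    missing = _RATING_COLS - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings file missing columns {sorted(missing)}")
    unknown = set(ratings["video_id"]) - set(labels)
    if unknown:
        raise ValueError(f"ratings reference unlabelled videos {sorted(unknown)[:5]}")
    df = ratings.copy()
    df["score"] = [gamma_human(d, c) for d, c in zip(df["d"], df["c"])]
    df["label"] = df["video_id"].map(labels)
    return df


def compare_examiner_sets(
    ratings_without_ai: pd.DataFrame,
    ratings_with_ai: pd.DataFrame,
    labels: dict[str, int],
    threshold: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Reader-study comparison: per-group and pooled metrics, both blocks.

    Each ratings frame holds one row per (examiner, video) with columns
    ``examiner_id, group, block, video_id, d, c``.  Per examiner the
    examiner score is computed from (d, c), then AUC and threshold metrics;
    groups and the pooled "examiner" row report mean/SD/median/min–max over
    examiners.  Blocks must rate the same video set per examiner.
    """
    out_rows: dict[str, list[dict]] = {"without_ai": [], "with_ai": []}
    per_examiner: dict[str, dict[str, dict]] = {"without_ai": {}, "with_ai": {}}
    blocks = {"without_ai": ratings_without_ai, "with_ai": ratings_with_ai}

    vids0 = None
    for block_name, ratings in blocks.items():
        df = _examiner_frame(ratings, labels)
        vids = set(df["video_id"])
        if vids0 is None:
            vids0 = vids
        elif vids != vids0:
            raise ValueError("blocks rate different video sets (alignment error)")
        for (ex, group), sub in df.groupby(["examiner_id", "group"]):
            auc = roc_auc(sub).auc
            metrics = threshold_metrics(sub, threshold)
            per_examiner[block_name][ex] = {
                "group": group,
                "auc": auc,
                **{k: v for k, v in metrics.items() if k != "precision_undefined"},
            }

    tables: dict[str, pd.DataFrame] = {}
    for block_name, exam in per_examiner.items():
        df = pd.DataFrame.from_dict(exam, orient="index")
        rows = []
        groups = list(dict.fromkeys(df["group"]))
        for group in groups + ["examiner"]:
            sub = df if group == "examiner" else df[df["group"] == group]
            row = {"group": group, "n": len(sub)}
            for metric in ("auc", "accuracy", "fpr", "recall", "precision", "f1"):
                stats = summary_stats(sub[metric])
                row.update({f"{metric}_{k}": v for k, v in stats.items()})
            rows.append(row)
        tables[block_name] = pd.DataFrame(rows).set_index("group")

    a, b = tables["without_ai"], tables["with_ai"]
    mean_cols = [c for c in a.columns if c.endswith("_mean")]
    tables["delta"] = (b[mean_cols] - a[mean_cols]).join(a["n"])
    return tables
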