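"""Linear max-margin frame classifier with temporal voting.

A frame is classified climbing/non-climbing from its LTP descriptor by a
linear SVM decision function; the raw per-frame decisions are then smoothed
by a temporal voting window so that the final label of a frame is the
consensus of the raw labels in a window around it. The voting step removes
spurious single-frame detections and heals single-frame gaps that would
otherwise split long climbing bouts.

The regularization strength C and the voting parameters are selected by
leave-one-segment-out cross-validation over annotated video segments, and
the final model is refit on all segments with the selected parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .ltp import LTPParams

__all__ = [
    "VotingParams",
    "ClimbModel",
    "CVResult",
    "DEFAULT_GRID",
    "train",
    "predict_raw",
    "temporal_vote",
    "predict",
    "leave_one_segment_out",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class VotingParams:
    """Temporal consensus window.

    The window at frame ``t`` is ``[max(0, t-k), min(n-1, t+k)]``
    (truncated at the ends, no padding); the smoothed label is 1 iff the
    raw positives in the window strictly exceed ``vote_fraction`` times
    the window size. ``vote_fraction=0.5`` is a strict majority.
    """

    half_width: int = 6
    vote_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if not 0 < self.vote_fraction <= 1:
            raise ValueError("vote_fraction must be in (0, 1]")


@dataclass
class ClimbModel:
    """Linear decision function plus the voting window applied on top.

    A frame's raw prediction is 1 iff ``weights . x + bias > 0``; exact
    zeros (on the boundary) classify as non-climbing.
    """

    weights: np.ndarray
    bias: float
    C: float
    voting: VotingParams = field(default_factory=VotingParams)
    ltp_params: LTPParams | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()

    @property
    def dimension(self) -> int:
        return self.weights.size

    def decision_values(self, features) -> np.ndarray:
        X = _as_matrix(features)
        if X.shape[1] != self.dimension:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.dimension}"
            )
        return np.asarray(X @ self.weights).ravel() + self.bias


def _as_matrix(features) -> np.ndarray | sparse.spmatrix:
    if sparse.issparse(features):
        return features
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def train(
    features,
    labels,
    C: float = 1.0,
    voting: VotingParams | None = None,
    class_weight: str | None = None,
    ltp_params: LTPParams | None = None,
) -> ClimbModel:
    """Fit the linear max-margin frame classifier at regularization ``C``.

    The optimisation (L2-regularized hinge loss) is delegated to
    liblinear; the contract is the returned linear decision function.
    ``class_weight="balanced"`` reweights the hinge loss by inverse class
    frequency; the default is unweighted.
    """
    X = _as_matrix(features)
    y = np.asarray(labels).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"{X.shape[0]} feature rows but {y.size} labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    # liblinear's standard L2-regularized L2-loss dual formulation: fast,
    # deterministic, and the usual choice for high-dimensional sparse frames.
    # The iteration budget is capped: near-separable frame sets make the
    # dual converge slowly in its last decimals without changing decisions.
    svc = LinearSVC(
        C=C,
        loss="squared_hinge",
        dual=True,
        class_weight=class_weight,
        tol=1e-3,
        max_iter=300,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        svc.fit(X, y)
    return ClimbModel(
        weights=svc.coef_.ravel(),
        bias=float(svc.intercept_[0]),
        C=C,
        voting=voting or VotingParams(),
        ltp_params=ltp_params,
    )


def predict_raw(model: ClimbModel, features) -> np.ndarray:
    """Per-frame raw labels: 1 iff the margin is strictly positive."""
    return (model.decision_values(features) > 0).astype(np.int8)


def temporal_vote(raw, voting: VotingParams) -> np.ndarray:
    """Smooth raw labels with the truncated voting window.

    ``out[t] = 1`` iff the sum of raw labels over
    ``[max(0, t-k), min(n-1, t+k)]`` strictly exceeds
    ``vote_fraction * window_size``. ``k=0`` is the identity.
    """
    x = np.asarray(raw, dtype=np.int64).ravel()
    if x.size == 0:
        raise ValueError("empty label sequence")
    k = voting.half_width
    n = x.size
    csum = np.concatenate([[0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - k, 0)
    hi = np.minimum(np.arange(n) + k, n - 1)
    window_sum = csum[hi + 1] - csum[lo]
    window_len = hi - lo + 1
    return (window_sum > voting.vote_fraction * window_len).astype(np.int8)


def predict(model: ClimbModel, features) -> np.ndarray:
    """Raw linear decision followed by temporal voting."""
    return temporal_vote(predict_raw(model, features), model.voting)


#: default cross-validation grid: (C, half_width k, vote fraction theta)
DEFAULT_GRID: tuple[tuple[float, int, float], ...] = tuple(
    (C, k, 0.5) for C in (0.01, 0.1, 1.0, 10.0) for k in (0, 3, 6, 12, 25)
)


@dataclass
class CVResult:
    """Outcome of leave-one-segment-out parameter selection."""

    grid: list[tuple[float, int, float]]
    fold_table: pd.DataFrame  # columns: fold, segment_id, C, k, theta, metric
    selected: tuple[float, int, float]
    selection_metric: str
    model: ClimbModel  # refit on all segments with the selected parameters
    heldout_raw: dict | None = None  # {C: [raw predictions per held-out fold]}

    def heldout_predictions(self) -> list[np.ndarray]:
        """Per-fold held-out labels of the selected candidate (raw SVM
        decisions of the fold's model smoothed by the selected voting)."""
        C, k, theta = self.selected
        vp = VotingParams(half_width=int(k), vote_fraction=float(theta))
        return [temporal_vote(raw, vp) for raw in self.heldout_raw[C]]


def _score(pred: np.ndarray, gold: np.ndarray, metric: str) -> float:
    if metric == "accuracy":
        return float(np.mean(pred == gold))
    if metric == "balanced_accuracy":
        recalls = []
        for cls in (0, 1):
            mask = gold == cls
            if mask.any():
                recalls.append(float(np.mean(pred[mask] == cls)))
        return float(np.mean(recalls))
    raise ValueError(f"unknown selection metric {metric!r}")


def leave_one_segment_out(
    segments: list[tuple],
    grid=DEFAULT_GRID,
    metric: str = "accuracy",
    class_weight: str | None = None,
    segment_ids: list[str] | None = None,
) -> CVResult:
    """Select (C, k, theta) by leave-one-segment-out cross-validation.

    ``segments`` is a list of ``(features, gold_labels)`` pairs, one per
    annotated video segment. For every grid candidate and every fold, the
    classifier is trained on all-but-one segment, raw predictions on the
    held-out segment are smoothed by the candidate's voting window, and
    the held-out ``metric`` is recorded. The selected candidate maximises
    the fold-mean metric; ties break toward smaller C, then smaller k.
    The returned model is refit on all segments with the winner.

    Raw SVM predictions depend only on C, so they are computed once per
    (C, fold) and shared across voting candidates.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments for leave-one-out")
    grid = [tuple(g) for g in grid]
    if not grid:
        raise ValueError("empty parameter grid")
    segment_ids = segment_ids or [f"seg{i}" for i in range(len(segments))]
    golds = [np.asarray(lab).ravel() for _, lab in segments]

    c_values = sorted({c for c, _, _ in grid})
    raw_by_c_fold: dict[tuple[float, int], np.ndarray] = {}
    for C in c_values:
        for fold in range(len(segments)):
            train_X = sparse.vstack(
                [_as_sparse(segments[i][0]) for i in range(len(segments)) if i != fold]
            )
            train_y = np.concatenate([golds[i] for i in range(len(segments)) if i != fold])
            model = train(train_X, train_y, C=C, class_weight=class_weight)
            raw_by_c_fold[(C, fold)] = predict_raw(model, segments[fold][0])

    rows = []
    for C, k, theta in grid:
        vp = VotingParams(half_width=k, vote_fraction=theta)
        for fold in range(len(segments)):
            pred = temporal_vote(raw_by_c_fold[(C, fold)], vp)
            rows.append(
                (fold, segment_ids[fold], C, k, theta, _score(pred, golds[fold], metric))
            )
    fold_table = pd.DataFrame(
        rows, columns=["fold", "segment_id", "C", "k", "theta", "metric"]
    )
    means = fold_table.groupby(["C", "k", "theta"])["metric"].mean()
    # argmax with deterministic tie-break: smaller C, then smaller k
    best = max(
        means.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1])
    )[0]
    C_sel, k_sel, theta_sel = best

    all_X = sparse.vstack([_as_sparse(f) for f, _ in segments])
    all_y = np.concatenate(golds)
    final = train(
        all_X,
        all_y,
        C=C_sel,
        voting=VotingParams(half_width=int(k_sel), vote_fraction=float(theta_sel)),
        class_weight=class_weight,
    )
    return CVResult(
        grid=grid,
        fold_table=fold_table,
        selected=(float(C_sel), int(k_sel), float(theta_sel)),
        selection_metric=metric,
        model=final,
        heldout_raw={
            C: [raw_by_c_fold[(C, f)] for f in range(len(segments))]
            for C in c_values
        },
    )


def _as_sparse(features) -> sparse.csr_matrix:
    X = _as_matrix(features)
    return X if sparse.issparse(X) else sparse.csr_matrix(X)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(model: ClimbModel, path: str | Path) -> None:
    """Serialize weights, bias, C, voting and LTP configuration (.npz)."""
    meta = {
        "C": model.C,
        "voting": asdict(model.voting),
        "ltp_params": asdict(model.ltp_params) if model.ltp_params else None,
    }
    np.savez(
        Path(path),
        weights=model.weights,
        bias=np.float64(model.bias),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> ClimbModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        ltp = LTPParams(**meta["ltp_params"]) if meta["ltp_params"] else None
        return ClimbModel(
            weights=data["weights"],
            bias=float(data["bias"]),
            C=float(meta["C"]),
            voting=VotingParams(**meta["voting"]),
            ltp_params=ltp,
        )
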