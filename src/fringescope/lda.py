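"""Linear-discriminant scoring of outflow geochemistry.

A fixed linear combination of 20 geochemical variables separates locations
that support photosynthesis from those that do not: sites scoring at or
above a decision threshold of 0.13 are called photosynthetic.  The
published weights ship as a text resource and are never re-derived; a
separate Fisher two-class trainer produces *new* models of the same shape
from labelled data (e.g. synthetic studies), with scores scaled to unit
pooled within-class variance.

Field sampling targets locations whose scores are equidistant from the
fringe site's score on either side; :func:`select_equidistant_sites`
implements that selection rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources as _resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

PUBLISHED_THRESHOLD = 0.13

LABEL_PHOTO = "photosynthetic"
LABEL_NONPHOTO = "non_photosynthetic"


class ScoringError(ValueError):
    """A model variable is missing from the sample and has no fallback."""


class TrainingError(ValueError):
    """Training input cannot support a two-class discriminant."""


class SelectionError(ValueError):
    """No candidate site on one side of the fringe."""


@dataclass
class LDAModel:
    """Named linear discriminant: ordered (variable, unit, weight) triples.

    ``intercept`` is 0 for the published model; all offset is carried by
    ``threshold``.
    """

    coefficients: list[tuple[str, str, float]]
    intercept: float = 0.0
    threshold: float = PUBLISHED_THRESHOLD

    def __post_init__(self) -> None:
        names = [v for v, _, _ in self.coefficients]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable in LDA model")

    @property
    def variables(self) -> list[str]:
        return [v for v, _, _ in self.coefficients]

    @property
    def units(self) -> dict[str, str]:
        return {v: u for v, u, _ in self.coefficients}

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.coefficients])

    @classmethod
    def read(cls, path: str | Path, threshold: float = PUBLISHED_THRESHOLD,
             intercept: float = 0.0) -> "LDAModel":
        coeffs = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["variable", "unit", "weight"]:
                raise ValueError(f"unexpected model header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                var, unit, w = line.rstrip("\n").split("\t")
                coeffs.append((var, "" if unit == "-" else unit, float(w)))
        return cls(coeffs, intercept=intercept, threshold=threshold)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variable\tunit\tweight\n")
            for var, unit, w in self.coefficients:
                fh.write(f"{var}\t{unit or '-'}\t{w!r}\n")


def published_model() -> LDAModel:
    """The published 20-variable discriminant with threshold 0.13."""
    ref = _resources.files("fringescope") / "resources" / "published_lda.tsv"
    with _resources.as_file(ref) as path:
        return LDAModel.read(path)


def lda_score(
    sample: Mapping[str, float],
    model: LDAModel,
    fallbacks: Mapping[str, float] | None = None,
) -> float:
    """Evaluate ``intercept + Σ wᵢ·xᵢ`` on one geochemistry row.

    ``sample`` must supply every model variable in the model's units
    (convert first via :mod:`fringescope.units` if needed); ``fallbacks``
    supplies declared defaults for unmeasured variables, mirroring the
    field practice of substituting historical values.
    """
    fallbacks = fallbacks or {}
    total = model.intercept
    for var, _unit, w in model.coefficients:
        x = sample.get(var)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            if var in fallbacks:
                x = fallbacks[var]
            else:
                raise ScoringError(f"variable {var!r} missing and no fallback given")
        total += w * float(x)
    return total


def score_table(geochem, model: LDAModel,
                fallbacks: Mapping[str, float] | None = None) -> "np.ndarray":
    """Score every row of a GeochemTable (values assumed in model units)."""
    return np.array([
        lda_score(geochem.row(sid).to_dict(), model, fallbacks)
        for sid in geochem.sample_ids
    ])


def classify_fringe(score: float, threshold: float = PUBLISHED_THRESHOLD) -> str:
    """Photosynthetic iff score ≥ threshold (ties count as photosynthetic)."""
    if not math.isfinite(score):
        raise ScoringError(f"non-finite score {score}")
    return LABEL_PHOTO if score >= threshold else LABEL_NONPHOTO


@dataclass
class FringeCall:
    sample_id: str
    score: float
    label: str
    margin: float


def call_fringe(sample_ids: Sequence[str], scores: Sequence[float],
                threshold: float = PUBLISHED_THRESHOLD) -> list[FringeCall]:
    return [
        FringeCall(sid, s, classify_fringe(s, threshold), s - threshold)
        for sid, s in zip(sample_ids, scores)
    ]


def train_lda(
    X: np.ndarray,
    labels: np.ndarray,
    variables: Sequence[str] | None = None,
    units: Mapping[str, str] | None = None,
    ridge: float | None = None,
) -> LDAModel:
    """Fisher two-class discriminant in closed form.

    w ∝ S_pooled⁻¹ (μ₁ − μ₀), scaled so the pooled within-class variance of
    the scores is 1 and oriented so the class-1 (photosynthetic) mean score
    exceeds the class-0 mean.  The intercept is 0; pick a decision boundary
    afterwards with :func:`select_threshold`.  A ridge of
    1e-8·trace(S)/p is added when S_pooled is singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2:
        raise TrainingError("X must be 2-D (samples × variables)")
    classes = np.unique(y)
    if set(classes.tolist()) != {0, 1}:
        raise TrainingError(f"need binary 0/1 labels with both classes, got {classes}")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise TrainingError("need at least 2 samples per class")

    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = (np.cov(X0, rowvar=False, ddof=1) * (n0 - 1)
         + np.cov(X1, rowvar=False, ddof=1) * (n1 - 1)) / (n0 + n1 - 2)
    S = np.atleast_2d(S)
    p = S.shape[0]
    if ridge is None:
        # add ridge only if needed
        if np.linalg.matrix_rank(S) < p:
            ridge = 1e-8 * np.trace(S) / p
        else:
            ridge = 0.0
    if ridge > 0:
        S = S + ridge * np.eye(p)
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise TrainingError(f"singular pooled covariance: {exc}") from exc

    within_var = float(w @ S @ w)
    if within_var > 0:
        w = w / math.sqrt(within_var)
    if (mu1 - mu0) @ w < 0:
        w = -w

    variables = list(variables) if variables is not None else [
        f"x{i}" for i in range(p)
    ]
    units = dict(units or {})
    coeffs = [(v, units.get(v, ""), float(wi)) for v, wi in zip(variables, w)]
    return LDAModel(coeffs, intercept=0.0, threshold=0.0)


def select_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Decision boundary minimizing false positives + false negatives.

    Candidates are midpoints between adjacent sorted unique scores plus one
    position below the minimum and one above the maximum; classification is
    score ≥ t → positive.  Ties in total error break toward the smallest
    threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(set(y.tolist())) < 2:
        raise TrainingError("both classes required to place a threshold")
    uniq = np.unique(s)
    if len(uniq) == 1:
        return float(uniq[0])
    candidates = np.concatenate((
        [uniq[0] - 1.0],
        (uniq[:-1] + uniq[1:]) / 2.0,
        [uniq[-1] + 1.0],
    ))
    best_t, best_err = None, None
    for t in candidates:
        pred = s >= t
        err = int((pred & (y == 0)).sum() + (~pred & (y == 1)).sum())
        if best_err is None or err < best_err:
            best_t, best_err = float(t), err
    return best_t


def select_equidistant_sites(
    scores_downstream: Sequence[float], fringe_index: int
) -> tuple[int, int]:
    """Pick (above, below) indices whose score offsets from the fringe match.

    Minimizes ``| |s_at − s_a| − |s_b − s_at| |`` over all pairs a < fringe
    < b; ties break toward the pair closest in rank to the fringe (smallest
    b − a, then smallest distance of the farther member).
    """
    s = list(scores_downstream)
    if not 0 < fringe_index < len(s) - 1:
        raise SelectionError(
            f"fringe index {fringe_index} needs a candidate on each side "
            f"of a {len(s)}-site transect"
        )
    s_at = s[fringe_index]
    best = None
    for a in range(fringe_index):
        for b in range(fringe_index + 1, len(s)):
            obj = abs(abs(s_at - s[a]) - abs(s[b] - s_at))
            span = b - a
            far = max(fringe_index - a, b - fringe_index)
            key = (obj, span, far, a)
            if best is None or key < best[0]:
                best = (key, (a, b))
    return best[1]
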