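"""Rule-based classification of 5-point OGTT glucose curve shapes.

Observed (not smoothed) glucose series are labelled biphasic, monophasic,
monotonically increasing, or inconclusive using the threshold rules common
in the pediatric OGTT literature: a drop or re-rise only "counts" when it
reaches 4.5 mg/dL.  Rules are applied in a fixed order that makes the four
labels mutually exclusive and exhaustive:

(a) *inconclusive* — no rise above the fasting value by 60 min;
(b) *monotonically increasing* — no point falls more than delta below the
    running maximum;
(c) *biphasic* — after the initial peak, a decrease of at least delta
    followed by a later increase of at least delta from the post-drop
    minimum;
(d) *monophasic* — otherwise: a single peak with a decrease of at least
    delta and no subsequent rise reaching delta.

"At least 4.5" is read inclusively (>= delta) for the biphasic and
monophasic drop/re-rise, while the monotonic rule's "more than 4.5" is
strict (> delta), honouring the phrasing distinction.  Plateaus (equal
consecutive values) count as neither rise nor drop.  Only glucose is ever
classified; insulin curves are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 4.5

BIPHASIC = "biphasic"
MONOPHASIC = "monophasic"
MONOTONIC = "monotonically_increasing"
INCONCLUSIVE = "inconclusive"

SHAPE_LABELS = (BIPHASIC, MONOPHASIC, MONOTONIC, INCONCLUSIVE)
#: the three classifiable shapes, in dummy-column order
CLASSIFIED_LABELS = (BIPHASIC, MONOPHASIC, MONOTONIC)


@dataclass(frozen=True)
class ShapeClass:
    """A shape label plus the evidence used to decide it.

    ``peak_index`` is the index (0..4) of the peak used by the decision;
    ``drop`` and ``rerise`` are the magnitudes (mg/dL) examined by the
    rules (NaN where a rule did not need them).
    """

    label: str
    peak_index: int | None
    drop: float
    rerise: float


def classify_shape(glucose, delta: float = DEFAULT_DELTA) -> ShapeClass:
    """Classify one 5-point glucose series; see module docstring for rules."""
    g = np.asarray(glucose, dtype=float).ravel()
    if g.size != 5:
        raise ValueError(f"expected 5 glucose values, got {g.size}")
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite glucose values")

    # (a) no rise above fasting at 30 or 60 min
    if g[1] <= g[0] and g[2] <= g[0]:
        return ShapeClass(INCONCLUSIVE, None, np.nan, np.nan)

    # (b) never falls more than delta below the running maximum
    runmax = np.maximum.accumulate(g)
    drops = runmax - g
    if drops.max() <= delta:
        return ShapeClass(MONOTONIC, int(np.argmax(g)), float(drops.max()), np.nan)

    # initial peak: first running maximum that is later undercut
    peak = None
    for p in range(5):
        if g[p] == runmax[p] and np.any(g[p + 1:] < g[p]):
            peak = p
            break
    assert peak is not None  # guaranteed: a drop > delta exists

    # (c) drop >= delta from the initial peak, then re-rise >= delta
    for m in range(peak + 1, 5):
        if g[m] >= g[peak]:
            continue
        drop = g[peak] - g[m]
        rerise = float(np.max(g[m + 1:]) - g[m]) if m < 4 else -np.inf
        if drop >= delta and rerise >= delta:
            return ShapeClass(BIPHASIC, peak, float(drop), rerise)

    # (d) monophasic
    gpeak = int(np.argmax(g))
    drop = float(g[gpeak] - np.min(g[gpeak:]))
    post = g[gpeak:]
    runmin = np.minimum.accumulate(post)
    rerise = float(np.max(post - runmin)) if post.size > 1 else 0.0
    return ShapeClass(MONOPHASIC, gpeak, drop, rerise)


def classify_cohort(
    glucose_matrix: np.ndarray, delta: float = DEFAULT_DELTA
) -> list[ShapeClass]:
    """Classify every row of an (n, 5) glucose matrix."""
    G = np.atleast_2d(np.asarray(glucose_matrix, dtype=float))
    return [classify_shape(row, delta) for row in G]


def shape_dummies(labels) -> pd.DataFrame:
    """Dichotomous 0/1 indicator columns for the three classifiable shapes.

    Inconclusive rows are dropped (their count is logged and stored in
    ``df.attrs['n_excluded']``); remaining rows keep their original index
    and each sums to exactly 1 across the three columns.
    """
    s = pd.Series(labels)
    bad = ~s.isin(SHAPE_LABELS)
    if bad.any():
        raise ValueError(f"unknown shape labels: {sorted(s[bad].unique())}")
    keep = s != INCONCLUSIVE
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluding %d participant(s) with inconclusive shape",
                    n_excluded)
    s = s[keep]
    df = pd.DataFrame(
        {lab: (s == lab).astype(int) for lab in CLASSIFIED_LABELS},
        index=s.index,
    )
    df.attrs["n_excluded"] = n_excluded
    return df
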