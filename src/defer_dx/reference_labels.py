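"""Consensus reference standards from multi-reader panels.

The binary reference label for an image is the majority vote of its
panel's binarized reads (rating >= 5 is a positive read); an exact tie
falls through to the mean of the raw 1-8 ratings, positive iff the mean is
>= 4.5 (inclusive).  Because a reader's own reads must never influence the
labels they are evaluated against, the leave-one-reader-out (LOO) variant
rebuilds the labels once per reader with that reader's reads deleted.

An image is *difficult* (for a given exclusion) when at least two of the
retained panel's binary reads disagree with the consensus label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientPanelError
from .scale_mapping import DECISION_THRESHOLD, reader_is_uncertain

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "DifficultyFlags",
    "consensus_labels",
    "loo_label_sets",
    "difficulty_flags",
    "reader_uncertain_flags",
    "MIN_PANEL_DESIGN",
]

#: The study design calls for panels of at least six readers; smaller
#: panels are legal (small fixtures) but logged as a warning.
MIN_PANEL_DESIGN = 6


@dataclass(frozen=True)
class LabelSet:
    """Binary reference labels plus per-image panel bookkeeping.

    ``table`` is indexed by image_id with columns ``label`` (0/1),
    ``panel_size``, ``n_agree`` (binary reads agreeing with the label) and
    ``mean_rating``.  ``excluded_reader`` records the reader (if any) whose
    reads were removed before construction.
    """

    table: pd.DataFrame
    excluded_reader: str | None = None

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def n_disagree(self) -> pd.Series:
        return self.table["panel_size"] - self.table["n_agree"]


@dataclass(frozen=True)
class DifficultyFlags:
    """Per-image difficult flag under a given reader exclusion."""

    flags: pd.Series  # bool, indexed by image_id
    excluded_reader: str | None = None


def consensus_labels(ratings: pd.DataFrame, excluded_reader: str | None = None) -> LabelSet:
    """Majority-vote reference labels with the mean-rating tie-break.

    ``ratings`` is long-format with columns reader_id, image_id, rating.
    Images left with fewer than two reads after excluding
    ``excluded_reader`` raise :class:`InsufficientPanelError`.
    """
    all_images = pd.Index(ratings["image_id"].unique(), name="image_id")
    df = ratings
    if excluded_reader is not None:
        df = ratings[ratings["reader_id"] != excluded_reader]

    grouped = df.groupby("image_id")["rating"]
    n = grouped.size().reindex(all_images, fill_value=0)
    short = n[n < 2]
    if len(short):
        raise InsufficientPanelError(short.index.tolist(), excluded_reader)
    # leave-one-out exclusions legitimately shrink 6-reader panels to 5,
    # so the design warning only fires for the all-reader consensus
    if excluded_reader is None and (n < MIN_PANEL_DESIGN).any():
        logger.warning(
            "%d image(s) have panels smaller than the %d-reader study design",
            int((n < MIN_PANEL_DESIGN).sum()),
            MIN_PANEL_DESIGN,
        )

    positive = (df["rating"] >= 5).groupby(df["image_id"]).sum().reindex(all_images)
    mean_rating = grouped.mean().reindex(all_images)
    negative = n - positive
    label = (positive > negative) | ((positive == negative) & (mean_rating >= DECISION_THRESHOLD))
    n_agree = np.where(label, positive, negative)

    table = pd.DataFrame(
        {
            "label": label.astype(int),
            "panel_size": n.astype(int),
            "n_agree": n_agree.astype(int),
            "mean_rating": mean_rating,
        },
        index=all_images,
    ).sort_index()
    return LabelSet(table=table, excluded_reader=excluded_reader)


def loo_label_sets(ratings: pd.DataFrame) -> dict[str, LabelSet]:
    """One leave-one-reader-out LabelSet per reader appearing in ``ratings``."""
    readers = sorted(ratings["reader_id"].unique())
    return {r: consensus_labels(ratings, excluded_reader=r) for r in readers}


def difficulty_flags(ratings: pd.DataFrame, label_set: LabelSet) -> DifficultyFlags:
    """Flag images where >= 2 retained binary reads disagree with the label.

    ``label_set`` must have been built from the same ratings with the same
    exclusion; coverage mismatches raise :class:`AlignmentError`.
    """
    df = ratings
    if label_set.excluded_reader is not None:
        df = ratings[ratings["reader_id"] != label_set.excluded_reader]

    rated = pd.Index(df["image_id"].unique())
    labeled = label_set.table.index
    missing = rated.symmetric_difference(labeled)
    if len(missing):
        raise AlignmentError("ratings and label set cover different images", missing)

    binary = (df["rating"] >= 5).astype(int)
    label_per_read = df["image_id"].map(label_set.labels)
    n_disagree = (binary != label_per_read).groupby(df["image_id"]).sum()
    flags = (n_disagree >= 2).reindex(labeled).sort_index()
    flags.name = "difficult"
    return DifficultyFlags(flags=flags, excluded_reader=label_set.excluded_reader)


def reader_uncertain_flags(ratings: pd.DataFrame, reader_id: str) -> pd.Series:
    """Per-image equivocal flag (rating in {4, 5}) for one reader's reads."""
    own = ratings[ratings["reader_id"] == reader_id]
    flags = pd.Series(
        reader_is_uncertain(own["rating"].to_numpy()),
        index=pd.Index(own["image_id"], name="image_id"),
        name="uncertain",
    )
    return flags.sort_index()
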