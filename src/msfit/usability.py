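"""Descriptive statistics for 5-point Likert questionnaires.

Ships the 9-participant x 8-item usability questionnaire of the study as a
packaged fixture and computes per-item means and sample standard deviations
(n-1 denominator), rounded to two decimals with half-up rounding — the
convention that reproduces the published table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib.resources import files

import numpy as np

from .errors import ValidationError

LIKERT_MIN, LIKERT_MAX = 1, 5


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half-up to ``ndigits`` decimals (0.005 -> 0.01, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class QuestionnaireItem:
    item_id: str
    domain: str
    question: str


@dataclass
class QuestionnaireTable:
    """Participants x items Likert score matrix with item metadata."""

    items: list[QuestionnaireItem]
    scores: np.ndarray  # (n_participants, n_items) integers
    participant_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a 2-D matrix")
        n_p, n_i = self.scores.shape
        if n_i != len(self.items):
            raise ValidationError("score columns must match the item list")
        if n_p != len(self.participant_ids):
            raise ValidationError("score rows must match the participant list")
        if self.scores.size and (
            self.scores.min() < LIKERT_MIN or self.scores.max() > LIKERT_MAX
        ):
            raise ValidationError(
                f"scores must lie in [{LIKERT_MIN}, {LIKERT_MAX}]"
            )

    def item_scores(self, item_id: str) -> list[int]:
        for j, item in enumerate(self.items):
            if item.item_id == item_id:
                return [int(v) for v in self.scores[:, j]]
        raise ValidationError(f"unknown item: {item_id!r}")


@dataclass(frozen=True)
class ItemStats:
    item_id: str
    mean: float
    sd: float


def item_stats(scores: list[int], item_id: str = "") -> ItemStats:
    """Mean and sample SD (n-1) of one item's scores, rounded to 2 decimals."""
    if len(scores) < 2:
        raise ValidationError("item_stats needs at least 2 scores")
    for s in scores:
        if not (LIKERT_MIN <= s <= LIKERT_MAX):
            raise ValidationError(f"score {s} outside [{LIKERT_MIN}, {LIKERT_MAX}]")
    n = len(scores)
    mean_exact = Fraction(sum(scores), n)
    # Sample variance is exact in rationals; only the sqrt goes through floats.
    var_exact = Fraction(sum((Fraction(s) - mean_exact) ** 2 for s in scores), n - 1)
    mean = float(
        (Decimal(mean_exact.numerator) / Decimal(mean_exact.denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    sd = round_half_up(math.sqrt(float(var_exact)), 2)
    return ItemStats(item_id=item_id, mean=mean, sd=sd)


def stats_table(table: QuestionnaireTable) -> list[ItemStats]:
    """Per-item stats in table order."""
    return [
        item_stats([int(v) for v in table.scores[:, j]], item_id=item.item_id)
        for j, item in enumerate(table.items)
    ]


def item_mean_range(stats: list[ItemStats]) -> tuple[float, float]:
    """(min, max) of the rounded per-item means."""
    if not stats:
        raise ValidationError("item_mean_range needs at least 1 item")
    means = [s.mean for s in stats]
    return (min(means), max(means))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _table_from_wide_df(df) -> QuestionnaireTable:
    meta_cols = ["item_id", "domain", "question"]
    participant_cols = [c for c in df.columns if c not in meta_cols]
    items = [
        QuestionnaireItem(row["item_id"], row["domain"], row["question"])
        for _, row in df.iterrows()
    ]
    scores = df[participant_cols].to_numpy(dtype=int).T  # participants x items
    return QuestionnaireTable(
        items=items, scores=scores, participant_ids=list(participant_cols)
    )


def load_fixture() -> QuestionnaireTable:
    """The packaged 9x8 usability questionnaire score matrix."""
    import pandas as pd

    with files("msfit").joinpath("data/table2.csv").open() as fh:
        df = pd.read_csv(fh)
    return _table_from_wide_df(df)


def read_questionnaire_csv(path: str) -> QuestionnaireTable:
    """Read a questionnaire from CSV.

    Accepts either the wide fixture layout (``item_id,domain,question,P1,...``)
    or a long layout with columns ``participant_id,item_id,score``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if {"participant_id", "item_id", "score"}.issubset(df.columns):
        wide = df.pivot(index="participant_id", columns="item_id", values="score")
        item_order = list(dict.fromkeys(df["item_id"]))
        wide = wide[item_order]
        items = [QuestionnaireItem(i, "", "") for i in item_order]
        return QuestionnaireTable(
            items=items,
            scores=wide.to_numpy(dtype=int),
            participant_ids=[str(p) for p in wide.index],
        )
    if {"item_id", "domain", "question"}.issubset(df.columns):
        return _table_from_wide_df(df)
    raise ValidationError("unrecognized questionnaire CSV layout")
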