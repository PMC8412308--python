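"""Domain types and I/O for structured expert-judgement panels.

A *panel* is the long-format record of an elicitation exercise: each
participant gives, for each claim (a binary-outcome statement) and each
elicitation round, a three-point probability judgement — a lower bound
``L``, a best estimate ``B`` and an upper bound ``U`` with
``0 <= L <= B <= U <= 1``.  Panels may also carry per-claim binary
outcomes and per-participant proxy metadata (quiz score, comprehension
ratings, comment word counts, coded reason counts/codes) used by the
proxy-weighted aggregation methods.

Point-estimate-only panels (no bounds elicited) are represented with
``lower``/``upper`` set to NaN; methods that need intervals are then
unavailable and are skipped by the dispatcher.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSESSMENT_COLUMNS = ["participant_id", "claim_id", "round", "lower", "best", "upper"]

#: column names of the long (element/value) CSV dialect
_LONG_ELEMENTS = {
    "three_point_lower": "lower",
    "three_point_best": "best",
    "three_point_upper": "upper",
}


class PanelIntegrityError(ValueError):
    """A panel violates a structural invariant (ordering, duplicates...)."""


@dataclass(frozen=True)
class Assessment:
    """One participant's three-point judgement for one claim in one round."""

    participant_id: str
    claim_id: str
    round: int
    lower: float
    best: float
    upper: float

    def __post_init__(self):
        if self.round not in (1, 2):
            raise PanelIntegrityError(f"round must be 1 or 2, got {self.round}")
        if not (0.0 <= self.best <= 1.0):
            raise PanelIntegrityError(f"best estimate {self.best} outside [0, 1]")
        if self.has_bounds and not (
            0.0 <= self.lower <= self.best <= self.upper <= 1.0
        ):
            raise PanelIntegrityError(
                f"bounds must satisfy 0 <= L <= B <= U <= 1, got "
                f"({self.lower}, {self.best}, {self.upper})"
            )

    @property
    def has_bounds(self) -> bool:
        return not (np.isnan(self.lower) or np.isnan(self.upper))

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ClaimOutcome:
    """Resolved truth of a claim: 1 if it occurred / is true, else 0."""

    claim_id: str
    outcome: int

    def __post_init__(self):
        if self.outcome not in (0, 1):
            raise PanelIntegrityError(f"outcome must be 0 or 1, got {self.outcome}")


@dataclass(frozen=True)
class ParticipantMeta:
    """Optional proxy metadata attached to one participant.

    All fields except the identifier are optional; mappings are keyed by
    claim_id.  ``reason_counts`` must agree with ``len(reason_codes)``
    wherever both are present.
    """

    participant_id: str
    quiz_score: float | None = None
    comprehension: Mapping[str, int] = field(default_factory=dict)
    comment_words: Mapping[str, int] = field(default_factory=dict)
    reason_counts: Mapping[str, int] = field(default_factory=dict)
    reason_codes: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        for c, r in self.comprehension.items():
            if not 1 <= r <= 7:
                raise PanelIntegrityError(
                    f"comprehension rating {r} for claim {c} outside 1..7"
                )
        for name in ("comment_words", "reason_counts"):
            for c, v in getattr(self, name).items():
                if v < 0:
                    raise PanelIntegrityError(f"{name}[{c}] negative: {v}")
        for c, codes in self.reason_codes.items():
            if c in self.reason_counts and self.reason_counts[c] != len(codes):
                raise PanelIntegrityError(
                    f"reason_counts[{c}]={self.reason_counts[c]} != "
                    f"|reason_codes[{c}]|={len(codes)}"
                )


@dataclass(frozen=True)
class AggregateResult:
    """A pooled probability for one claim under one aggregation method."""

    claim_id: str
    method_id: str
    value: float
    n_experts: int

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"aggregated probability {self.value} outside [0, 1]")


class Panel:
    """A validated collection of assessments, outcomes and proxy metadata.

    Internally pandas-backed: ``assessments`` is a DataFrame with columns
    ``participant_id, claim_id, round, lower, best, upper``; ``outcomes``
    maps claim_id -> {0, 1}; ``quiz`` maps participant_id -> score;
    ``claim_meta`` has one row per (participant, claim) with columns
    ``comprehension, comment_words, reason_count, reason_codes``.
    """

    def __init__(
        self,
        assessments: pd.DataFrame,
        outcomes: pd.DataFrame | None = None,
        quiz: pd.DataFrame | None = None,
        claim_meta: pd.DataFrame | None = None,
        validate: bool = True,
    ):
        df = assessments.copy()
        for col in ("lower", "upper"):
            if col not in df.columns:
                df[col] = np.nan
        df = df[ASSESSMENT_COLUMNS].reset_index(drop=True)
        df["round"] = df["round"].astype(int)
        for col in ("lower", "best", "upper"):
            df[col] = df[col].astype(float)
        self.assessments = df
        self.outcomes = (
            outcomes.reset_index(drop=True)
            if outcomes is not None
            else pd.DataFrame(columns=["claim_id", "outcome"])
        )
        self.quiz = (
            quiz.reset_index(drop=True)
            if quiz is not None
            else pd.DataFrame(columns=["participant_id", "score"])
        )
        self.claim_meta = (
            claim_meta.reset_index(drop=True)
            if claim_meta is not None
            else pd.DataFrame(
                columns=[
                    "participant_id",
                    "claim_id",
                    "comprehension",
                    "comment_words",
                    "reason_count",
                    "reason_codes",
                ]
            )
        )
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        df = self.assessments
        if ((df["best"] < 0) | (df["best"] > 1)).any():
            bad = df.index[(df["best"] < 0) | (df["best"] > 1)].tolist()
            raise PanelIntegrityError(f"best estimate outside [0, 1] at rows {bad}")
        if not df["round"].isin([1, 2]).all():
            raise PanelIntegrityError("round must be 1 or 2")
        has_b = df["lower"].notna() & df["upper"].notna()
        if (df["lower"].notna() != df["upper"].notna()).any():
            raise PanelIntegrityError("lower/upper must be both present or both absent")
        sub = df[has_b]
        bad = sub.index[
            (sub["lower"] < 0)
            | (sub["lower"] > sub["best"])
            | (sub["best"] > sub["upper"])
            | (sub["upper"] > 1)
        ]
        if len(bad):
            raise PanelIntegrityError(
                "bounds violate 0 <= L <= B <= U <= 1 at rows "
                f"{bad.tolist()} (row numbers refer to the assessment table)"
            )
        dup = df.duplicated(["participant_id", "claim_id", "round"])
        if dup.any():
            raise PanelIntegrityError(
                "duplicate (participant, claim, round) rows: "
                f"{df.loc[dup, ['participant_id', 'claim_id', 'round']].values.tolist()}"
            )
        if self.outcomes["claim_id"].duplicated().any():
            raise PanelIntegrityError("more than one outcome for a claim")
        if not self.outcomes.empty and not self.outcomes["outcome"].isin([0, 1]).all():
            raise PanelIntegrityError("outcomes must be coded 0/1")
        if len(df) == 0:
            logger.warning("panel contains no assessments")

    # -- derived views ------------------------------------------------

    @property
    def claims(self) -> list:
        return sorted(self.assessments["claim_id"].unique())

    @property
    def participants(self) -> list:
        return sorted(self.assessments["participant_id"].unique())

    @property
    def rounds(self) -> list[int]:
        return sorted(self.assessments["round"].unique())

    @property
    def has_bounds(self) -> bool:
        """True when every assessment carries an elicited interval."""
        df = self.assessments
        return len(df) > 0 and bool(df["lower"].notna().all())

    @property
    def has_two_rounds(self) -> bool:
        return set(self.rounds) == {1, 2}

    def n_assessors(self, claim_id) -> int:
        df = self.analysis_round().assessments
        return int((df["claim_id"] == claim_id).sum())

    def assessors(self, claim_id) -> list:
        df = self.analysis_round().assessments
        return sorted(df.loc[df["claim_id"] == claim_id, "participant_id"].unique())

    def analysis_round(self) -> "Panel":
        """The panel restricted to the latest round per (participant, claim)."""
        return select_round(self, "latest")

    def claim_assessments(self, claim_id) -> list[Assessment]:
        df = self.analysis_round().assessments
        df = df[df["claim_id"] == claim_id]
        return [
            Assessment(r.participant_id, r.claim_id, int(r.round), r.lower, r.best, r.upper)
            for r in df.itertuples()
        ]

    def outcome_map(self) -> dict:
        return dict(zip(self.outcomes["claim_id"], self.outcomes["outcome"].astype(int)))

    def participant_meta(self, participant_id) -> ParticipantMeta:
        quiz = None
        q = self.quiz[self.quiz["participant_id"] == participant_id]
        if len(q):
            quiz = float(q["score"].iloc[0])
        cm = self.claim_meta[self.claim_meta["participant_id"] == participant_id]
        def col(name, cast):
            return {
                r.claim_id: cast(getattr(r, name))
                for r in cm.itertuples()
                if not pd.isna(getattr(r, name))
            }
        codes = {
            r.claim_id: frozenset(str(r.reason_codes).split(";"))
            for r in cm.itertuples()
            if isinstance(r.reason_codes, str) and r.reason_codes
        }
        return ParticipantMeta(
            participant_id,
            quiz_score=quiz,
            comprehension=col("comprehension", int),
            comment_words=col("comment_words", int),
            reason_counts=col("reason_count", int),
            reason_codes=codes,
        )

    def __repr__(self) -> str:
        return (
            f"Panel({len(self.assessments)} assessments, "
            f"{len(self.claims)} claims, {len(self.participants)} participants, "
            f"rounds={self.rounds}, bounds={self.has_bounds})"
        )


# ---------------------------------------------------------------------------
# operations


def clip_probability(p, eps: float = 0.01):
    """Clamp a probability (scalar or array) into ``[eps, 1 - eps]``.

    Used before logit transforms: judgements of exactly 0 or 1 are moved
    slightly away from the extremes so the log odds stay finite.
    """
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    return np.clip(p, eps, 1.0 - eps)


def select_round(panel: Panel, round: int | str = 2) -> Panel:
    """Restrict a panel to one assessment per (participant, claim).

    ``round`` is 1, 2 or ``"latest"``; the post-discussion round (2) is the
    conventional analysis round, and ``"latest"`` takes round 2 where
    present, otherwise round 1.
    """
    df = panel.assessments
    if round == "latest":
        idx = df.sort_values("round").groupby(
            ["participant_id", "claim_id"], sort=False
        )["round"].idxmax()
        keep = df.loc[sorted(idx)]
    else:
        round = int(round)
        if round not in panel.rounds:
            raise ValueError(
                f"round {round} absent from panel; available rounds: {panel.rounds}"
            )
        keep = df[df["round"] == round]
    return Panel(
        keep,
        outcomes=panel.outcomes,
        quiz=panel.quiz,
        claim_meta=panel.claim_meta,
        validate=False,
    )


def subsample_groups(
    panel: Panel, group_size: int, n_groups: int, seed: int
) -> list[Panel]:
    """Randomly split a large panel into tournament-style small groups.

    For each of ``n_groups`` groups and each claim, ``min(group_size,
    available)`` assessors are drawn without replacement (sampling is over
    participant IDs; all rounds of a chosen participant are kept).
    Deterministic given ``seed``.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    df = panel.assessments
    groups = []
    for _ in range(n_groups):
        masks = []
        for claim in panel.claims:
            sub = df[df["claim_id"] == claim]
            pids = sorted(sub["participant_id"].unique())
            take = min(group_size, len(pids))
            chosen = set(rng.choice(pids, size=take, replace=False))
            masks.append(sub[sub["participant_id"].isin(chosen)])
        groups.append(
            Panel(
                pd.concat(masks, ignore_index=True),
                outcomes=panel.outcomes,
                quiz=panel.quiz,
                claim_meta=panel.claim_meta,
                validate=False,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# I/O


def _parse_probability(x) -> float:
    """Parse a probability cell; percent strings like ``"60%"`` become 0.60."""
    if isinstance(x, str):
        x = x.strip()
        if x.endswith("%"):
            return float(x[:-1]) / 100.0
        if x == "":
            return np.nan
    return float(x)


def read_panel(
    path,
    dialect: str = "wide",
    outcomes_path=None,
    quiz_path=None,
    claim_meta_path=None,
) -> Panel:
    """Read a panel from CSV.

    ``dialect="wide"`` expects columns
    ``participant_id,claim_id,round,lower,best,upper`` (``lower``/``upper``
    optional for point-estimate-only panels); ``dialect="long"`` expects
    ``participant_id,claim_id,round,element,value`` with element in
    ``three_point_{lower,best,upper}``.  Probabilities written as
    percentages ("60%") are divided by 100.  Rows violating
    ``L <= B <= U`` raise :class:`PanelIntegrityError` naming the rows.
    """
    raw = pd.read_csv(path, dtype={"participant_id": str, "claim_id": str})
    if dialect == "long":
        missing = {"participant_id", "claim_id", "round", "element", "value"} - set(
            raw.columns
        )
        if missing:
            raise ValueError(f"long dialect missing columns {sorted(missing)}")
        bad = set(raw["element"]) - set(_LONG_ELEMENTS)
        if bad:
            raise ValueError(f"unknown long-dialect elements {sorted(bad)}")
        raw["value"] = raw["value"].map(_parse_probability)
        wide = raw.pivot_table(
            index=["participant_id", "claim_id", "round"],
            columns="element",
            values="value",
            aggfunc="first",
        ).reset_index()
        wide = wide.rename(columns=_LONG_ELEMENTS).rename_axis(columns=None)
        df = wide
    elif dialect == "wide":
        missing = {"participant_id", "claim_id", "round", "best"} - set(raw.columns)
        if missing:
            raise ValueError(f"wide dialect missing columns {sorted(missing)}")
        df = raw
        for col in ("lower", "best", "upper"):
            if col in df.columns:
                df[col] = df[col].map(_parse_probability)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    outcomes = quiz = claim_meta = None
    if outcomes_path is not None:
        outcomes = pd.read_csv(outcomes_path, dtype={"claim_id": str})
    if quiz_path is not None:
        quiz = pd.read_csv(quiz_path, dtype={"participant_id": str})
    if claim_meta_path is not None:
        claim_meta = pd.read_csv(
            claim_meta_path,
            dtype={"participant_id": str, "claim_id": str, "reason_codes": str},
        )
    return Panel(df, outcomes=outcomes, quiz=quiz, claim_meta=claim_meta)


def write_panel(panel: Panel, path) -> None:
    """Write the wide-dialect assessment CSV (full float precision)."""
    df = panel.assessments.copy()
    df.to_csv(path, index=False, float_format="%.17g")
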