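"""Proxy-weighted linear opinion pools.

Thirteen differentially weighted combinations of best estimates, all of
the form ``p_hat_c = sum_i w_tilde_{i,c} * B_{i,c}`` with per-claim
normalised weights.  The weights are built from observable *proxies* for
forecasting skill — properties of the judgements themselves (interval
width, asymmetry, shift after discussion, granularity of the point
estimates) or participant metadata (comment length, coded reasons, quiz
score, self-rated comprehension) — rather than from scored past
performance, which is rarely available in practice.

Unnormalised weight recipes (``eps`` keeps every weight strictly
positive; ``d = U - L`` is the interval width):

========================  ====================================================
IntWAgg                   1 / (d_{i,c} + eps)
IndIntWAgg                1 / (r_{i,c} + eps), r = d / max_c' d_{i,c'}
VarIndIntWAgg             Var_c(d_{i,.}) + eps (constant across i's claims)
AsymWAgg                  a_{i,c} + eps, a = |B - (L+U)/2| / ((U-L)/2)
IndIntAsymWAgg            w~_IndIntWAgg * w~_AsymWAgg, renormalised
KitchSinkWAgg             w~_IndIntWAgg * w~_AsymWAgg * w~_VarIndIntWAgg
DistLimitWAgg             max(B, 1 - B)
ShiftWAgg                 eps + |B2-B1| + (|L2-L1| + |U2-U1|) / 4
GranWAgg                  eps + fraction of i's best estimates off the
                          0.05 grid (per participant)
EngWAgg                   eps + comment word count (per claim)
ReasonWAgg                eps + count of unique coded reasons (per claim)
ReasonWAgg2               (eps + reason count) * (1 + D_i), D_i the share
                          of the full codebook participant i ever used
QuizWAgg                  eps + quiz score (per participant)
CompWAgg                  comprehension rating on the 1..7 scale
========================  ====================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Assessment, AggregateResult, Panel, select_round

logger = logging.getLogger(__name__)

INTERVAL_VARIANTS = ("IntWAgg", "IndIntWAgg", "VarIndIntWAgg")
SHAPE_VARIANTS = ("AsymWAgg", "IndIntAsymWAgg", "KitchSinkWAgg")
ESTIMATE_VARIANTS = ("DistLimitWAgg", "GranWAgg")
METADATA_VARIANTS = ("EngWAgg", "ReasonWAgg", "ReasonWAgg2", "QuizWAgg", "CompWAgg")
ALL_WEIGHTED = (
    INTERVAL_VARIANTS
    + SHAPE_VARIANTS
    + ESTIMATE_VARIANTS
    + ("ShiftWAgg",)
    + METADATA_VARIANTS
)


@dataclass(frozen=True)
class WeightVector:
    """Normalised weights over the assessors of one claim."""

    claim_id: str
    weights: Mapping[str, float]
    method_id: str

    def __post_init__(self):
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError(f"negative weight in {self.method_id}/{self.claim_id}")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"weights for claim {self.claim_id} sum to {w.sum()!r}, not 1"
            )


def weighted_pool(
    assessments: Sequence[Assessment], weights: WeightVector
) -> AggregateResult:
    """Convex combination of the assessors' best estimates."""
    by_pid = {a.participant_id: a for a in assessments}
    if set(by_pid) != set(weights.weights):
        raise ValueError(
            f"weight support {sorted(weights.weights)} does not match "
            f"assessors {sorted(by_pid)} for claim {weights.claim_id}"
        )
    value = float(
        sum(w * by_pid[pid].best for pid, w in weights.weights.items())
    )
    return AggregateResult(
        claim_id=weights.claim_id,
        method_id=weights.method_id,
        value=min(max(value, 0.0), 1.0),
        n_experts=len(by_pid),
    )


# ---------------------------------------------------------------------------
# unnormalised weight tables
#
# All computations run on the analysis-round assessment table with columns
# participant_id, claim_id, lower, best, upper; they return a DataFrame
# [claim_id, participant_id, weight] of *unnormalised* weights.


def _require_bounds(df: pd.DataFrame, variant: str) -> None:
    if df["lower"].isna().any() or df["upper"].isna().any():
        raise ValueError(f"{variant} requires elicited lower/upper bounds")


def _interval_raw(df: pd.DataFrame, variant: str, eps: float) -> pd.Series:
    _require_bounds(df, variant)
    d = df["upper"] - df["lower"]
    if variant == "IntWAgg":
        return 1.0 / (d + eps)
    if variant == "IndIntWAgg":
        max_d = d.groupby(df["participant_id"]).transform("max").clip(lower=eps)
        r = d / max_d
        return 1.0 / (r + eps)
    if variant == "VarIndIntWAgg":
        var = d.groupby(df["participant_id"]).transform(
            lambda s: s.var(ddof=1) if len(s) > 1 else 0.0
        )
        single = df["participant_id"].map(
            df.groupby("participant_id").size() == 1
        )
        if single.any():
            logger.warning(
                "VarIndIntWAgg: participants with a single claim get weight eps"
            )
        return var + eps
    raise ValueError(f"unknown interval variant {variant!r}")


def _asymmetry(df: pd.DataFrame) -> pd.Series:
    """a = |B - midpoint| / half-width, in [0, 1]; 0 for zero-width intervals."""
    half = (df["upper"] - df["lower"]) / 2.0
    mid = (df["upper"] + df["lower"]) / 2.0
    a = (df["best"] - mid).abs() / half.where(half > 0, np.nan)
    return a.fillna(0.0)


def _normalise(raw: pd.DataFrame) -> pd.DataFrame:
    out = raw.copy()
    out["weight"] = out["weight"] / out.groupby("claim_id")["weight"].transform("sum")
    return out


def _shape_raw(df: pd.DataFrame, variant: str, eps: float) -> pd.Series:
    _require_bounds(df, variant)
    if variant == "AsymWAgg":
        return _asymmetry(df) + eps
    # composite variants multiply the *normalised* component weights
    parts = {
        "IndIntAsymWAgg": ("IndIntWAgg", "AsymWAgg"),
        "KitchSinkWAgg": ("IndIntWAgg", "AsymWAgg", "VarIndIntWAgg"),
    }[variant]
    prod = pd.Series(1.0, index=df.index)
    for p in parts:
        raw = df[["claim_id", "participant_id"]].copy()
        if p in INTERVAL_VARIANTS:
            raw["weight"] = _interval_raw(df, p, eps)
        else:
            raw["weight"] = _asymmetry(df) + eps
        prod = prod * _normalise(raw)["weight"]
    return prod


def _estimate_raw(df: pd.DataFrame, variant: str, eps: float) -> pd.Series:
    if variant == "DistLimitWAgg":
        return np.maximum(df["best"], 1.0 - df["best"])
    if variant == "GranWAgg":
        b4 = df["best"].round(4)
        off_grid = (b4 - 0.05 * (b4 / 0.05).round()).abs() > 1e-9
        frac = off_grid.groupby(df["participant_id"]).transform("mean")
        return frac + eps
    raise ValueError(f"unknown estimate variant {variant!r}")


def _metadata_raw(panel: Panel, df: pd.DataFrame, variant: str, eps: float) -> pd.Series:
    meta = panel.claim_meta.set_index(["participant_id", "claim_id"])
    idx = pd.MultiIndex.from_frame(df[["participant_id", "claim_id"]])

    def lookup(col):
        s = meta[col] if col in meta.columns else pd.Series(dtype=float)
        return pd.Series(s.reindex(idx).to_numpy(dtype=object), index=df.index)

    if variant == "EngWAgg":
        words = pd.to_numeric(lookup("comment_words"), errors="coerce")
        _check_any(words, df, variant)
        return words.fillna(0.0) + eps
    if variant in ("ReasonWAgg", "ReasonWAgg2"):
        counts = pd.to_numeric(lookup("reason_count"), errors="coerce")
        _check_any(counts, df, variant)
        w = counts.fillna(0.0) + eps
        if variant == "ReasonWAgg2":
            codes = {}
            cm = panel.claim_meta
            for r in cm.itertuples():
                if isinstance(r.reason_codes, str) and r.reason_codes:
                    codes.setdefault(r.participant_id, set()).update(
                        r.reason_codes.split(";")
                    )
            codebook = set().union(*codes.values()) if codes else set()
            diversity = {
                pid: len(c) / len(codebook) if codebook else 0.0
                for pid, c in codes.items()
            }
            w = w * (1.0 + df["participant_id"].map(diversity).fillna(0.0))
        return w
    if variant == "QuizWAgg":
        scores = dict(
            zip(panel.quiz["participant_id"], panel.quiz["score"].astype(float))
        )
        s = df["participant_id"].map(scores)
        _check_any(s, df, variant)
        fallback = float(np.mean(list(scores.values()))) if scores else 0.0
        if s.isna().any():
            logger.warning("QuizWAgg: missing quiz scores filled with cohort mean")
        return s.fillna(fallback) + eps
    if variant == "CompWAgg":
        comp = pd.to_numeric(lookup("comprehension"), errors="coerce")
        _check_any(comp, df, variant)
        if comp.isna().any():
            logger.warning("CompWAgg: missing ratings set to the scale minimum (1)")
        return comp.fillna(1.0)
    raise ValueError(f"unknown metadata variant {variant!r}")


def _check_any(series: pd.Series, df: pd.DataFrame, variant: str) -> None:
    present = series.notna()
    missing_claims = sorted(
        set(df["claim_id"]) - set(df.loc[present, "claim_id"])
    )
    if missing_claims:
        raise ValueError(
            f"{variant}: required metadata absent for every assessor of "
            f"claims {missing_claims}"
        )


def _shift_raw(panel: Panel, eps: float) -> pd.DataFrame:
    """eps + |B2-B1| + (|L2-L1| + |U2-U1|)/4, on the round-2 table."""
    df = panel.assessments
    if not panel.has_two_rounds:
        raise ValueError("ShiftWAgg requires both elicitation rounds")
    r1 = df[df["round"] == 1].set_index(["participant_id", "claim_id"])
    r2 = df[df["round"] == 2].reset_index(drop=True)
    idx = pd.MultiIndex.from_frame(r2[["participant_id", "claim_id"]])
    prev = r1.reindex(idx)
    shift_b = (r2["best"].to_numpy() - prev["best"].to_numpy())
    shift_l = (r2["lower"].to_numpy() - prev["lower"].to_numpy())
    shift_u = (r2["upper"].to_numpy() - prev["upper"].to_numpy())
    with np.errstate(invalid="ignore"):
        w = (
            np.abs(shift_b)
            + (np.nan_to_num(np.abs(shift_l)) + np.nan_to_num(np.abs(shift_u))) / 4.0
        )
    missing = np.isnan(shift_b)
    if missing.any():
        logger.warning(
            "ShiftWAgg: %d round-2 assessments lack a round-1 counterpart; "
            "their weight falls back to eps",
            int(missing.sum()),
        )
    w = np.where(missing, 0.0, w) + eps
    out = r2[["claim_id", "participant_id"]].copy()
    out["weight"] = w
    return out


# ---------------------------------------------------------------------------
# public per-variant entry points


def _to_weight_vectors(norm: pd.DataFrame, method_id: str) -> dict[str, WeightVector]:
    out = {}
    for claim, grp in norm.groupby("claim_id", sort=True):
        w = dict(zip(grp["participant_id"], grp["weight"].astype(float)))
        total = sum(w.values())
        w = {pid: v / total for pid, v in w.items()}  # exact renormalisation
        out[claim] = WeightVector(claim_id=claim, weights=w, method_id=method_id)
    return out


def _analysis_table(panel: Panel) -> pd.DataFrame:
    return panel.analysis_round().assessments.reset_index(drop=True)


def interval_weights(
    panel: Panel, variant: str, eps: float = 0.01
) -> dict[str, WeightVector]:
    """Width-based weights: IntWAgg, IndIntWAgg, VarIndIntWAgg."""
    if variant not in INTERVAL_VARIANTS:
        raise ValueError(f"variant must be one of {INTERVAL_VARIANTS}")
    df = _analysis_table(panel)
    raw = df[["claim_id", "participant_id"]].copy()
    raw["weight"] = _interval_raw(df, variant, eps)
    return _to_weight_vectors(_normalise(raw), variant)


def shape_weights(
    panel: Panel, variant: str, eps: float = 0.01
) -> dict[str, WeightVector]:
    """Asymmetry-based and composite weights: AsymWAgg, IndIntAsymWAgg, KitchSinkWAgg."""
    if variant not in SHAPE_VARIANTS:
        raise ValueError(f"variant must be one of {SHAPE_VARIANTS}")
    df = _analysis_table(panel)
    raw = df[["claim_id", "participant_id"]].copy()
    raw["weight"] = _shape_raw(df, variant, eps)
    return _to_weight_vectors(_normalise(raw), variant)


def estimate_weights(
    panel: Panel, variant: str, eps: float = 0.01
) -> dict[str, WeightVector]:
    """Best-estimate-based weights: DistLimitWAgg, GranWAgg."""
    if variant not in ESTIMATE_VARIANTS:
        raise ValueError(f"variant must be one of {ESTIMATE_VARIANTS}")
    df = _analysis_table(panel)
    raw = df[["claim_id", "participant_id"]].copy()
    raw["weight"] = _estimate_raw(df, variant, eps)
    return _to_weight_vectors(_normalise(raw), variant)


def shift_weights(panel: Panel, eps: float = 0.01) -> dict[str, WeightVector]:
    """Weights proportional to the movement of estimates after discussion."""
    raw = _shift_raw(panel, eps)
    return _to_weight_vectors(_normalise(raw), "ShiftWAgg")


def metadata_weights(
    panel: Panel, variant: str, eps: float = 0.01
) -> dict[str, WeightVector]:
    """Metadata-proxy weights: EngWAgg, ReasonWAgg, ReasonWAgg2, QuizWAgg, CompWAgg."""
    if variant not in METADATA_VARIANTS:
        raise ValueError(f"variant must be one of {METADATA_VARIANTS}")
    df = _analysis_table(panel)
    raw = df[["claim_id", "participant_id"]].copy()
    raw["weight"] = _metadata_raw(panel, df, variant, eps)
    return _to_weight_vectors(_normalise(raw), variant)


def weights_for(
    panel: Panel, method_id: str, eps: float = 0.01
) -> dict[str, WeightVector]:
    """Dispatch to the weight family owning ``method_id``."""
    if method_id in INTERVAL_VARIANTS:
        return interval_weights(panel, method_id, eps)
    if method_id in SHAPE_VARIANTS:
        return shape_weights(panel, method_id, eps)
    if method_id in ESTIMATE_VARIANTS:
        return estimate_weights(panel, method_id, eps)
    if method_id == "ShiftWAgg":
        return shift_weights(panel, eps)
    if method_id in METADATA_VARIANTS:
        return metadata_weights(panel, method_id, eps)
    raise ValueError(f"{method_id!r} is not a weighted-pool method")
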