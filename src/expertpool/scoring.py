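"""Performance measures for probabilistic claim forecasts.

Four measures, applicable to an individual expert's predictions or to an
aggregation method's pooled predictions (a "virtual expert"):

* **accuracy** — the average Brier score, mean over claims of
  ``(p - x)^2`` (default single-term convention, range [0, 1]; the
  two-outcome sum ``sum_j (p_j - x_j)^2 = 2 (p - x)^2`` is available as
  ``variant="two_term"``), and the area under the ROC curve;
* **calibration** — predictions are assigned to ten probability bins
  ``Bin_k`` with nominal probability ``p_k = k/10``; the calibration term
  of the Brier decomposition is ``sum_k c_k (p_k - s_k)^2 / C`` where
  ``c_k`` claims land in bin k and ``s_k`` of them occur (0 is perfect);
* **informativeness** — the mean Kullback–Leibler divergence of the
  chosen bin from the uniform (0.5, 0.5) bin; 0 iff everything sits at
  0.5, larger when predictions venture toward the certainty limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionSet",
    "BinProfile",
    "ScoreReport",
    "brier_score",
    "roc_auc",
    "assign_bins",
    "calibration_score",
    "informativeness",
    "score_methods",
    "score_table",
]


@dataclass(frozen=True)
class PredictionSet:
    """Per-claim probabilities issued by one source (expert or method)."""

    source_id: str
    entries: Mapping[str, float]

    def __post_init__(self):
        bad = {c: p for c, p in self.entries.items() if not 0.0 <= p <= 1.0}
        if bad:
            raise ValueError(f"probabilities outside [0, 1]: {bad}")


@dataclass(frozen=True)
class BinProfile:
    """Occupancy of the ten probability bins ``p_k = k/10``.

    ``counts[k-1]`` claims were assigned to bin k; ``occurred[k-1]`` is
    the empirical proportion of those that occurred (NaN for empty bins
    or when no outcomes were supplied).
    """

    counts: np.ndarray    # shape (10,), int
    occurred: np.ndarray  # shape (10,), float with NaN for empty bins

    @property
    def p_k(self) -> np.ndarray:
        return np.arange(1, 11) / 10.0

    @property
    def n_claims(self) -> int:
        return int(self.counts.sum())


def _aligned(preds: PredictionSet, outcomes) -> tuple[np.ndarray, np.ndarray]:
    omap = _outcome_map(outcomes)
    common = [c for c in preds.entries if c in omap]
    if not common:
        raise ValueError(
            f"no claims with both a prediction and an outcome for {preds.source_id}"
        )
    p = np.array([preds.entries[c] for c in common], dtype=float)
    x = np.array([omap[c] for c in common], dtype=float)
    return p, x


def _outcome_map(outcomes) -> dict:
    if isinstance(outcomes, Mapping):
        return dict(outcomes)
    if isinstance(outcomes, pd.DataFrame):
        return dict(zip(outcomes["claim_id"], outcomes["outcome"].astype(int)))
    return {o.claim_id: o.outcome for o in outcomes}


def brier_score(preds: PredictionSet, outcomes, variant: str = "single_term") -> float:
    """Average Brier score; 0 is perfect.

    ``single_term`` (default) is ``mean (p - x)^2`` in [0, 1];
    ``two_term`` sums over both outcomes of each claim, in [0, 2].
    """
    p, x = _aligned(preds, outcomes)
    base = float(np.mean((p - x) ** 2))
    if variant == "single_term":
        return base
    if variant == "two_term":
        return 2.0 * base
    raise ValueError(f"unknown Brier variant {variant!r}")


def roc_auc(preds: PredictionSet, outcomes) -> float:
    """Area under the ROC curve (Mann–Whitney concordance, ties at 1/2)."""
    p, x = _aligned(preds, outcomes)
    if len(np.unique(x)) < 2:
        raise ValueError("AUC undefined: only one outcome class present")
    return float(roc_auc_score(x, p))


def _bin_of(p: np.ndarray) -> np.ndarray:
    """k = clamp(round(10 p), 1, 10), rounding half-up; no zero bin exists."""
    return np.clip(np.floor(10.0 * p + 0.5).astype(int), 1, 10)


def assign_bins(preds: PredictionSet, outcomes=None) -> BinProfile:
    """Assign each prediction to its probability bin, tallying outcomes."""
    claims = list(preds.entries)
    p = np.array([preds.entries[c] for c in claims], dtype=float)
    k = _bin_of(p)
    counts = np.bincount(k, minlength=11)[1:11]
    occurred = np.full(10, np.nan)
    if outcomes is not None:
        omap = _outcome_map(outcomes)
        x = np.array([omap.get(c, np.nan) for c in claims], dtype=float)
        for b in range(1, 11):
            sel = (k == b) & ~np.isnan(x)
            if sel.any():
                occurred[b - 1] = float(x[sel].mean())
        counts = np.array(
            [int(((k == b) & ~np.isnan(x)).sum()) for b in range(1, 11)]
        )
    return BinProfile(counts=counts, occurred=occurred)


def calibration_score(profile: BinProfile) -> float:
    """Calibration term of the Brier decomposition: sum c_k (p_k - s_k)^2 / C."""
    C = profile.n_claims
    if C < 1:
        raise ValueError("empty bin profile")
    mask = profile.counts > 0
    s = profile.occurred[mask]
    if np.isnan(s).any():
        raise ValueError("calibration needs outcomes for every occupied bin")
    p = profile.p_k[mask]
    return float(np.sum(profile.counts[mask] * (p - s) ** 2) / C)


def informativeness(preds: PredictionSet, log_base: str = "natural") -> float:
    """Mean KL divergence of the chosen bin from the uniform (0.5, 0.5) bin.

    Does not require outcomes; 0 iff every prediction is binned at 0.5.
    """
    profile = assign_bins(preds)
    C = profile.n_claims
    if C < 1:
        raise ValueError("no predictions to score")
    p = profile.p_k
    kl = rel_entr(p, np.full(10, 0.5)) + rel_entr(1.0 - p, np.full(10, 0.5))
    value = float(np.sum(profile.counts * kl) / C)
    if log_base == "base2":
        return value / np.log(2.0)
    if log_base != "natural":
        raise ValueError(f"unknown log base {log_base!r}")
    return value


@dataclass(frozen=True)
class ScoreReport:
    """The four measures for one prediction source against outcomes."""

    source_id: str
    avg_brier: float
    auc: float  # NaN when only one outcome class is present
    calibration: float
    informativeness: float
    n_claims: int
    n_unscored: int = 0  # predictions without an outcome


def score_predictions(
    preds: PredictionSet,
    outcomes,
    brier_variant: str = "single_term",
    log_base: str = "natural",
) -> ScoreReport:
    """All four measures for one prediction set."""
    omap = _outcome_map(outcomes)
    scored = {c: p for c, p in preds.entries.items() if c in omap}
    n_unscored = len(preds.entries) - len(scored)
    sub = PredictionSet(preds.source_id, scored)
    try:
        auc = roc_auc(sub, omap)
    except ValueError:
        logger.warning("AUC undefined for %s (single outcome class)", preds.source_id)
        auc = float("nan")
    return ScoreReport(
        source_id=preds.source_id,
        avg_brier=brier_score(sub, omap, brier_variant),
        auc=auc,
        calibration=calibration_score(assign_bins(sub, omap)),
        informativeness=informativeness(sub, log_base),
        n_claims=len(scored),
        n_unscored=n_unscored,
    )


def score_methods(panel, methods: Sequence[str], config=None) -> list[ScoreReport]:
    """Aggregate a panel under each method and score the pooled predictions.

    Methods whose required inputs (bounds, rounds, metadata, priors) are
    absent from the panel are skipped with a logged reason; reports come
    back ordered from best to worst average Brier score.
    """
    from .methods import aggregate_panel, available_methods
    from .config import RunConfig

    config = config or RunConfig()
    if panel.outcomes.empty:
        raise ValueError("scoring requires claim outcomes")
    runnable, skipped = available_methods(panel, methods, config)
    for m, reason in skipped.items():
        logger.warning("skipping %s: %s", m, reason)
    reports = []
    for m in runnable:
        agg = aggregate_panel(panel, m, config)
        preds = PredictionSet(m, dict(zip(agg["claim_id"], agg["value"])))
        reports.append(
            score_predictions(
                preds,
                panel.outcomes,
                brier_variant=config.brier_variant,
                log_base=config.log_base,
            )
        )
    return sorted(reports, key=lambda r: r.avg_brier)


def score_table(reports: Sequence[ScoreReport]) -> pd.DataFrame:
    """Reports as a DataFrame, one row per method."""
    return pd.DataFrame(
        [
            {
                "method": r.source_id,
                "avg_brier": r.avg_brier,
                "auc": r.auc,
                "calibration": r.calibration,
                "informativeness": r.informativeness,
                "n_claims": r.n_claims,
            }
            for r in reports
        ]
    )
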