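"""Method registry and the panel-level aggregation dispatcher.

Twenty-one aggregation methods share one flat output schema (claim_id,
method, value, n_experts) so that scoring is method-agnostic.  Each
method declares what it needs from the panel — elicited bounds, both
rounds, specific metadata, external claim priors — and the dispatcher
skips unavailable methods with a named reason (point-estimate-only
panels, for instance, support exactly six of the 21 methods).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import McmcSettings, TriVarModelSpec, fit_bay_priors_agg, fit_bay_tri_var
from .config import RunConfig
from .panel import Panel
from .pooling import (
    BetaTransformSpec,
    ar_mean,
    beta_ar_mean,
    distrib_ar_mean,
    lo_ar_mean,
    median_pool,
)
from .weights import ALL_WEIGHTED, weighted_pool, weights_for

logger = logging.getLogger(__name__)

#: the 21 method IDs, in presentation order
METHOD_IDS = (
    "ArMean", "Median", "LOArMean", "BetaArMean", "DistribArMean",
    "IntWAgg", "IndIntWAgg", "VarIndIntWAgg", "AsymWAgg", "IndIntAsymWAgg",
    "KitchSinkWAgg", "DistLimitWAgg", "ShiftWAgg", "GranWAgg", "EngWAgg",
    "ReasonWAgg", "ReasonWAgg2", "QuizWAgg", "CompWAgg",
    "BayTriVar", "BayPRIORSAgg",
)

#: inputs each method needs beyond round-2 best estimates
REQUIREMENTS: dict[str, frozenset] = {
    "ArMean": frozenset(),
    "Median": frozenset(),
    "LOArMean": frozenset(),
    "BetaArMean": frozenset(),
    "DistribArMean": frozenset({"bounds"}),
    "IntWAgg": frozenset({"bounds"}),
    "IndIntWAgg": frozenset({"bounds"}),
    "VarIndIntWAgg": frozenset({"bounds"}),
    "AsymWAgg": frozenset({"bounds"}),
    "IndIntAsymWAgg": frozenset({"bounds"}),
    "KitchSinkWAgg": frozenset({"bounds"}),
    "DistLimitWAgg": frozenset(),
    "ShiftWAgg": frozenset({"two_rounds"}),
    "GranWAgg": frozenset(),
    "EngWAgg": frozenset({"comment_words"}),
    "ReasonWAgg": frozenset({"reason_count"}),
    "ReasonWAgg2": frozenset({"reason_codes"}),
    "QuizWAgg": frozenset({"quiz"}),
    "CompWAgg": frozenset({"comprehension"}),
    "BayTriVar": frozenset({"bounds"}),
    "BayPRIORSAgg": frozenset({"bounds", "claim_priors"}),
}

_REASONS = {
    "bounds": "panel has no elicited lower/upper bounds",
    "two_rounds": "panel does not contain both elicitation rounds",
    "comment_words": "no comment word counts in the panel metadata",
    "reason_count": "no coded reason counts in the panel metadata",
    "reason_codes": "no coded reason identifiers in the panel metadata",
    "quiz": "no quiz scores in the panel metadata",
    "comprehension": "no comprehension ratings in the panel metadata",
    "claim_priors": "no external per-claim prior probabilities supplied",
}


def _panel_features(panel: Panel, claim_priors=None) -> set:
    feats = set()
    if panel.has_bounds:
        feats.add("bounds")
    if panel.has_two_rounds:
        feats.add("two_rounds")
    cm = panel.claim_meta
    if "comment_words" in cm.columns and cm["comment_words"].notna().any():
        feats.add("comment_words")
    if "reason_count" in cm.columns and cm["reason_count"].notna().any():
        feats.add("reason_count")
    if "reason_codes" in cm.columns and cm["reason_codes"].notna().any():
        feats.add("reason_codes")
    if len(panel.quiz):
        feats.add("quiz")
    if "comprehension" in cm.columns and cm["comprehension"].notna().any():
        feats.add("comprehension")
    if claim_priors:
        feats.add("claim_priors")
    return feats


def available_methods(
    panel: Panel,
    methods: Sequence[str] | str = "all",
    config: RunConfig | None = None,
    claim_priors: Mapping[str, float] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Split requested methods into runnable ones and skipped-with-reason."""
    if methods == "all" or methods is None:
        methods = list(METHOD_IDS)
    unknown = [m for m in methods if m not in REQUIREMENTS]
    if unknown:
        raise ValueError(
            f"unknown method IDs {unknown}; valid IDs: {', '.join(METHOD_IDS)}"
        )
    feats = _panel_features(panel, claim_priors)
    runnable, skipped = [], {}
    for m in methods:
        missing = REQUIREMENTS[m] - feats
        if missing:
            skipped[m] = "; ".join(_REASONS[f] for f in sorted(missing))
        else:
            runnable.append(m)
    return runnable, skipped


def aggregate_panel(
    panel: Panel,
    method: str,
    config: RunConfig | None = None,
    claim_priors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate every claim of a panel under one method.

    Returns a DataFrame with columns ``method, claim_id, value, n_experts``.
    All methods pool the analysis-round (latest) best estimates; ShiftWAgg
    additionally consumes round-1 judgements to build its weights.
    """
    if method not in REQUIREMENTS:
        raise ValueError(
            f"unknown method ID {method!r}; valid IDs: {', '.join(METHOD_IDS)}"
        )
    config = config or RunConfig()
    runnable, skipped = available_methods(panel, [method], config, claim_priors)
    if skipped:
        raise ValueError(f"cannot run {method}: {skipped[method]}")

    work = panel.analysis_round()
    df = work.assessments
    rows = []

    if method in ("ArMean", "Median", "LOArMean", "BetaArMean", "DistribArMean"):
        spec = BetaTransformSpec(config.beta_alpha, config.beta_alpha)
        for claim, grp in df.groupby("claim_id", sort=True):
            best = grp["best"].to_numpy()
            if method == "ArMean":
                value = ar_mean(best)
            elif method == "Median":
                value = median_pool(best)
            elif method == "LOArMean":
                value = lo_ar_mean(best, eps=config.clip_eps)
            elif method == "BetaArMean":
                value = beta_ar_mean(best, spec)
            else:
                value = distrib_ar_mean(work.claim_assessments(claim))
            rows.append((method, claim, value, len(grp)))

    elif method in ALL_WEIGHTED:
        source = panel if method == "ShiftWAgg" else work
        wvs = weights_for(source, method, eps=config.eps)
        for claim in work.claims:
            res = weighted_pool(work.claim_assessments(claim), wvs[claim])
            rows.append((method, claim, res.value, res.n_experts))

    else:  # Bayesian methods
        spec = TriVarModelSpec(
            prior_sd=config.prior_sd,
            sigma_bounds=config.sigma_bounds,
            bound_coverage_z=config.bound_coverage_z,
            eps_clip=config.clip_eps,
        )
        mcmc = McmcSettings(
            chains=config.chains, warmup=config.warmup,
            draws=config.draws, seed=config.seed,
        )
        if method == "BayTriVar":
            fit = fit_bay_tri_var(panel, spec, mcmc)
        else:
            fit = fit_bay_priors_agg(panel, claim_priors, spec, mcmc)
        for claim in work.claims:
            rows.append((method, claim, fit[claim].point, work.n_assessors(claim)))

    return pd.DataFrame(rows, columns=["method", "claim_id", "value", "n_experts"])
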