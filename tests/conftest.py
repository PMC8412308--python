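import numpy as np
import pandas as pd
import pytest

from expertpool import Assessment, Panel, SimulationScenario, simulate_panel

#: the three-expert example used throughout: (L, B, U) read as 5/50/95 percentiles
WORKED_TRIPLES = [(0.60, 0.70, 0.99), (0.38, 0.58, 0.60), (0.50, 0.85, 0.90)]


@pytest.fixture
def worked_assessments():
    return [
        Assessment(f"p{i+1}", "c1", 2, lo, b, hi)
        for i, (lo, b, hi) in enumerate(WORKED_TRIPLES)
    ]


@pytest.fixture
def small_panel():
    return simulate_panel(
        SimulationScenario(n_claims=8, n_participants=6, proxy_effect=0.5, seed=7)
    )


def make_constant_proxy_panel(seed: int, n_claims: int = 5, n_participants: int = 6) -> Panel:
    """A panel in which every weighting proxy is constant across assessors.

    Best estimates still vary (each participant reports b_c or 1 - b_c),
    but interval widths, asymmetry, shift, granularity status, distance to
    the certainty limits and all metadata are identical within each claim,
    so every proxy-weighted pool must collapse to the arithmetic mean.
    """
    rng = np.random.default_rng(seed)
    claims = [f"c{k}" for k in range(n_claims)]
    pids = [f"p{k}" for k in range(n_participants)]
    b_c = rng.uniform(0.25, 0.75, n_claims)
    half = 0.1
    rows, meta_rows = [], []
    for c, claim in enumerate(claims):
        for pid in pids:
            b = b_c[c] if rng.uniform() < 0.5 else 1.0 - b_c[c]
            for rnd in (1, 2):  # identical rounds: zero shift for everyone
                rows.append((pid, claim, rnd, b - half, b, b + half))
            meta_rows.append((pid, claim, 4, 50, 3, "R01;R02;R03"))
    assessments = pd.DataFrame(
        rows, columns=["participant_id", "claim_id", "round", "lower", "best", "upper"]
    )
    claim_meta = pd.DataFrame(
        meta_rows,
        columns=["participant_id", "claim_id", "comprehension", "comment_words",
                 "reason_count", "reason_codes"],
    )
    quiz = pd.DataFrame({"participant_id": pids, "score": [10.0] * n_participants})
    outcomes = pd.DataFrame(
        {"claim_id": claims, "outcome": rng.integers(0, 2, n_claims)}
    )
    return Panel(assessments, outcomes=outcomes, quiz=quiz, claim_meta=claim_meta)


@pytest.fixture
def constant_proxy_panel():
    return make_constant_proxy_panel(seed=11)
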