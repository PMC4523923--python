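"""Parameter-sweep robustness of scored bait–prey interactions.

The scoring model leaves several analyst-chosen knobs open: the confidence
threshold tau used to call an interaction, the identification-score cutoff
m, and whether high counts are capped and totals normalized. Rather than
committing to one combination, the screen is re-scored under every
combination of a grid (the published sweep uses tau in 0.8–0.95 by 0.01,
m in {10, 20, 30, 40, 50} and both binary axes — 16 x 5 x 2 x 2 = 320
combinations) and each pair receives a *robustness fraction*: the share of
combinations in which it is called. Pairs reaching an average score above
0.8 in at least one combination are candidates; candidates with robustness
>= 0.5 are classed ``robust``, the rest ``low``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .scoring import ScoringOptions, apply_filters, score_dataset

CANDIDATE_MIN_SCORE = 0.8  # strict: "above 0.8 in at least one parameter set"
ROBUST_MIN_FRACTION = 0.5  # inclusive: "high (>=0.5)"


@dataclass(frozen=True)
class ParameterCombo:
    tau: float
    id_score_min: float
    cap_high_counts: bool
    normalize: bool


@dataclass(frozen=True)
class ParameterGrid:
    tau_values: tuple[float, ...]
    m_values: tuple[float, ...]
    cap_flags: tuple[bool, ...]
    norm_flags: tuple[bool, ...]
    combos: tuple[ParameterCombo, ...]

    def __len__(self) -> int:
        return len(self.combos)


def build_parameter_grid(
    tau_range: tuple[float, float, float] = (0.8, 0.95, 0.01),
    m_set: Iterable[float] = (10, 20, 30, 40, 50),
    include_cap_axis: bool = True,
    include_norm_axis: bool = True,
) -> ParameterGrid:
    """Enumerate the sweep grid in canonical order.

    tau values are built by integer index arithmetic (``lo + i*step``) so the
    endpoint is included exactly and no floating-point drift accumulates;
    the defaults give 16 values. Canonical combo order: tau ascending, then
    m in the given order, then cap in (off, on), then normalize in (off, on).
    """
    lo, hi, step = tau_range
    if step <= 0:
        raise ValueError("tau step must be > 0")
    if lo > hi:
        raise ValueError("tau range must have lo <= hi")
    m_values = tuple(float(m) for m in m_set)
    if not m_values:
        raise ValueError("m_set must not be empty")
    n_tau = int(round((hi - lo) / step)) + 1
    tau_values = tuple(round(lo + i * step, 10) for i in range(n_tau))
    cap_flags = (False, True) if include_cap_axis else (False,)
    norm_flags = (False, True) if include_norm_axis else (False,)
    combos = tuple(
        ParameterCombo(tau, m, cap, norm)
        for tau in tau_values
        for m in m_values
        for cap in cap_flags
        for norm in norm_flags
    )
    return ParameterGrid(tau_values, m_values, cap_flags, norm_flags, combos)


@dataclass
class SweepResult:
    """Per-combo call sets plus the score table of each option set."""

    grid: ParameterGrid
    call_sets: dict[ParameterCombo, frozenset[tuple[str, str]]]
    score_tables: dict[tuple[float, bool, bool], pd.DataFrame]


def calls_at_tau(scores: pd.DataFrame, tau: float) -> frozenset[tuple[str, str]]:
    """Pairs called at threshold tau: avg_score >= tau (inclusive)."""
    hit = scores[scores["avg_score"] >= tau]
    return frozenset(zip(hit["bait"], hit["prey"]))


def run_sweep(
    table: pd.DataFrame,
    controls: pd.DataFrame,
    grid: ParameterGrid,
    base_options: ScoringOptions | None = None,
) -> SweepResult:
    """Re-score the screen under every grid combination.

    Scoring depends only on (m, cap, normalize); each distinct option set is
    scored once and the tau axis is applied as a threshold on the resulting
    average scores, which is exactly equivalent to re-scoring per combo.
    """
    base = base_options or ScoringOptions()
    option_sets = sorted(
        {(c.id_score_min, c.cap_high_counts, c.normalize) for c in grid.combos}
    )
    score_tables: dict[tuple[float, bool, bool], pd.DataFrame] = {}
    for m, cap, norm in option_sets:
        options = ScoringOptions(
            normalize=norm,
            cap_high_counts=cap,
            id_score_min=m,
            prior_true=base.prior_true,
            pseudocount=base.pseudocount,
            cap_quantile=base.cap_quantile,
            min_enrichment=base.min_enrichment,
        )
        ft = apply_filters(table, options)
        fc = apply_filters(controls, options)
        score_tables[(m, cap, norm)] = score_dataset(ft, fc, options, prefiltered=True)
    call_sets = {
        combo: calls_at_tau(
            score_tables[(combo.id_score_min, combo.cap_high_counts, combo.normalize)],
            combo.tau,
        )
        for combo in grid.combos
    }
    return SweepResult(grid=grid, call_sets=call_sets, score_tables=score_tables)


def robustness_fraction(sweep: SweepResult) -> pd.DataFrame:
    """Per-pair robustness records from a finished sweep.

    Returns one row per pair that was scored in at least one option set,
    with columns ``bait prey calls robustness max_avg_score candidate``.
    Pairs never scored anywhere have no record.
    """
    n_combos = len(sweep.grid)
    calls: dict[tuple[str, str], int] = {}
    for pair_set in sweep.call_sets.values():
        for pair in pair_set:
            calls[pair] = calls.get(pair, 0) + 1

    max_score: dict[tuple[str, str], float] = {}
    for scores in sweep.score_tables.values():
        for bait, prey, avg in zip(scores["bait"], scores["prey"], scores["avg_score"]):
            key = (bait, prey)
            if avg > max_score.get(key, -np.inf):
                max_score[key] = float(avg)

    rows = [
        {
            "bait": bait,
            "prey": prey,
            "calls": calls.get((bait, prey), 0),
            "robustness": calls.get((bait, prey), 0) / n_combos,
            "max_avg_score": score,
            "candidate": score > CANDIDATE_MIN_SCORE,
        }
        for (bait, prey), score in sorted(max_score.items())
    ]
    return pd.DataFrame(
        rows, columns=["bait", "prey", "calls", "robustness", "max_avg_score", "candidate"]
    )


def classify_robustness(records: pd.DataFrame) -> pd.DataFrame:
    """Label candidate pairs ``robust`` (fraction >= 0.5) or ``low``.

    Non-candidate records receive an empty label; the two labels partition
    the candidates.
    """
    out = records.copy()
    out["class"] = np.where(
        out["candidate"],
        np.where(out["robustness"] >= ROBUST_MIN_FRACTION, "robust", "low"),
        "",
    )
    return out
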