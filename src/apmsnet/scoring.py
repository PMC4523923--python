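"""Two-component Poisson confidence scoring of bait–prey spectral counts.

Each bait–prey pair is assigned the probability of being a true interaction
from its replicate spectral counts, in the spirit of SAINT-style scorers:
counts of a true interaction follow a Poisson with a pair-specific foreground
rate, counts of a contaminant follow a Poisson with a prey-specific
background rate estimated from the no-bait control runs and from all other
baits' purifications. With prior probability ``pi`` of a true interaction,
the per-replicate posterior for an observed count ``x`` is

    p(true | x) = pi * Pois(x | lambda_true)
                  / (pi * Pois(x | lambda_true) + (1 - pi) * Pois(x | lambda_false))

and the pair's confidence is the arithmetic mean of its replicate posteriors
(replicates where the prey went unobserved contribute x = 0). The published
SAINT model is hierarchical-Bayes; this module fixes a concrete, documented
two-component posterior as its implementable core.

Three switchable preprocessing options form the sweep axes of the
companion robustness module: an identification-score (Mascot-like) filter,
capping of extremely high counts at an empirical quantile, and per-
purification normalization of totals to the median purification total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

#: numerical floor on the background rate, guarding preys absent everywhere
LAMBDA_FALSE_FLOOR = 0.01


@dataclass(frozen=True)
class ScoringOptions:
    """Preprocessing switches and model constants for one scoring run."""

    normalize: bool = False
    cap_high_counts: bool = False
    id_score_min: float = 0.0
    prior_true: float = 0.1
    pseudocount: float = 0.5
    cap_quantile: float = 0.95
    min_enrichment: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_true < 1.0:
            raise ValueError("prior_true must lie in (0, 1)")
        if not 0.0 < self.cap_quantile < 1.0:
            raise ValueError("cap_quantile must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_enrichment < 1:
            raise ValueError("min_enrichment must be >= 1")


@dataclass(frozen=True)
class PoissonMixtureModel:
    """The two rates and prior that define one pair's posterior."""

    lambda_false: float
    lambda_true: float
    prior_true: float


@dataclass(frozen=True)
class InteractionScore:
    bait: str
    prey: str
    replicate_posteriors: tuple[float, ...]
    avg_score: float


def _purification_keys(table: pd.DataFrame) -> list[str]:
    """Grouping columns identifying one purification in this table."""
    if "bait" in table.columns:
        return ["bait", "replicate"]
    return ["control_run"]


def _normalize(table: pd.DataFrame, round_counts: bool = True) -> pd.DataFrame:
    """Rescale each purification's counts so its total equals the median total.

    Rounding is to nearest integer, ties to even; ``round_counts=False``
    exposes the pre-rounding values (the rescaled totals are then exactly
    equal to the common median).
    """
    keys = _purification_keys(table)
    totals = table.groupby(keys)["count"].transform("sum")
    median_total = table.groupby(keys)["count"].sum().median()
    out = table.copy()
    scaled = out["count"] * (median_total / totals)
    if round_counts:
        out["count"] = np.rint(scaled).astype(int)
    else:
        out["count"] = scaled
    return out


def apply_filters(table: pd.DataFrame, options: ScoringOptions) -> pd.DataFrame:
    """Apply identification-score filtering, count capping and normalization.

    Order: (1) drop records with ``id_score < id_score_min``; (2) if
    ``cap_high_counts``, replace counts above the ``cap_quantile`` empirical
    quantile of all retained nonzero counts (linear interpolation, floored to
    an integer) by that quantile; (3) if ``normalize``, rescale each
    purification's counts to the median purification total and round.
    """
    out = table[table["id_score"] >= options.id_score_min].copy()
    if out.empty:
        if not table.empty:
            warnings.warn("all records removed by identification-score filter")
        return out.reset_index(drop=True)
    if options.cap_high_counts:
        nonzero = out.loc[out["count"] > 0, "count"].to_numpy()
        if nonzero.size:
            cap = math.floor(np.quantile(nonzero, options.cap_quantile))
            out.loc[out["count"] > cap, "count"] = cap
    if options.normalize:
        out = _normalize(out)
    return out.reset_index(drop=True)


def estimate_background_rate(
    prey: str,
    bait: str,
    table: pd.DataFrame,
    controls: pd.DataFrame,
    options: ScoringOptions,
) -> float:
    """Background Poisson rate for one prey, excluding the scored bait.

    lambda_false = (prey's total count over control runs and over all baits
    other than ``bait``, + pseudocount) / (number of those purifications +
    pseudocount), floored at :data:`LAMBDA_FALSE_FLOOR`. Tables are expected
    to be filtered already.
    """
    ctrl_sum = controls.loc[controls["prey"] == prey, "count"].sum() if len(controls) else 0
    n_ctrl = controls["control_run"].nunique() if len(controls) else 0
    others = table[table["bait"] != bait]
    other_sum = others.loc[others["prey"] == prey, "count"].sum() if len(others) else 0
    n_other = others.groupby(["bait", "replicate"]).ngroups if len(others) else 0
    lam = (ctrl_sum + other_sum + options.pseudocount) / (n_ctrl + n_other + options.pseudocount)
    return max(float(lam), LAMBDA_FALSE_FLOOR)


def replicate_posterior(
    x: np.ndarray | float,
    lambda_false: np.ndarray | float,
    lambda_true: np.ndarray | float,
    prior_true: float,
) -> np.ndarray:
    """Posterior probability of a true interaction given one replicate count.

    Evaluated in log space for numerical stability; broadcasts over inputs.
    """
    x = np.asarray(x)
    log_a = np.log(prior_true) + poisson.logpmf(x, lambda_true)
    log_b = np.log1p(-prior_true) + poisson.logpmf(x, lambda_false)
    return np.exp(log_a - np.logaddexp(log_a, log_b))


def _bait_replicates(table: pd.DataFrame, bait: str) -> list[int]:
    """Replicate indices present for this bait in the (filtered) table."""
    return sorted(table.loc[table["bait"] == bait, "replicate"].unique().tolist())


def score_pair(
    bait: str,
    prey: str,
    table: pd.DataFrame,
    controls: pd.DataFrame,
    options: ScoringOptions,
) -> InteractionScore:
    """Score one bait–prey pair (tables already filtered).

    The foreground rate is ``max(mean replicate count, min_enrichment *
    lambda_false)``; replicates of the bait where the prey is unobserved
    contribute x = 0. Raises for a pair with no nonzero count (such pairs
    are excluded upstream).
    """
    reps = _bait_replicates(table, bait)
    if not reps:
        raise ValueError(f"bait {bait!r} has no purifications in the table")
    sub = table[(table["bait"] == bait) & (table["prey"] == prey)]
    counts = np.zeros(len(reps), dtype=float)
    for _, row in sub.iterrows():
        counts[reps.index(row["replicate"])] = row["count"]
    if not np.any(counts > 0):
        raise ValueError(f"pair ({bait!r}, {prey!r}) has no nonzero filtered count")
    lam_f = estimate_background_rate(prey, bait, table, controls, options)
    lam_t = max(float(counts.mean()), options.min_enrichment * lam_f)
    posts = replicate_posterior(counts, lam_f, lam_t, options.prior_true)
    return InteractionScore(
        bait=bait,
        prey=prey,
        replicate_posteriors=tuple(float(p) for p in posts),
        avg_score=float(posts.mean()),
    )


def score_dataset(
    table: pd.DataFrame,
    controls: pd.DataFrame,
    options: ScoringOptions,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Score every bait–prey pair with at least one nonzero filtered count.

    Vectorized over preys within each bait; numerically identical to
    :func:`score_pair` applied pairwise. Returns a DataFrame with columns
    ``bait prey avg_score n_replicates``, sorted by (bait, prey).
    """
    if not prefiltered:
        table = apply_filters(table, options)
        controls = apply_filters(controls, options)
    if table.empty:
        return pd.DataFrame(columns=["bait", "prey", "avg_score", "n_replicates"])

    ctrl_sum = (
        controls.groupby("prey")["count"].sum() if len(controls) else pd.Series(dtype=float)
    )
    n_ctrl = controls["control_run"].nunique() if len(controls) else 0
    total_by_prey = table.groupby("prey")["count"].sum()
    purifs = table[["bait", "replicate"]].drop_duplicates()
    n_purifs_by_bait = purifs.groupby("bait").size()
    n_purifs_total = len(purifs)

    frames: list[pd.DataFrame] = []
    for bait, bait_tab in table.groupby("bait", sort=True):
        reps = sorted(bait_tab["replicate"].unique().tolist())
        mat = (
            bait_tab.pivot_table(
                index="prey", columns="replicate", values="count", aggfunc="sum"
            )
            .reindex(columns=reps)
            .fillna(0.0)
        )
        counts = mat.to_numpy(dtype=float)
        keep = counts.sum(axis=1) > 0
        mat = mat.loc[keep]
        counts = counts[keep]
        if counts.size == 0:
            continue
        preys = mat.index.to_numpy()

        bait_sum = bait_tab.groupby("prey")["count"].sum()
        other_sum = (
            total_by_prey.reindex(preys).fillna(0.0) - bait_sum.reindex(preys).fillna(0.0)
        ).to_numpy()
        csum = ctrl_sum.reindex(preys).fillna(0.0).to_numpy()
        n_other = n_purifs_total - int(n_purifs_by_bait.get(bait, 0))
        denom = n_ctrl + n_other + options.pseudocount
        lam_f = np.maximum(
            (csum + other_sum + options.pseudocount) / denom, LAMBDA_FALSE_FLOOR
        )
        lam_t = np.maximum(counts.mean(axis=1), options.min_enrichment * lam_f)
        posts = replicate_posterior(counts, lam_f[:, None], lam_t[:, None], options.prior_true)
        frames.append(
            pd.DataFrame(
                {
                    "bait": bait,
                    "prey": preys,
                    "avg_score": posts.mean(axis=1),
                    "n_replicates": len(reps),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["bait", "prey", "avg_score", "n_replicates"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["bait", "prey"], ignore_index=True)
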