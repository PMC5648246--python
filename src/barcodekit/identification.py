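"""Sequence-based identification simulation.

Every member of a species with two or more sequences is treated in turn as
an unknown query against the rest of the library (its own sequence removed)
and scored under three criteria:

* **BM** (Best Match) — the closest match names the query regardless of
  divergence; a tie at the closest distance spanning two or more species is
  ambiguous.
* **BCM** (Best Close Match) — as BM, but only matches within a distance
  threshold count; no match within the threshold leaves the query
  unidentified.
* **BIC** (BOLD-style criterion) — *all* matches within the threshold are
  considered: all conspecific = correct, several species = ambiguous, all
  one other species = incorrect, none = unidentified.

Singletons are never queries but remain available as matches; unlabeled
records are neither (they cannot confer a name).  "Within the threshold" is
implemented inclusively (d <= t).

Two data-driven threshold-selection rules are provided: the minimizer of the
cumulative (false positive + false negative) identification error, and the
lowest interior local minimum of a kernel density estimate over all pairwise
distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelmin
from scipy.stats import gaussian_kde

from .distances import DistanceMatrix

__all__ = [
    "OUTCOMES",
    "NoDensityMinimumError",
    "simulate_identifications",
    "threshold_cumulative_error",
    "optimal_threshold",
    "threshold_density_minimum",
    "run_identification_panel",
]

OUTCOMES = ("correct", "incorrect", "ambiguous", "no_identification")

#: relative tolerance when deciding that two match distances tie
_TIE_RTOL = 1e-9


class NoDensityMinimumError(ValueError):
    """The pooled distance density has no interior local minimum."""


def _query_setup(dm: DistanceMatrix, labels: Mapping[str, str]):
    lab = np.array([labels.get(sid, "") or "" for sid in dm.ids], dtype=object)
    counts = pd.Series(lab[lab != ""]).value_counts()
    multi = set(counts[counts >= 2].index)
    query_idx = [i for i, sp in enumerate(lab) if sp in multi]
    candidate_mask = lab != ""  # labeled records only can confer a name
    return lab, query_idx, candidate_mask


def _score_closest(tied_species: set[str], query_species: str) -> str:
    if tied_species == {query_species}:
        return "correct"
    if len(tied_species) >= 2:
        return "ambiguous"
    return "incorrect"


def simulate_identifications(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    criterion: str,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Outcome table (one row per query) for a criterion at a threshold.

    ``threshold`` must be given for BCM and BIC and is ignored for BM.
    """
    criterion = criterion.upper()
    if criterion not in ("BM", "BCM", "BIC"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion in ("BCM", "BIC") and threshold is None:
        raise ValueError(f"{criterion} requires a threshold")

    lab, query_idx, cand_mask = _query_setup(dm, labels)
    rows = []
    for i in query_idx:
        mask = cand_mask.copy()
        mask[i] = False
        dists = dm.d[i]
        valid = mask & ~np.isnan(dists)
        idx = np.flatnonzero(valid)
        dvals = dists[idx]
        if criterion == "BM":
            # BM always has a candidate (another conspecific exists)
            dmin = dvals.min()
            tied = idx[dvals <= dmin * (1 + _TIE_RTOL) + 1e-15]
            outcome = _score_closest({lab[j] for j in tied}, lab[i])
            match_ids = [dm.ids[j] for j in tied]
        else:
            within = idx[dvals <= threshold]
            if within.size == 0:
                outcome, match_ids = "no_identification", []
            elif criterion == "BCM":
                dw = dists[within]
                dmin = dw.min()
                tied = within[dw <= dmin * (1 + _TIE_RTOL) + 1e-15]
                outcome = _score_closest({lab[j] for j in tied}, lab[i])
                match_ids = [dm.ids[j] for j in tied]
            else:  # BIC
                species_within = {lab[j] for j in within}
                if species_within == {lab[i]}:
                    outcome = "correct"
                elif len(species_within) >= 2:
                    outcome = "ambiguous"
                else:
                    outcome = "incorrect"
                match_ids = [dm.ids[j] for j in within]
        rows.append(
            {
                "query_id": dm.ids[i],
                "species": lab[i],
                "criterion": criterion,
                "threshold": np.nan if threshold is None else threshold,
                "outcome": outcome,
                "match_ids": match_ids,
            }
        )
    return pd.DataFrame(
        rows, columns=["query_id", "species", "criterion", "threshold", "outcome", "match_ids"]
    )


def summarize_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per outcome category (denominator = queries)."""
    n = len(outcomes)
    rows = []
    for cat in OUTCOMES:
        k = int((outcomes["outcome"] == cat).sum())
        rows.append({"outcome": cat, "count": k, "n_queries": n, "percent": 100.0 * k / n if n else np.nan})
    return pd.DataFrame(rows)


def _query_extremes(dm: DistanceMatrix, labels: Mapping[str, str]):
    """Per query: nearest conspecific and nearest non-conspecific distances."""
    lab, query_idx, cand_mask = _query_setup(dm, labels)
    nearest_con, nearest_het = [], []
    for i in query_idx:
        dists = dm.d[i]
        con = cand_mask & (lab == lab[i]) & ~np.isnan(dists)
        con[i] = False
        het = cand_mask & (lab != lab[i]) & ~np.isnan(dists)
        nearest_con.append(dists[con].min() if con.any() else np.inf)
        nearest_het.append(dists[het].min() if het.any() else np.inf)
    return np.array(nearest_con), np.array(nearest_het)


def threshold_cumulative_error(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cumulative identification error over a threshold grid.

    At threshold t a query is a *false negative* when its nearest conspecific
    lies beyond t (it would go unidentified) and a *false positive* when at
    least one non-conspecific lies within t.  The default grid is every
    observed distinct distance plus the midpoints between consecutive values
    (the error curve is piecewise constant between observed distances).

    Returns ``(minimizers, curve)`` — all grid values attaining the minimum
    summed error, and the full curve as a DataFrame.
    """
    nearest_con, nearest_het = _query_extremes(dm, labels)
    if grid is None:
        vals = np.unique(dm.condensed())
        vals = vals[~np.isnan(vals)]
        vals = vals[vals > 0]
        mids = (vals[:-1] + vals[1:]) / 2 if vals.size > 1 else np.array([])
        grid = np.unique(np.concatenate([vals, mids]))
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")

    fn = (nearest_con[None, :] > grid[:, None]).sum(axis=1)
    fp = (nearest_het[None, :] <= grid[:, None]).sum(axis=1)
    total = fn + fp
    curve = pd.DataFrame(
        {"threshold": grid, "false_negative": fn, "false_positive": fp, "cumulative_error": total}
    )
    minimizers = grid[total == total.min()]
    return minimizers, curve


def optimal_threshold(minimizers: np.ndarray) -> float:
    """Midpoint of the minimizing band (its mean endpoint), the conventional
    single-number summary of a flat optimum."""
    return float((np.min(minimizers) + np.max(minimizers)) / 2.0)


def threshold_density_minimum(
    dm: DistanceMatrix,
    bw_method: str | float = "scott",
    grid_points: int = 512,
) -> float:
    """Lowest interior local minimum of the pooled distance density.

    A Gaussian kernel density (bandwidth by the given data-driven rule) is
    evaluated on ``grid_points`` points spanning [0, max distance]; among
    interior local minima the one with the smallest density value is
    returned.  Raises :class:`NoDensityMinimumError` when the density is
    unimodal so the caller can fall back to a configured default.
    """
    vals = dm.condensed()
    vals = vals[~np.isnan(vals)]
    if np.unique(vals).size < 2:
        raise ValueError("need at least 2 distinct distances")
    kde = gaussian_kde(vals, bw_method=bw_method)
    xs = np.linspace(0.0, float(vals.max()), grid_points)
    dens = kde(xs)
    minima = argrelmin(dens)[0]
    if minima.size == 0:
        raise NoDensityMinimumError("distance density has no interior local minimum")
    best = minima[np.argmin(dens[minima])]
    return float(xs[best])


@dataclass
class IdentificationPanel:
    """Identification summary across criteria and thresholds."""

    thresholds: dict[str, float]
    counts: pd.DataFrame  # rows = outcome, columns = (criterion, threshold name)
    percents: pd.DataFrame
    n_queries: int
    outcome_tables: dict[tuple[str, str], pd.DataFrame]


def run_identification_panel(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    thresholds: Mapping[str, float],
) -> IdentificationPanel:
    """Run BM once and BCM/BIC at each named threshold.

    ``thresholds`` maps a display name (e.g. "q95_intra", "bold_1pct",
    "cumulative_error", "density_minimum") to a distance fraction.
    """
    outcome_tables: dict[tuple[str, str], pd.DataFrame] = {}
    columns: dict[tuple[str, str], pd.Series] = {}

    bm = simulate_identifications(dm, labels, "BM")
    outcome_tables[("BM", "-")] = bm
    columns[("BM", "-")] = summarize_outcomes(bm).set_index("outcome")["count"]
    n_queries = len(bm)

    for name, t in thresholds.items():
        for crit in ("BCM", "BIC"):
            tab = simulate_identifications(dm, labels, crit, threshold=t)
            outcome_tables[(crit, name)] = tab
            columns[(crit, name)] = summarize_outcomes(tab).set_index("outcome")["count"]

    counts = pd.DataFrame(columns)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["criterion", "threshold"])
    percents = 100.0 * counts / n_queries if n_queries else counts * np.nan
    return IdentificationPanel(
        thresholds=dict(thresholds),
        counts=counts,
        percents=percents,
        n_queries=n_queries,
        outcome_tables=outcome_tables,
    )
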