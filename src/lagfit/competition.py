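"""Malthusian and relative fitness from labelled two-strain competitions.

A query strain and a fluorescently labelled reference strain are mixed,
grown through one or more carbon cycles, and counted by labelled-cell
cytometry at the start and end; absolute densities come from plating.
Fitness is Lenski-style Malthusian growth: the natural-log fold change of
each subpopulation over the episode, with relative fitness the ratio
``w_query / w_reference`` (any common duration normalisation cancels).

Label counts carry small misclassification rates (a reference event called
query and vice versa, typically < 1/5000); :func:`correct_counts` inverts
the 2x2 confusion matrix estimated from single-strain control cultures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ErrorRates",
    "FitnessResult",
    "correct_counts",
    "confusion_forward",
    "malthusian_fitness",
    "proportion_series",
    "aggregate_fitness",
]


@dataclass
class ErrorRates:
    """Label misclassification probabilities.

    ``e_qr``: probability a true *reference* event is called query;
    ``e_rq``: probability a true *query* event is called reference.
    Both must lie in [0, 0.5) and sum below 1 so the confusion matrix is
    invertible.
    """

    e_qr: float = 0.0
    e_rq: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("e_qr", self.e_qr), ("e_rq", self.e_rq)):
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5)")

    def matrix(self) -> np.ndarray:
        """Confusion matrix M with M @ (true_q, true_r) = expected observed."""
        return np.array(
            [[1.0 - self.e_rq, self.e_qr], [self.e_rq, 1.0 - self.e_qr]]
        )


@dataclass
class FitnessResult:
    """Malthusian growth of both competitors and their ratio."""

    w_query: float
    w_reference: float
    rel_fitness: float
    fitness_vs_ancestor: float | None = None


def confusion_forward(
    count_query: float, count_reference: float, rates: ErrorRates
) -> tuple[float, float]:
    """Expected observed counts given true counts (the forward model)."""
    obs = rates.matrix() @ np.array([count_query, count_reference], dtype=float)
    return float(obs[0]), float(obs[1])


def correct_counts(
    count_query: float, count_reference: float, rates: ErrorRates
) -> tuple[float, float]:
    """Invert label misclassification on an observed count pair.

    Solves ``M @ true = observed`` for the 2x2 confusion matrix ``M``;
    negative solutions (possible when an observed count is at or near zero)
    are clipped to 0 with a warning.
    """
    if rates.e_qr + rates.e_rq >= 1.0:
        raise ValueError("confusion matrix singular: e_qr + e_rq >= 1")
    obs = np.array([count_query, count_reference], dtype=float)
    true = np.linalg.solve(rates.matrix(), obs)
    if np.any(true < 0):
        warnings.warn(
            "misclassification correction produced a negative count; clipping to 0",
            stacklevel=2,
        )
        true = np.clip(true, 0.0, None)
    return float(true[0]), float(true[1])


def _subpop_sizes(row: pd.Series, rates: ErrorRates | None) -> tuple[float, float]:
    q, r = float(row["count_query"]), float(row["count_reference"])
    if rates is not None:
        q, r = correct_counts(q, r, rates)
    total_events = q + r
    if total_events <= 0:
        raise ValueError("row has zero labelled events")
    density = row.get("total_density")
    if density is not None and np.isfinite(density):
        scale = float(density)
    else:
        scale = total_events  # counts double as sizes when no plating density
    return scale * q / total_events, scale * r / total_events


def malthusian_fitness(
    initial: pd.Series,
    final: pd.Series,
    rates: ErrorRates | None = None,
    ancestor_rel_fitness: float | None = None,
) -> FitnessResult:
    """Malthusian growth and relative fitness over one competition episode.

    ``initial`` and ``final`` are count-table rows with ``count_query``,
    ``count_reference`` and optionally ``total_density`` (cells/ml from
    plating).  Each strain's subpopulation size is total density times its
    corrected label fraction; ``w = ln(size_final / size_initial)``.
    Relative fitness is ``w_query / w_reference``; dividing by the same
    statistic measured for the ancestor (``ancestor_rel_fitness``) gives
    fitness versus the ancestor.
    """
    nq0, nr0 = _subpop_sizes(initial, rates)
    nq1, nr1 = _subpop_sizes(final, rates)
    if min(nq0, nr0, nq1, nr1) <= 0:
        raise ValueError("zero subpopulation size; Malthusian fitness undefined")
    w_q = float(np.log(nq1 / nq0))
    w_r = float(np.log(nr1 / nr0))
    rel = w_q / w_r
    return FitnessResult(
        w_query=w_q,
        w_reference=w_r,
        rel_fitness=rel,
        fitness_vs_ancestor=None if ancestor_rel_fitness is None else rel / ancestor_rel_fitness,
    )


def proportion_series(
    table: pd.DataFrame, rates: ErrorRates | None = None
) -> pd.DataFrame:
    """Corrected query fraction at every observation time.

    Rows with zero total labelled events are skipped with a warning.
    Returns a DataFrame with columns ``time_h`` and ``p_query``, suitable
    for overlay against simulated proportion trajectories.
    """
    if len(table) == 0:
        raise ValueError("count table is empty")
    out_t, out_p = [], []
    for _, row in table.iterrows():
        q, r = float(row["count_query"]), float(row["count_reference"])
        if q + r <= 0:
            warnings.warn(
                f"skipping t={row.get('time_h')}: zero labelled events", stacklevel=2
            )
            continue
        if rates is not None:
            q, r = correct_counts(q, r, rates)
        out_t.append(float(row["time_h"]))
        out_p.append(q / (q + r))
    return pd.DataFrame({"time_h": out_t, "p_query": out_p})


def aggregate_fitness(results: "list[FitnessResult]") -> tuple[float, float]:
    """Mean and SD of relative fitness across biological replicates."""
    vals = np.array([r.rel_fitness for r in results], dtype=float)
    if len(vals) == 0:
        raise ValueError("no replicates")
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
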