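"""Mitotic timing and event statistics.

Cells are annotated with the times of nuclear envelope breakdown (NEBD),
metaphase-plate formation and anaphase onset (AO) on a fixed frame grid
(6 min by default), plus per-cell outcome flags (completed mitosis,
congressed, maintained congression, lagging chromosomes at anaphase). The
module computes the cumulative-frequency summary t50 — the time by which
50% of cells have completed a transition — per-replicate event fractions,
and the hypothesis tests used to compare conditions.

t50 reads the empirical cumulative step function at 0.5 without
interpolation, honouring the frame quantization; cells that never reach
the event stay in the denominator by default, matching cumulative-frequency
curves that plateau below 100% (``completers_only`` restricts to
completers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MitoticEventRecord",
    "t50",
    "cumulative_frequency",
    "event_fractions",
    "compare_groups",
    "timing_summary",
    "read_events",
]


@dataclass
class MitoticEventRecord:
    """One cell's annotated mitotic progression."""

    cell_id: str
    condition: str
    replicate_id: str
    t_NEBD: float
    t_plate: float | None = None
    t_AO: float | None = None
    completed: bool = False
    congressed: bool = False
    maintained_congression: bool = False
    lagging: bool = False

    def __post_init__(self) -> None:
        if self.t_plate is not None and self.t_plate < self.t_NEBD:
            raise ValueError("t_plate before t_NEBD")
        if self.t_AO is not None:
            if self.t_AO < self.t_NEBD:
                raise ValueError("t_AO before t_NEBD")
            if self.t_plate is not None and self.t_AO < self.t_plate:
                raise ValueError("t_AO before t_plate")

    @property
    def nebd_to_ao(self) -> float | None:
        return None if self.t_AO is None else self.t_AO - self.t_NEBD

    @property
    def nebd_to_plate(self) -> float | None:
        return None if self.t_plate is None else self.t_plate - self.t_NEBD


def t50(durations: Sequence[float], n_total: int) -> float | None:
    """Time by which 50% of cells complete the transition.

    ``durations`` are the observed completer durations; ``n_total`` is the
    full denominator (completers plus censored cells). Returns the smallest
    observed duration t with (# durations <= t) / n_total >= 0.5, or None
    if the cumulative curve never reaches 50%.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if len(durations) > n_total:
        raise ValueError("more durations than n_total")
    d = np.sort(np.asarray(durations, dtype=float))
    for k, t in enumerate(d, start=1):
        if k / n_total >= 0.5:
            return float(t)
    return None


def cumulative_frequency(
    durations: Sequence[float], n_total: int
) -> pd.DataFrame:
    """Empirical cumulative frequency table over the observed durations."""
    d = np.sort(np.asarray(durations, dtype=float))
    ts = np.unique(d)
    frac = [np.count_nonzero(d <= t) / n_total for t in ts]
    return pd.DataFrame({"t_min": ts, "cumulative_fraction": frac})


_FLAGS = ("completed", "congressed", "maintained_congression", "lagging")


def event_fractions(records: Sequence[MitoticEventRecord]) -> pd.DataFrame:
    """Per-replicate event fractions, their mean, and pooled fractions.

    Per-replicate fractions mirror dots-per-experiment plotting; the
    ``mean`` row averages replicates (unweighted) and the ``pooled`` row
    recomputes from summed counts.
    """
    if not records:
        return pd.DataFrame(
            columns=["condition", "replicate_id", "n_cells", *[f"fraction_{f}" for f in _FLAGS]]
        )
    df = pd.DataFrame(
        [
            {"condition": r.condition, "replicate_id": r.replicate_id,
             **{f: getattr(r, f) for f in _FLAGS}}
            for r in records
        ]
    )
    rows = []
    for cond, sub in df.groupby("condition", sort=True):
        reps = []
        for rep, rsub in sub.groupby("replicate_id", sort=True):
            row = {"condition": cond, "replicate_id": rep, "n_cells": len(rsub)}
            row.update({f"fraction_{f}": rsub[f].mean() for f in _FLAGS})
            reps.append(row)
        rows.extend(reps)
        rows.append(
            {"condition": cond, "replicate_id": "mean",
             "n_cells": len(sub),
             **{f"fraction_{f}": float(np.mean([r[f"fraction_{f}"] for r in reps]))
                for f in _FLAGS}}
        )
        rows.append(
            {"condition": cond, "replicate_id": "pooled", "n_cells": len(sub),
             **{f"fraction_{f}": sub[f].mean() for f in _FLAGS}}
        )
    return pd.DataFrame(rows)


def compare_groups(a, b=None, test: str = "mann_whitney"):
    """Two-group (or multi-group) hypothesis tests used across the study.

    - ``mann_whitney``: two-sided Mann-Whitney U; exact null distribution
      for n1, n2 <= 8 without ties, normal approximation with tie
      correction otherwise.
    - ``chi_square``: Pearson chi-square on a contingency table passed as
      ``a`` (no continuity correction).
    - ``paired_t``: two-sided paired t test.
    - ``anova_dunnett``: Dunnett's many-to-one comparison of the treatment
      groups in ``a`` (list of samples) against the control ``b``.

    Returns (statistic, p); arrays for Dunnett.
    """
    if test == "mann_whitney":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both samples must be non-empty")
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "chi_square":
        table = np.asarray(a, dtype=float)
        if table.ndim != 2:
            raise ValueError("chi_square expects a contingency table")
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    if test == "paired_t":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired_t needs two equal-length samples of n >= 2")
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "anova_dunnett":
        groups = [np.asarray(g, dtype=float) for g in a]
        control = np.asarray(b, dtype=float)
        if len(groups) == 0 or any(len(g) < 2 for g in groups) or len(control) < 2:
            raise ValueError("anova_dunnett needs groups and control with n >= 2")
        res = stats.dunnett(*groups, control=control)
        return np.asarray(res.statistic), np.asarray(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def timing_summary(
    records: Sequence[MitoticEventRecord],
    completers_only: bool = False,
) -> pd.DataFrame:
    """Per-condition t50 (NEBD->AO and NEBD->plate) and event fractions."""
    rows = []
    by_cond: dict[str, list[MitoticEventRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition, []).append(r)
    for cond in sorted(by_cond):
        recs = by_cond[cond]
        ao = [r.nebd_to_ao for r in recs if r.nebd_to_ao is not None]
        plate = [r.nebd_to_plate for r in recs if r.nebd_to_plate is not None]
        n_ao = len(ao) if completers_only else len(recs)
        n_plate = len(plate) if completers_only else len(recs)
        rows.append(
            {
                "condition": cond,
                "n_cells": len(recs),
                "t50_nebd_to_ao": t50(ao, n_ao) if n_ao else None,
                "t50_nebd_to_plate": t50(plate, n_plate) if n_plate else None,
                "fraction_completed": float(np.mean([r.completed for r in recs])),
                "fraction_congressed": float(np.mean([r.congressed for r in recs])),
                "fraction_lagging": float(np.mean([r.lagging for r in recs])),
            }
        )
    return pd.DataFrame(rows)


def read_events(path: str) -> list[MitoticEventRecord]:
    """Read an events CSV (cell_id,condition,replicate_id,t_NEBD,t_plate,
    t_AO,completed,congressed,maintained,lagging)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            MitoticEventRecord(
                cell_id=str(row["cell_id"]),
                condition=str(row["condition"]),
                replicate_id=str(row["replicate_id"]),
                t_NEBD=float(row["t_NEBD"]),
                t_plate=float(row["t_plate"]) if pd.notna(row.get("t_plate")) else None,
                t_AO=float(row["t_AO"]) if pd.notna(row.get("t_AO")) else None,
                completed=bool(row.get("completed", False)),
                congressed=bool(row.get("congressed", False)),
                maintained_congression=bool(row.get("maintained", row.get("maintained_congression", False))),
                lagging=bool(row.get("lagging", False)),
            )
        )
    return out
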