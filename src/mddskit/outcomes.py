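"""Cohort aggregation: per-direction counts, response rates, summaries.

Operates on a cohort table with one row per patient (see
:func:`mddskit.synthetic_data.gen_cohort` for the column contract) and
reproduces the reporting conventions of the clinical analysis:
percentages rounded to the nearest integer, means and standard
deviations rendered ``a(b)``, and follow-up rates computed over the
patients with known follow-up only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import PullDirection

__all__ = [
    "CohortSummary",
    "proportion",
    "mean_sd",
    "summarize",
    "compare_proportions",
    "records_from_csv",
    "records_to_csv",
]

RECORD_COLUMNS = [
    "patient_id",
    "trigger",
    "sex",
    "pull_directions",
    "dominant_direction",
    "oks_given",
    "treatment_minutes",
    "response",
    "likert_before",
    "likert_after",
    "followup_improved",
]


def proportion(k: int, n: int) -> int:
    """Percentage 100*k/n rounded to the nearest integer."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("count must lie in [0, n]")
    return int(round(100.0 * k / n))


def mean_sd(values) -> str:
    """Render mean and SD as ``a(b)`` with integer rounding.

    A single value has no SD and renders ``a(–)``.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    m = f"{v.mean():.0f}"
    if v.size < 2:
        return f"{m}(–)"
    return f"{m}({v.std(ddof=1):.0f})"


@dataclass(frozen=True)
class CohortSummary:
    """Aggregated cohort statistics.

    All percentages are nearest-integer; fractional rates are also kept
    for parameter-recovery checks.
    """

    n_patients: int
    direction_counts: dict = field(default_factory=dict)       # experienced
    direction_pct: dict = field(default_factory=dict)
    dominant_counts: dict = field(default_factory=dict)
    single_direction_count: int = 0
    multi_direction_count: int = 0
    response_rate_pct: dict = field(default_factory=dict)      # per dominant dir
    response_rate_frac: dict = field(default_factory=dict)
    direction_marginal_frac: dict = field(default_factory=dict)
    treatment_minutes: str = ""
    immediate_success_pct: int = 0
    immediate_success_frac: float = 0.0
    followup_n_known: int = 0
    followup_success_pct: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "direction_counts": dict(self.direction_counts),
            "direction_pct": dict(self.direction_pct),
            "dominant_counts": dict(self.dominant_counts),
            "single_direction_count": self.single_direction_count,
            "multi_direction_count": self.multi_direction_count,
            "response_rate_pct": dict(self.response_rate_pct),
            "treatment_minutes": self.treatment_minutes,
            "immediate_success_pct": self.immediate_success_pct,
            "followup_n_known": self.followup_n_known,
            "followup_success_pct": self.followup_success_pct,
        }

    def to_markdown(self) -> str:
        lines = [
            "| measure | value |",
            "| --- | --- |",
            f"| patients | {self.n_patients} |",
            f"| immediate success | {self.immediate_success_pct}% |",
            f"| treatment time (min) | {self.treatment_minutes} |",
        ]
        for d, pct in self.direction_pct.items():
            rr = self.response_rate_pct.get(d)
            rr_s = f"{rr}%" if rr is not None else "–"
            lines.append(f"| pull {d}: experienced / responders | {pct}% / {rr_s} |")
        if self.followup_success_pct is not None:
            lines.append(
                f"| sustained at follow-up (n={self.followup_n_known}) | "
                f"{self.followup_success_pct}% |"
            )
        return "\n".join(lines)


def _direction_sets(series: pd.Series) -> list[frozenset]:
    out = []
    for v in series:
        if isinstance(v, (set, frozenset)):
            out.append(frozenset(str(x) for x in v))
        else:  # "back|left" string encoding from CSV
            out.append(frozenset(s for s in str(v).split("|") if s))
    return out


def summarize(records: pd.DataFrame) -> CohortSummary:
    """Aggregate a cohort table into the standard summary.

    Per-direction *experienced* counts use the full direction sets;
    response rates are per *dominant* direction.  Patients with unknown
    follow-up (NaN) are excluded from the follow-up denominator.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    n = len(records)
    sets = _direction_sets(records["pull_directions"])

    direction_counts: dict[str, int] = {}
    for s in sets:
        for d in s:
            direction_counts[d] = direction_counts.get(d, 0) + 1
    order = [d.value for d in PullDirection]
    direction_counts = {
        d: direction_counts[d] for d in order if d in direction_counts
    }
    direction_pct = {d: proportion(k, n) for d, k in direction_counts.items()}
    marginal_frac = {d: k / n for d, k in direction_counts.items()}

    single = sum(1 for s in sets if len(s) == 1)

    dominant = records["dominant_direction"].astype(str)
    improved = records["response"].astype(str) == "improved"
    dominant_counts = {
        d: int((dominant == d).sum()) for d in order if (dominant == d).any()
    }
    response_rate_pct, response_rate_frac = {}, {}
    for d, k in dominant_counts.items():
        resp = int(improved[dominant == d].sum())
        response_rate_pct[d] = proportion(resp, k)
        response_rate_frac[d] = resp / k

    fup = records["followup_improved"]
    known = fup.notna()
    followup_pct = None
    if int(known.sum()) > 0:
        followup_pct = proportion(int(fup[known].astype(bool).sum()), int(known.sum()))

    return CohortSummary(
        n_patients=n,
        direction_counts=direction_counts,
        direction_pct=direction_pct,
        dominant_counts=dominant_counts,
        single_direction_count=single,
        multi_direction_count=n - single,
        response_rate_pct=response_rate_pct,
        response_rate_frac=response_rate_frac,
        direction_marginal_frac=marginal_frac,
        treatment_minutes=mean_sd(records["treatment_minutes"]),
        immediate_success_pct=proportion(int(improved.sum()), n),
        immediate_success_frac=float(improved.mean()),
        followup_n_known=int(known.sum()),
        followup_success_pct=followup_pct,
    )


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Chi-square test comparing two proportions (2x2 table).

    Pearson chi-square without continuity correction by default; set
    ``continuity=True`` for the Yates-corrected statistic.  Returns
    ``(statistic, p_value)``.
    """
    for k, m in ((k1, n1), (k2, n2)):
        if m <= 0 or not 0 <= k <= m:
            raise ValueError("invalid counts")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate table: an outcome column is empty")
    if k1 / n1 == k2 / n2:
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Record table I/O
# ---------------------------------------------------------------------------


def records_to_csv(records: pd.DataFrame, path) -> None:
    """Write a cohort table; direction sets become "a|b" strings."""
    out = records.copy()
    out["pull_directions"] = [
        "|".join(sorted(s)) for s in _direction_sets(out["pull_directions"])
    ]
    out.to_csv(path, index=False)


def records_from_csv(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`records_to_csv`."""
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing cohort columns: {sorted(missing)}")
    df["pull_directions"] = _direction_sets(df["pull_directions"])
    return df
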