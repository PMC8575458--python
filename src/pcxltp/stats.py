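"""Pre/post potentiation statistics for LTP experiments.

The potentiation metric is percent of control: the per-cell mean
post-induction EPSP amplitude over the per-cell mean pre-induction
amplitude, ×100, averaged across cells (mean ± SEM, n−1 denominator).
Significance within a condition uses a two-tailed paired Student's t-test
on the per-cell pre/post means; comparisons across conditions (different
cells) use Welch's two-sample t.  Cells whose resting membrane potential
drifted more than 3 mV from its initial value are excluded before
averaging.  No multiple-testing correction is applied.

``PlasticityExperiment(records).fit()`` runs the full chain and returns a
``PlasticityResults`` object with per-condition summaries, comparisons and
a text ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import ExperimentRecord
from .synth import CONDITION_ORDER

__all__ = [
    "ConditionSummary",
    "PairedTResult",
    "PlasticityExperiment",
    "PlasticityResults",
    "stability_filter",
    "percent_of_control",
    "paired_t_test",
    "compare_conditions",
    "summarize_conditions",
]

#: Maximum admissible resting-membrane-potential drift (mV) for inclusion.
DEFAULT_MAX_DRIFT_MV = 3.0


@dataclass(frozen=True)
class PairedTResult:
    """Two-tailed paired t-test outcome.

    ``degenerate`` flags the zero-variance case (all differences equal but
    nonzero), where the statistic diverges and p is reported as 0.
    """

    t: float
    p: float
    df: int
    degenerate: bool = False

    def __iter__(self):
        return iter((self.t, self.p, self.df))


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition potentiation summary."""

    condition: str
    n_cells: int
    mean_percent_of_control: float
    sem_percent: float
    t_statistic: float
    p_value: float
    per_cell_ratios: tuple[float, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_cells != len(self.per_cell_ratios):
            raise ValueError("n_cells must equal the number of per-cell ratios")


def stability_filter(
    record: ExperimentRecord, max_drift: float = DEFAULT_MAX_DRIFT_MV
) -> ExperimentRecord:
    """Apply the recording-stability rule.

    A cell is included only if its resting membrane potential never moved
    more than ``max_drift`` mV away from its initial value.  Records without
    an RMP series pass with a warning (the monitoring data is missing, not
    failing).
    """
    if len(record.rmp_series) == 0:
        warnings.warn(
            f"record {record.cell_id}: no RMP series; stability cannot be "
            "checked, record passes",
            stacklevel=2,
        )
        return replace(record, included=True)
    drift = np.max(np.abs(record.rmp_series - record.rmp_series[0]))
    return replace(record, included=bool(drift <= max_drift))


def percent_of_control(record: ExperimentRecord) -> float:
    """100 × mean(post amplitudes) / mean(pre amplitudes) for one cell."""
    if not record.included:
        raise ValueError(f"record {record.cell_id} is excluded")
    pre_mean = float(np.mean(record.pre_amplitudes))
    if pre_mean == 0:
        raise ValueError(f"record {record.cell_id}: zero mean control amplitude")
    return 100.0 * float(np.mean(record.post_amplitudes)) / pre_mean


def paired_t_test(
    pre_means: Sequence[float], post_means: Sequence[float]
) -> PairedTResult:
    """Classical two-tailed paired Student's t on per-cell differences.

    t = mean(d) / (sd(d)/√n) with d = post − pre and n−1 degrees of
    freedom.  Degenerate inputs: identical pairs give t = 0, p = 1;
    nonzero differences with zero variance give p = 0 with the
    ``degenerate`` flag set.
    """
    pre = np.asarray(pre_means, dtype=float)
    post = np.asarray(post_means, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = post - pre
    df = n - 1
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTResult(t=0.0, p=1.0, df=df)
        return PairedTResult(
            t=math.copysign(math.inf, mean_d), p=0.0, df=df, degenerate=True
        )
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTResult(t=t, p=min(p, 1.0), df=df)


def compare_conditions(
    summary_a: ConditionSummary, summary_b: ConditionSummary
) -> tuple[float, float]:
    """Welch's two-sample two-tailed t on per-cell percent-of-control values.

    Cross-condition comparisons involve different cells, so the paired test
    does not apply; unequal variances are not assumed.
    """
    a = np.asarray(summary_a.per_cell_ratios, dtype=float)
    b = np.asarray(summary_b.per_cell_ratios, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both conditions need n >= 2 cells")
    if np.array_equal(a, b):
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _condition_sort_key(condition: str):
    try:
        return (0, CONDITION_ORDER.index(condition))
    except ValueError:
        return (1, condition)


def summarize_conditions(
    records: Iterable[ExperimentRecord],
    max_drift: float = DEFAULT_MAX_DRIFT_MV,
    apply_stability: bool = True,
) -> list[ConditionSummary]:
    """Per-condition mean ± SEM of percent-of-control with a paired test.

    Applies the stability filter (unless already applied), computes per-cell
    ratios from included records, the cohort mean and SEM (sd with n−1
    denominator over √n), and a paired t-test on per-cell pre/post mean
    amplitudes.  Conditions are reported in preset order, then
    alphabetically for unknown labels.
    """
    by_condition: dict[str, list[ExperimentRecord]] = {}
    for rec in records:
        if apply_stability and len(rec.rmp_series) > 0:
            rec = stability_filter(rec, max_drift=max_drift)
        by_condition.setdefault(rec.condition, []).append(rec)
    summaries = []
    for cond in sorted(by_condition, key=_condition_sort_key):
        recs = by_condition[cond]
        included = [r for r in recs if r.included]
        n_excluded = len(recs) - len(included)
        if not included:
            continue
        ratios = np.array([percent_of_control(r) for r in included])
        n = len(ratios)
        mean = float(np.mean(ratios))
        sem = float(np.std(ratios, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        if n >= 2:
            pre_means = [float(np.mean(r.pre_amplitudes)) for r in included]
            post_means = [float(np.mean(r.post_amplitudes)) for r in included]
            tt = paired_t_test(pre_means, post_means)
            t_stat, p_val = tt.t, tt.p
        else:
            t_stat, p_val = float("nan"), float("nan")
        summaries.append(
            ConditionSummary(
                condition=cond,
                n_cells=n,
                mean_percent_of_control=mean,
                sem_percent=sem,
                t_statistic=t_stat,
                p_value=p_val,
                per_cell_ratios=tuple(float(x) for x in ratios),
                n_excluded=n_excluded,
            )
        )
    return summaries


class PlasticityExperiment:
    """Model object over a set of experiment records.

    ``fit()`` applies the stability exclusion rule and computes per-condition
    potentiation statistics, returning :class:`PlasticityResults`.
    """

    def __init__(self, records: Sequence[ExperimentRecord]):
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PlasticityExperiment":
        """Build from a long-format frame with columns
        cell_id, condition, phase ('pre'/'post'), amplitude_mV and
        optionally rmp_mV."""
        required = {"cell_id", "condition", "phase", "amplitude_mV"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        records = []
        for (cell, cond), grp in df.groupby(["cell_id", "condition"], sort=False):
            pre = grp.loc[grp["phase"] == "pre", "amplitude_mV"].to_numpy()
            post = grp.loc[grp["phase"] == "post", "amplitude_mV"].to_numpy()
            rmp = grp["rmp_mV"].to_numpy() if "rmp_mV" in grp.columns else np.array([])
            records.append(
                ExperimentRecord(
                    cell_id=str(cell), condition=str(cond),
                    pre_amplitudes=pre, post_amplitudes=post,
                    rmp_series=rmp[~pd.isna(rmp)] if len(rmp) else rmp,
                )
            )
        return cls(records)

    def fit(self, max_drift: float = DEFAULT_MAX_DRIFT_MV) -> "PlasticityResults":
        filtered = [
            stability_filter(r, max_drift=max_drift) if len(r.rmp_series) else r
            for r in self.records
        ]
        summaries = summarize_conditions(filtered, apply_stability=False)
        return PlasticityResults(summaries=summaries, records=filtered, max_drift=max_drift)


@dataclass
class PlasticityResults:
    """Fitted per-condition potentiation statistics."""

    summaries: list[ConditionSummary]
    records: list[ExperimentRecord] = field(default_factory=list)
    max_drift: float = DEFAULT_MAX_DRIFT_MV

    def __getitem__(self, condition: str) -> ConditionSummary:
        for s in self.summaries:
            if s.condition == condition:
                return s
        raise KeyError(condition)

    def compare(self, condition_a: str, condition_b: str) -> tuple[float, float]:
        """Welch t between two conditions' per-cell percent-of-control."""
        return compare_conditions(self[condition_a], self[condition_b])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": s.condition,
                    "n": s.n_cells,
                    "mean_percent": s.mean_percent_of_control,
                    "sem_percent": s.sem_percent,
                    "t": s.t_statistic,
                    "p": s.p_value,
                    "excluded_n": s.n_excluded,
                }
                for s in self.summaries
            ]
        )

    def summary(self) -> str:
        header = (
            f"{'condition':<16}{'n':>4}{'mean %':>10}{'SEM %':>8}"
            f"{'t':>9}{'p':>12}{'excl':>6}"
        )
        lines = [
            "LTP potentiation summary (percent of control EPSP)",
            "=" * len(header),
            header,
            "-" * len(header),
        ]
        for s in self.summaries:
            lines.append(
                f"{s.condition:<16}{s.n_cells:>4}"
                f"{s.mean_percent_of_control:>10.2f}{s.sem_percent:>8.2f}"
                f"{s.t_statistic:>9.3f}{s.p_value:>12.3g}{s.n_excluded:>6}"
            )
        lines += [
            "-" * len(header),
            f"stability rule: |RMP drift| <= {self.max_drift:g} mV; paired "
            "two-tailed t within condition; no multiplicity correction.",
        ]
        return "\n".join(lines)
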