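"""Editing frequencies, on-target specificity, dose–response tables and
the replicate statistics chain.

The per-sample editing readout is the percentage of structure-passing,
locus-assigned reads whose alignment contains an indel:

    pct_indels = 100 * reads_with_indel / reads_pass

On-target specificity asks "what percentage of the observed indels
happen on-target?", corrected for per-locus read depth by working on
percentages rather than raw counts:

    pct_specificity = 100 * on_pct / (on_pct + sum(off_pcts))

With the canonical two off-target loci this is the three-locus form; it
is undefined when no locus shows indels (conditions without nuclease are
excluded for exactly this reason).

Replicate comparisons run Shapiro–Wilk normality per group, Levene's
test for equal variances, one-way ANOVA, and Tukey's range post hoc
test, with the conventional 0.05 / 0.01 / 0.001 significance tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    UndefinedStatisticError,
    ValidationError,
)


@dataclass(frozen=True)
class EditingSummary:
    sample_id: str
    locus: str
    reads_pass: int
    reads_with_indel: int

    def __post_init__(self) -> None:
        if self.reads_with_indel > self.reads_pass:
            raise ValidationError("reads_with_indel exceeds reads_pass")

    @property
    def pct_indels(self) -> float:
        if self.reads_pass == 0:
            raise UndefinedStatisticError(
                f"{self.sample_id}/{self.locus}: no passing reads, "
                "indel frequency undefined"
            )
        return 100.0 * self.reads_with_indel / self.reads_pass


@dataclass(frozen=True)
class SpecificityResult:
    sample_id: str
    on_pct: float
    off_pcts: tuple[float, ...]

    @property
    def pct_specificity(self) -> float:
        return specificity(self.on_pct, list(self.off_pcts))


def editing_summary(
    calls: pd.DataFrame, sample_id: str, locus: str
) -> EditingSummary:
    """Summarise one (sample, locus) cell of a per-read call table.

    ``reads_pass`` counts structure-accepted reads assigned to this
    locus; a cell with zero passing reads raises
    :class:`UndefinedStatisticError` rather than reporting 0%.
    """
    sub = calls[
        (calls["sample_id"] == sample_id)
        & (calls["locus"] == locus)
        & calls["assigned"]
    ]
    summary = EditingSummary(
        sample_id=sample_id,
        locus=locus,
        reads_pass=int(len(sub)),
        reads_with_indel=int(sub["has_indel"].sum()),
    )
    summary.pct_indels  # raises on an empty cell
    return summary


def summarize_all(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, locus) editing summary table with a ``pct_indels``
    column, for every cell with at least one passing read."""
    assigned = calls[calls["assigned"]]
    grouped = (
        assigned.groupby(["sample_id", "locus"], as_index=False)
        .agg(
            reads_pass=("read_id", "size"),
            reads_with_indel=("has_indel", "sum"),
        )
    )
    grouped["pct_indels"] = (
        100.0 * grouped["reads_with_indel"] / grouped["reads_pass"]
    )
    return grouped


def specificity(on_pct: float, off_pcts: Sequence[float]) -> float:
    """Percentage of observed indels that are on-target.

    Raises :class:`UndefinedStatisticError` when all inputs are zero —
    specificity is meaningless with virtually no indels anywhere.
    """
    if on_pct < 0 or any(p < 0 for p in off_pcts):
        raise ValidationError("percentages must be non-negative")
    total = on_pct + sum(off_pcts)
    if total == 0:
        raise UndefinedStatisticError(
            "specificity undefined: no indels at any locus"
        )
    return 100.0 * on_pct / total


def specificity_by_condition(
    summaries: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-condition, per-replicate specificity from a summary table.

    Samples sharing (inhibitor_kind, relative_concentration, replicate)
    form one pool whose on-target percentage is divided by the summed
    percentages across its loci. Conditions with no indels anywhere are
    reported with ``pct_specificity`` NaN (they carry no information).
    """
    if "role" not in samples.columns:
        raise ConsistencyError(
            "samples table needs a 'role' column (on_target/off_target) "
            "to compute specificity"
        )
    joined = dose_response(summaries, samples)
    rows = []
    keys = ["inhibitor_kind", "relative_concentration", "replicate"]
    for cond, grp in joined.groupby(keys):
        on = grp[grp["role"] == "on_target"]["pct_indels"]
        off = grp[grp["role"] == "off_target"]["pct_indels"]
        if len(on) != 1:
            raise ConsistencyError(
                f"condition {cond}: expected exactly one on-target row, "
                f"got {len(on)}"
            )
        try:
            spec = specificity(float(on.iloc[0]), list(off))
        except UndefinedStatisticError:
            spec = float("nan")
        rows.append(
            dict(
                zip(keys, cond),
                on_pct=float(on.iloc[0]),
                pct_specificity=spec,
            )
        )
    return pd.DataFrame(rows)


def dose_response(
    summaries: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Join editing summaries to their experimental conditions into a
    tidy long table keyed by (locus, inhibitor_kind,
    relative_concentration, replicate); replicates stay as rows.

    ``samples`` needs sample_id, locus, inhibitor_kind,
    relative_concentration and replicate columns; a ``role`` column is
    carried through when present.

    Raises :class:`ConsistencyError` if any summary fails to join.
    """
    cond_cols = [
        "sample_id",
        "locus",
        "inhibitor_kind",
        "relative_concentration",
        "replicate",
    ]
    if "role" in samples.columns:
        cond_cols.append("role")
    merged = summaries.merge(
        samples[cond_cols], on=["sample_id", "locus"], how="left", validate="m:1"
    )
    unjoined = merged["inhibitor_kind"].isna()
    if unjoined.any():
        bad = merged.loc[unjoined, "sample_id"].unique().tolist()
        raise ConsistencyError(f"summaries without a condition: {bad}")
    return merged


SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_label(p: float) -> str:
    for threshold, label in SIGNIFICANCE_TIERS:
        if p < threshold:
            return label
    return "n.s."


@dataclass
class GroupComparison:
    """Result of the replicate statistics chain on one panel."""

    groups: dict[str, list[float]]
    normality_p: dict[str, float]  # Shapiro–Wilk per group
    levene_p: float
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    """Columns: group1, group2, meandiff, p_adj, significance."""


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Shapiro–Wilk, Levene, one-way ANOVA and Tukey's range test, in
    that order, over named replicate groups.

    Requires at least two groups of at least two values each. Raises
    :class:`DegenerateInputError` when every group has zero variance
    (nothing to test).
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
    if all(np.ptp(arr) == 0 for arr in arrays.values()):
        raise DegenerateInputError("zero within-group variance everywhere")

    normality = {}
    for name, arr in arrays.items():
        if np.ptp(arr) == 0 or arr.size < 3:
            normality[name] = float("nan")
        else:
            normality[name] = float(sps.shapiro(arr).pvalue)
    levene_p = float(sps.levene(*arrays.values()).pvalue)
    f, p = sps.f_oneway(*arrays.values())

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate(
        [[name] * arr.size for name, arr in arrays.items()]
    )
    tk = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )[["group1", "group2", "meandiff", "p-adj"]]
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    # recover full-precision adjusted p-values (the summary table rounds)
    tukey["p_adj"] = tk.pvalues
    tukey["significance"] = tukey["p_adj"].map(significance_label)
    return GroupComparison(
        groups={k: list(map(float, v)) for k, v in arrays.items()},
        normality_p=normality,
        levene_p=levene_p,
        anova_f=float(f),
        anova_p=float(p),
        tukey=tukey,
    )


def plot_dose_response(table: pd.DataFrame, value_col: str = "pct_indels",
                       ax=None):
    """Strip plot of replicate values against relative concentration,
    with a mean bar per concentration (one locus/panel at a time)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    concs = sorted(table["relative_concentration"].unique())
    for i, c in enumerate(concs):
        vals = table.loc[table["relative_concentration"] == c, value_col]
        ax.plot([i] * len(vals), vals, "o", alpha=0.7)
        ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="black")
    ax.set_xticks(range(len(concs)), [str(c) for c in concs])
    ax.set_xlabel("relative inhibitor concentration")
    ax.set_ylabel(value_col)
    return ax
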