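"""Exclusion cascade and outlier filtering for trial records.

The cascade runs in a fixed order: (1) participants who mispronounced
more than 45% of the CCVs over the whole experiment are dropped
entirely; (2) flagged trials (not fixated, mispronounced, more than one
production attempt) are dropped; (3) a single-pass outlier filter drops
trials with any measured variable outside the participant's own
x_bar +/- 2 s band (sample SD, bounds computed before any removal).
Intra-word frequencies are binned into low / medium / high levels.

Trial records travel as a pandas DataFrame with one row per CCV
presentation (see :mod:`ccvmotor.synthetic_data` for the column
contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "exclude_participants",
    "exclude_trials",
    "outlier_filter",
    "bin_frequency",
    "run_cascade",
    "OUTLIER_VARIABLES",
]

OUTLIER_VARIABLES = ("ffd", "fprt", "tft", "delta", "tau_norm")
FLAG_COLUMNS = ("unfixated", "mispronounced", "multi_attempt")


@dataclass
class QCReport:
    """Per-stage removal counts; conservation: n_in = n_removed + n_out."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, reason: str, n_removed: int, n_remaining: int) -> None:
        self.stages.append(
            {
                "stage": stage,
                "reason": reason,
                "n_removed": int(n_removed),
                "n_remaining": int(n_remaining),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "reason", "n_removed", "n_remaining"]
        )


def exclude_participants(
    records: pd.DataFrame,
    max_mispronounced_fraction: float = 0.45,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop subjects whose mispronounced fraction is strictly above the
    threshold, computed over their oral-block trials (silent trials
    cannot be mispronounced). Removal applies to both blocks."""
    report = report if report is not None else QCReport()
    oral = records[records["block"] == "oral"]
    frac = oral.groupby("subject")["mispronounced"].mean()
    bad = set(frac[frac > max_mispronounced_fraction].index)
    kept = records[~records["subject"].isin(bad)]
    report.add(
        "participants",
        f"mispronounced > {max_mispronounced_fraction:.0%} of CCVs",
        len(records) - len(kept),
        len(kept),
    )
    return kept.copy(), report


def exclude_trials(
    records: pd.DataFrame, report: QCReport | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Drop flagged trials; the report counts each reason separately
    (a trial is charged to the first flag that applies)."""
    report = report if report is not None else QCReport()
    remaining = records
    reasons = {
        "unfixated": "not fixated with the eyes",
        "mispronounced": "mispronounced",
        "multi_attempt": "more than one production attempt",
    }
    for col, reason in reasons.items():
        flagged = remaining[col].fillna(False).astype(bool)
        removed = int(flagged.sum())
        remaining = remaining[~flagged]
        report.add("trials", reason, removed, len(remaining))
    return remaining.copy(), report


def outlier_filter(
    records: pd.DataFrame,
    variables=OUTLIER_VARIABLES,
    n_sd: float = 2.0,
    min_values: int = 3,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Single-pass per-participant outlier removal.

    For each participant and variable, bounds x_bar +/- n_sd * s are
    computed from that participant's non-missing values (sample SD,
    ddof=1) before any removal; a trial is dropped when ANY listed
    variable falls outside its band. Zero-SD (all identical) bands
    remove nothing; participants with fewer than ``min_values`` values
    for a variable skip that variable with a warning.
    """
    report = report if report is not None else QCReport()
    drop = pd.Series(False, index=records.index)
    for var in variables:
        if var not in records.columns:
            continue
        for subject, group in records.groupby("subject"):
            vals = group[var].dropna()
            if len(vals) < min_values:
                warnings.warn(
                    f"subject {subject}: only {len(vals)} values of {var}; skipped"
                )
                continue
            mean, sd = vals.mean(), vals.std(ddof=1)
            if sd == 0:
                continue
            lo, hi = mean - n_sd * sd, mean + n_sd * sd
            out = (group[var] < lo) | (group[var] > hi)
            drop.loc[group.index[out.fillna(False)]] = True
    kept = records[~drop]
    report.add(
        "outliers",
        f"any variable outside participant mean +/- {n_sd:g} SD",
        int(drop.sum()),
        len(kept),
    )
    return kept.copy(), report


def bin_frequency(f: float) -> str:
    """Intra-word frequency level: low (f <= 10), medium (10 < f <= 50),
    high (f > 50); boundary values go to the lower bin."""
    if f < 0:
        raise ValueError("frequency must be non-negative")
    if f <= 10:
        return "low"
    if f <= 50:
        return "medium"
    return "high"


def run_cascade(
    records: pd.DataFrame,
    max_mispronounced_fraction: float = 0.45,
    outlier_variables=OUTLIER_VARIABLES,
) -> tuple[pd.DataFrame, QCReport]:
    """Full cascade: participants -> flagged trials -> outliers."""
    report = QCReport()
    report.add("input", "all recorded trials", 0, len(records))
    kept, report = exclude_participants(records, max_mispronounced_fraction, report)
    kept, report = exclude_trials(kept, report)
    kept, report = outlier_filter(kept, outlier_variables, report=report)
    return kept, report
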