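"""End-to-end orchestration: generate -> gaze -> QC -> aggregate -> infer.

``run_analysis`` drives a complete seeded synthetic experiment through
the same code paths a real dataset would take: the generator draws the
design and trial-level variables, fixation streams are realized and
pushed back through the gaze-measure pipeline (a built-in round-trip
check), screen edges are discarded, the exclusion cascade and
participant-wise outlier filter run, and the statistical battery is
applied: trial-level regressions in each block, the cross-block
SEM-weighted regressions of the silent-block ocular aggregates on the
oral-block normalized transitions, the voicing-group t-tests, and the
articulatory-effort table with its transition regression and
inter-closure-interval sweep.

Audio landmark extraction is exercised separately (it operates per
WAV record; see the CLI ``extract`` subcommand) — the trial table
already carries the timing draws the audio would reproduce.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import qc_filter, stats_inference
from .effort import (
    EffortConfig,
    analysis_ccvs,
    ccv_from_string,
    effort_sweep,
    effort_table,
)
from .gaze_metrics import (
    N_AOIS,
    OcularMeasures,
    NOT_FIXATED,
    ScreenLayout,
    discard_edges,
    screen_measures,
)
from .synthetic_data import (
    CalibrationTable,
    DesignSpec,
    build_design,
    realize_fixations,
    simulate_timing,
)
from .tract_model import default_geometry, load_geometry

__all__ = ["PipelineConfig", "ResultsBundle", "run_analysis", "replicate_deposited"]

log = logging.getLogger("ccvmotor")

VOICED_GROUP = ("bda", "bga", "dba", "dga", "gba", "gda")
DEVOICED_GROUP = ("bpa", "bta", "bca", "dpa", "dta", "dca", "gpa", "gta", "gca")
CANONICAL_SUBGROUP = ("bda", "bga", "dga")
INTERCHANGED_SUBGROUP = ("dba", "gba", "gda")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 30
    alpha: float = 0.01
    dt_closure: float = 0.200
    sweep: bool = True
    E0_value: float | None = None  # None = calibrated
    geometry_file: str | None = None  # None = packaged default
    max_mispronounced_fraction: float = 0.45

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ResultsBundle:
    config: PipelineConfig
    trials: pd.DataFrame
    retained: pd.DataFrame
    qc_report: pd.DataFrame
    table1: pd.DataFrame
    aggregates: pd.DataFrame
    cross_block: dict
    group_tests: dict
    effort: pd.DataFrame
    effort_vs_tau: "stats_inference.StatResult"
    sweep: pd.DataFrame | None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# ccvmotor seed={self.config.seed} config={self.config.hash()}\n"

        def dump(df: pd.DataFrame, name: str) -> None:
            with open(outdir / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)

        dump(self.trials, "trials.csv")
        dump(self.retained, "trials_retained.csv")
        dump(self.qc_report, "qc_report.csv")
        dump(self.table1, "table1_statistics.csv")
        dump(self.aggregates, "ccv_aggregates.csv")
        dump(self.effort, "effort_table.csv")
        dump(self.effort_vs_tau.to_frame(), "effort_vs_tau_regression.csv")
        if self.sweep is not None:
            dump(self.sweep, "effort_sweep.csv")
        cross = pd.concat(
            [r.to_frame().assign(ocular=k) for k, r in self.cross_block.items()],
            ignore_index=True,
        )
        dump(cross, "cross_block_regressions.csv")
        groups = pd.concat(
            [r.to_frame().assign(comparison=k) for k, r in self.group_tests.items()],
            ignore_index=True,
        )
        dump(groups, "group_ttests.csv")


def _row_measures(row) -> OcularMeasures:
    if row["unfixated"] or not np.isfinite(row["ffd"]):
        return NOT_FIXATED
    return OcularMeasures(
        ffd=float(row["ffd"]),
        fprt=float(row["fprt"]),
        tft=float(row["tft"]),
        fixated=True,
        first_fixation_onset=float(row["first_fix_onset"]),
    )


def _gaze_round_trip(trials: pd.DataFrame, layout: ScreenLayout) -> pd.DataFrame:
    """Realize fixation streams per screen, re-measure them through the
    gaze pipeline, and write the forward-computed values back."""
    trials = trials.sort_values(["subject", "block", "screen", "position"]).copy()
    out_cols = {c: trials[c].to_numpy().copy() for c in ("ffd", "fprt", "tft", "first_fix_onset")}
    idx_lookup = {}
    for pos, idx in enumerate(trials.index):
        idx_lookup[idx] = pos
    for (_, _, _), group in trials.groupby(["subject", "block", "screen"], sort=False):
        group = group.sort_values("position")
        measures = [_row_measures(r) for _, r in group.iterrows()]
        # a re-read only on the last fixated AOI cannot be realized as a
        # separate pass; fold it into the first pass of that AOI
        fixated = [i for i, m in enumerate(measures) if m.fixated]
        rereads = [i for i in fixated if measures[i].tft > measures[i].fprt]
        if rereads and rereads == [fixated[-1]]:
            i = rereads[0]
            m = measures[i]
            measures[i] = OcularMeasures(
                m.ffd, m.fprt, m.fprt, True, m.first_fixation_onset
            )
        start = float(group["first_fix_onset"].dropna().min()) if group["first_fix_onset"].notna().any() else 0.0
        events = realize_fixations(measures, layout, screen_start=start)
        forward = screen_measures(events, layout)
        for local, (idx, _) in enumerate(group.iterrows()):
            fm = forward[local]
            pos = idx_lookup[idx]
            if fm.fixated:
                out_cols["ffd"][pos] = fm.ffd
                out_cols["fprt"][pos] = fm.fprt
                out_cols["tft"][pos] = fm.tft
                out_cols["first_fix_onset"][pos] = fm.first_fixation_onset
            else:
                for c in out_cols:
                    out_cols[c][pos] = np.nan
    for c, v in out_cols.items():
        trials[c] = v
    # the vocal onset trails the *realized* first fixation by the trial's
    # onset delay; re-anchor it now that fixation streams exist
    trials["vocal_onset"] = trials["first_fix_onset"] + trials["delta"]
    return trials


def _analysis_subset(records: pd.DataFrame) -> pd.DataFrame:
    labels = {c.label for c in analysis_ccvs()}
    return records[records["ccv"].isin(labels)]


def _cross_block_aggregates(records: pd.DataFrame) -> list:
    """Per-CCV aggregates pairing silent-block ocular means/SEMs with
    the oral-block mean normalized transition."""
    oral = records[records["block"] == "oral"]
    silent = records[records["block"] == "silent"]
    oral_agg = stats_inference.aggregate_by_ccv(oral, ["tau_norm"])
    silent_agg = stats_inference.aggregate_by_ccv(silent, ["ffd", "fprt", "tft"])
    oral_by_ccv = {a.ccv: a for a in oral_agg}
    merged = []
    for a in silent_agg:
        o = oral_by_ccv.get(a.ccv)
        if o is None or "tau_norm" not in o.means:
            continue
        merged.append(
            stats_inference.CCVAggregate(
                ccv=a.ccv,
                n=a.n,
                means={**a.means, "tau_norm": o.means["tau_norm"]},
                sems={**a.sems, "tau_norm": o.sems["tau_norm"]},
            )
        )
    return merged


def _table1(records: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Trial-level regression / ANOVA battery per block and variable."""
    rows = []
    oral = records[records["block"] == "oral"]
    silent = records[records["block"] == "silent"]

    def add(block, variable, predictor, term):
        rows.append(
            {
                "block": block,
                "variable": variable,
                "predictor": predictor,
                "estimate": term.estimate,
                "statistic": term.statistic,
                "df": term.df,
                "p": term.p,
                "significant": term.p < alpha,
            }
        )

    for var in ("delta", "tft", "fprt", "ffd"):
        sub = oral.dropna(subset=[var, "tau_norm"])
        res = stats_inference.ols_regression(
            sub[var], {"tau_norm": sub["tau_norm"], "repetition": sub["repetition"]},
            alpha=alpha,
        )
        add("oral", var, "tau_norm", res.term("tau_norm"))
        add("oral", var, "repetition", res.term("repetition"))
        groups = [g[var].dropna() for _, g in sub.groupby("freq_level") if len(g) >= 2]
        if len(groups) >= 2:
            anova = stats_inference.one_way_anova(groups, alpha=alpha)
            add("oral", var, "freq_level", anova.term("between_groups"))
    for var in ("tft", "fprt", "ffd"):
        sub = silent.dropna(subset=[var])
        res = stats_inference.ols_regression(
            sub[var], {"repetition": sub["repetition"]}, alpha=alpha
        )
        add("silent", var, "repetition", res.term("repetition"))
        groups = [g[var].dropna() for _, g in sub.groupby("freq_level") if len(g) >= 2]
        if len(groups) >= 2:
            anova = stats_inference.one_way_anova(groups, alpha=alpha)
            add("silent", var, "freq_level", anova.term("between_groups"))
    return pd.DataFrame(rows)


def run_analysis(
    config: PipelineConfig = PipelineConfig(),
    calibration: CalibrationTable | None = None,
) -> ResultsBundle:
    """Full seeded pipeline; deterministic given (config, calibration)."""
    t_start = time.perf_counter()
    calibration = calibration if calibration is not None else CalibrationTable.default()
    layout = ScreenLayout()
    geometry = (
        load_geometry(config.geometry_file)
        if config.geometry_file
        else default_geometry()
    )

    log.info("stage=generate seed=%d subjects=%d", config.seed, config.n_subjects)
    design = build_design(DesignSpec(n_subjects=config.n_subjects), seed=config.seed)
    trials = simulate_timing(design, calibration, seed=config.seed)

    log.info("stage=gaze trials=%d", len(trials))
    trials = _gaze_round_trip(trials, layout)

    interior = trials[~trials["position"].isin([0, N_AOIS - 1])].copy()
    log.info("stage=edge_discard retained=%d", len(interior))

    retained, report = qc_filter.run_cascade(
        _analysis_subset(interior),
        max_mispronounced_fraction=config.max_mispronounced_fraction,
    )
    log.info("stage=qc retained=%d", len(retained))

    table1 = _table1(retained, config.alpha)

    aggs = _cross_block_aggregates(retained)
    cross_block = {
        var: stats_inference.wls_regression(aggs, var, "tau_norm", alpha=config.alpha)
        for var in ("ffd", "fprt", "tft")
    }
    agg_frame = pd.DataFrame(
        [
            {
                "ccv": a.ccv,
                "n": a.n,
                **{f"{k}_mean": v for k, v in a.means.items()},
                **{f"{k}_sem": v for k, v in a.sems.items()},
            }
            for a in aggs
        ]
    )

    oral = retained[retained["block"] == "oral"]
    group_tests = {
        "voiced_vs_devoiced": stats_inference.two_sample_ttest(
            oral[oral["ccv"].isin(VOICED_GROUP)]["tau_norm"].dropna(),
            oral[oral["ccv"].isin(DEVOICED_GROUP)]["tau_norm"].dropna(),
            alpha=config.alpha,
        ),
        "canonical_vs_interchanged": stats_inference.two_sample_ttest(
            oral[oral["ccv"].isin(CANONICAL_SUBGROUP)]["tau_norm"].dropna(),
            oral[oral["ccv"].isin(INTERCHANGED_SUBGROUP)]["tau_norm"].dropna(),
            alpha=config.alpha,
        ),
    }

    log.info("stage=effort dt=%.3f", config.dt_closure)
    e_config = EffortConfig(dt_closure=config.dt_closure, E0_value=config.E0_value)
    e_table = effort_table(analysis_ccvs(), geometry, e_config)
    eff_aggs = []
    e_by_ccv = e_table.set_index("ccv")["E_total"]
    for a in stats_inference.aggregate_by_ccv(oral, ["tau_norm"]):
        if a.ccv in e_by_ccv.index:
            eff_aggs.append(
                stats_inference.CCVAggregate(
                    ccv=a.ccv,
                    n=a.n,
                    means={"tau_norm": a.means["tau_norm"], "E_total": float(e_by_ccv[a.ccv])},
                    sems={"tau_norm": a.sems["tau_norm"], "E_total": 1.0},
                )
            )
    effort_vs_tau = stats_inference.wls_regression(
        eff_aggs, "tau_norm", "E_total", alpha=config.alpha
    )
    sweep = (
        effort_sweep(geometry=geometry, config=e_config) if config.sweep else None
    )
    log.info("stage=done elapsed=%.1fs", time.perf_counter() - t_start)
    return ResultsBundle(
        config=config,
        trials=trials,
        retained=retained,
        qc_report=report.to_frame(),
        table1=table1,
        aggregates=agg_frame,
        cross_block=cross_block,
        group_tests=group_tests,
        effort=e_table,
        effort_vs_tau=effort_vs_tau,
        sweep=sweep,
    )


def sweep_tau_correlation(
    sweep_table: pd.DataFrame, calibration: CalibrationTable | None = None
) -> pd.DataFrame:
    """Spearman correlation of E_total with the calibrated tau' means at
    each inter-closure interval of a sweep table."""
    calibration = calibration if calibration is not None else CalibrationTable.default()
    rows = []
    for dt, group in sweep_table.groupby("dt_closure"):
        tau = group["ccv"].map(calibration.tau_mean)
        rho, p = sps.spearmanr(group["E_total"], tau)
        rows.append({"dt_closure": float(dt), "spearman_rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)


def replicate_deposited(data_dir: str | Path) -> dict:
    """Replication entry point for the deposited experimental dataset.

    Expects ``data_dir`` to contain a trial table ``trials.csv`` in this
    package's column contract (one row per CCV presentation; see
    :mod:`ccvmotor.synthetic_data`), converted by the user from the
    published repository. Runs the exclusion cascade and the
    cross-block SEM-weighted FFD regression and returns the retained
    plosive-plosive count and the slope t statistic.
    """
    data_dir = Path(data_dir)
    table = data_dir / "trials.csv"
    if not table.exists():
        raise FileNotFoundError(
            f"deposited dataset not found: {table} — download the published "
            "data repository and convert its trial records to the ccvmotor "
            "trial-table format first"
        )
    records = pd.read_csv(table, comment="#")
    retained, report = qc_filter.run_cascade(_analysis_subset(records))
    aggs = _cross_block_aggregates(retained)
    ffd = stats_inference.wls_regression(aggs, "ffd", "tau_norm")
    return {
        "n_retained": int(len(retained)),
        "ffd_slope_t": float(ffd.term("tau_norm").statistic),
        "ffd_slope_df": float(ffd.term("tau_norm").df),
        "qc_report": report.to_frame(),
    }
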