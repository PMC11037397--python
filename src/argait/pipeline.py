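"""End-to-end orchestration: simulate -> detect -> extract -> test -> report.

``run_experiment`` simulates (or accepts) a cohort, extracts every outcome
measure, applies the exclusion policy (hurdle trials are generated but never
analyzed; missing outcomes are excluded analysis-by-analysis with listwise
deletion inside each ANOVA), and produces:

* a per-trial parameter table and a static head-pitch table;
* a TOST table, one row per content x modulation cell of the gait-speed and
  step-length tasks, mirroring the imposed/executed/t-test/TOST-lower/
  TOST-upper/equivalence column layout;
* split-plot ANOVA tables per outcome, with Bonferroni post-hoc tests on
  the factors of interest;
* a trial-accounting log recording, for every generated trial, whether it
  was analyzed and if not why.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SPEED_MODULATION_CMPS, STEP_MODULATION_CM
from .params import extract_trial, head_pitch_static
from .simulate import Cohort, CohortConfig, TrialRecord, simulate_cohort
from .stats import bonferroni_posthoc, equivalence_bound, mixed_anova, tost_paired

__all__ = ["RunConfig", "ResultsBundle", "run_experiment", "report"]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    v_thresh: float = 0.2  # stance-detector velocity threshold, m/s
    min_duration: float = 0.15  # s
    merge_gap: float = 0.05  # s
    alpha: float = 0.05
    #: walking-trial head-pitch baseline: "static" (straight-ahead pitch of
    #: the participant's static trial) or "zero"
    pitch_baseline: str = "static"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if self.pitch_baseline not in ("static", "zero"):
            raise ValueError("pitch_baseline must be 'static' or 'zero'")


@dataclass
class ResultsBundle:
    params: pd.DataFrame  # one row per walking trial
    static_pitch: pd.DataFrame  # one row per participant x content x line
    tost: pd.DataFrame  # one row per task x content x modulation
    anovas: dict[str, pd.DataFrame]
    posthocs: dict[str, pd.DataFrame]
    accounting: pd.DataFrame
    config: RunConfig


def _static_baseline_pitch(record: TrialRecord) -> float:
    h = record.headset
    mask = np.zeros(h.t.shape, bool)
    for ts, te in record.annotations.get("straight_segments", []):
        mask |= (h.t >= ts) & (h.t < te)
    if not mask.any():
        return 0.0
    return float(np.median(h.pitch[mask]))


def run_experiment(cfg: RunConfig | None = None, cohort: Cohort | None = None) -> ResultsBundle:
    """Execute the full analysis chain; deterministic given the cohort seed."""
    cfg = cfg or RunConfig()
    if cohort is None:
        cohort = simulate_cohort(cfg.cohort)

    # per-participant head-pitch baseline from the static trials' straight-
    # ahead segments (falls back to 0 when no static trial exists)
    baselines: dict[str, float] = {}
    if cfg.pitch_baseline == "static":
        for rec in cohort.records:
            if rec.spec.task == "static" and rec.spec.participant_id not in baselines:
                baselines[rec.spec.participant_id] = _static_baseline_pitch(rec)

    rows, static_rows, accounting = [], [], []
    for rec in cohort.records:
        s = rec.spec
        base = dict(
            participant_id=s.participant_id, trial_index=s.trial_index, task=s.task,
            content=s.content, modulation=s.modulation, imposed_value=s.imposed_value,
            headset=s.headset,
        )
        if s.is_calibration:
            accounting.append(dict(base, status="calibration", reason="baseline walk, not analyzed"))
            continue
        if s.task == "static":
            for dist, meas in head_pitch_static(rec):
                static_rows.append(
                    dict(
                        participant_id=s.participant_id, content=s.content, headset=s.headset,
                        distance_cm=dist, pitch=np.nan if meas.is_missing else meas.value,
                        reason=meas.reason,
                    )
                )
            accounting.append(dict(base, status="analyzed", reason=""))
            continue

        gp = extract_trial(
            rec, v_thresh=cfg.v_thresh, min_duration=cfg.min_duration,
            merge_gap=cfg.merge_gap,
            baseline_pitch=baselines.get(s.participant_id, 0.0),
        )

        def _val(m):
            return np.nan if m is None or m.is_missing else m.value

        def _reason(m):
            return None if m is None else m.reason

        rows.append(
            dict(
                base,
                analysis_included=s.analysis_included,
                gait_speed=_val(gp.gait_speed),
                step_length=_val(gp.step_length),
                crossing_init=_val(gp.crossing_init),
                crossing_halfway=_val(gp.crossing_halfway),
                head_pitch=_val(gp.head_pitch_walking),
                gait_speed_reason=_reason(gp.gait_speed),
                step_length_reason=_reason(gp.step_length),
            )
        )
        if not s.analysis_included:
            accounting.append(dict(base, status="excluded", reason="step height not analyzed"))
        elif gp.gait_speed is not None and gp.gait_speed.is_missing:
            accounting.append(dict(base, status="missing", reason=gp.gait_speed.reason))
        else:
            accounting.append(dict(base, status="analyzed", reason=""))

    params = pd.DataFrame(rows)
    static_pitch = pd.DataFrame(static_rows)
    analyzable = params[params["analysis_included"]] if len(params) else params

    tost = _tost_table(analyzable, cfg.alpha)
    anovas, posthocs = _statistics(analyzable, static_pitch, cfg)

    return ResultsBundle(
        params=params, static_pitch=static_pitch, tost=tost, anovas=anovas,
        posthocs=posthocs, accounting=pd.DataFrame(accounting), config=cfg,
    )


def _tost_table(params: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """One TOST row per content x modulation cell of the speed and
    step-length tasks, columns ordered as in the modulation-equivalence
    table layout (imposed, executed, t-test, TOST lower, TOST upper,
    verdict)."""
    out = []
    for task, outcome, magnitude in (
        ("gait_speed", "gait_speed", SPEED_MODULATION_CMPS),
        ("step_length", "step_length", STEP_MODULATION_CM),
    ):
        sub = params[params["task"] == task]
        if sub.empty:
            continue
        bound = equivalence_bound(task, magnitude)
        for (content, modulation), cell in sub.groupby(["content", "modulation"], observed=True):
            ok = cell.dropna(subset=[outcome, "imposed_value"])
            if len(ok) < 3:
                continue
            res = tost_paired(ok[outcome].to_numpy(), ok["imposed_value"].to_numpy(),
                              bound=bound, alpha=alpha)
            out.append(
                dict(
                    task=task, content=content, modulation=modulation, n=res.n,
                    imposed_mean=float(ok["imposed_value"].mean()),
                    imposed_sd=float(ok["imposed_value"].std(ddof=1)),
                    executed_mean=float(ok[outcome].mean()),
                    executed_sd=float(ok[outcome].std(ddof=1)),
                    mean_diff=res.mean_diff, t=res.t_conventional, df=res.df,
                    p=res.p_conventional, t_lower=res.t_lower, p_lower=res.p_lower,
                    t_upper=res.t_upper, p_upper=res.p_upper, bound=res.bound,
                    equivalent=res.equivalent,
                )
            )
    order = {"low": 0, "mid": 1, "high": 2}
    frame = pd.DataFrame(out)
    if not frame.empty:
        frame = frame.sort_values(
            ["task", "content", "modulation"],
            key=lambda c: c.map(order) if c.name == "modulation" else c,
        ).reset_index(drop=True)
    return frame


def _statistics(params: pd.DataFrame, static_pitch: pd.DataFrame, cfg: RunConfig):
    anovas: dict[str, pd.DataFrame] = {}
    posthocs: dict[str, pd.DataFrame] = {}

    def _try_anova(name, data, dv, within, posthoc_factors=()):
        data = data.dropna(subset=[dv])
        if data.empty:
            return
        try:
            anovas[name] = mixed_anova(data, dv=dv, subject="participant_id",
                                       between="headset", within=within)
        except ValueError as exc:
            anovas[name] = pd.DataFrame({"error": [str(exc)]})
            return
        for factor in posthoc_factors:
            posthocs[f"{name}:{factor}"] = bonferroni_posthoc(
                data, dv=dv, subject="participant_id", factor=factor, alpha=cfg.alpha
            )

    speed = params[params["task"] == "gait_speed"]
    if not speed.empty:
        _try_anova("gait_speed", speed, "gait_speed", ["content", "modulation"],
                   posthoc_factors=("modulation",))
        _try_anova("head_pitch_speed_task", speed, "head_pitch", ["content", "modulation"],
                   posthoc_factors=("content", "modulation"))

    step = params[params["task"] == "step_length"]
    if not step.empty:
        _try_anova("step_length", step, "step_length", ["content", "modulation"],
                   posthoc_factors=("modulation",))
        _try_anova("head_pitch_step_task", step, "head_pitch", ["content", "modulation"],
                   posthoc_factors=("modulation",))

    crossing = params[params["task"] == "crossing_length"]
    if not crossing.empty:
        long = crossing.melt(
            id_vars=["participant_id", "headset", "content", "modulation"],
            value_vars=["crossing_init", "crossing_halfway"],
            var_name="location", value_name="crossing_length",
        )
        long["location"] = long["location"].map(
            {"crossing_init": "initiation", "crossing_halfway": "halfway"}
        )
        _try_anova("crossing_step_length", long, "crossing_length",
                   ["content", "location", "modulation"],
                   posthoc_factors=("modulation", "location"))

    if not static_pitch.empty:
        _try_anova("head_pitch_static", static_pitch.rename(columns={"pitch": "value"}),
                   "value", ["content", "distance_cm"], posthoc_factors=("distance_cm",))

    return anovas, posthocs


def report(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Write every table as CSV plus a plain-text summary (and optional
    modulation-means plot)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(frame: pd.DataFrame, name: str):
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    _write(bundle.params, "gait_params.csv")
    if not bundle.static_pitch.empty:
        _write(bundle.static_pitch, "static_pitch.csv")
    if not bundle.tost.empty:
        _write(bundle.tost, "tost.csv")
    for name, table in bundle.anovas.items():
        _write(table, f"anova_{name}.csv")
    for name, table in bundle.posthocs.items():
        _write(table, f"posthoc_{name.replace(':', '_')}.csv")
    _write(bundle.accounting, "trial_accounting.csv")

    lines = ["Cued-walking analysis summary", "=" * 31, ""]
    counts = bundle.accounting["status"].value_counts().to_dict()
    lines.append("Trial accounting: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    dropped = bundle.accounting[bundle.accounting["status"].isin(["missing", "excluded"])]
    for row in dropped.itertuples(index=False):
        lines.append(
            f"  - {row.participant_id} trial {row.trial_index} ({row.task}/{row.content}"
            f"/{row.modulation}): {row.status} - {row.reason}"
        )
    lines.append("")
    if not bundle.tost.empty:
        lines.append("TOST equivalence (executed vs imposed):")
        for row in bundle.tost.itertuples(index=False):
            lines.append(
                f"  {row.task:12s} {row.content:12s} {row.modulation:4s} "
                f"diff={row.mean_diff:+6.2f}  t={row.t:6.2f}  "
                f"tL={row.t_lower:6.2f} tU={row.t_upper:6.2f}  "
                f"equivalent={'yes' if row.equivalent else 'no'}"
            )
        lines.append("")
    for name, table in bundle.anovas.items():
        lines.append(f"ANOVA [{name}]:")
        if "error" in table.columns:
            lines.append(f"  not computed: {table['error'].iloc[0]}")
            continue
        for row in table.itertuples(index=False):
            eps = "" if not np.isfinite(getattr(row, "epsilon_used", np.nan)) else (
                f" eps={row.epsilon_used:.3f}({row.correction})"
            )
            lines.append(
                f"  {row.effect:40s} F({row.df_num_corr:.2f},{row.df_den_corr:.2f})="
                f"{row.F:9.3f}  p={row.p:.4f}  eta_p2={row.eta_p_sq:.3f}{eps}"
            )
        lines.append("")
    for name, table in bundle.posthocs.items():
        sig = table[table["significant"]] if "significant" in table else table
        lines.append(
            f"Post-hoc [{name}]: {len(sig)}/{len(table)} pairwise comparisons "
            f"significant after Bonferroni"
        )
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)

    if bundle.config.make_plots and not bundle.params.empty:
        written.append(_plot_modulation_means(bundle, outdir))
    return written


def _plot_modulation_means(bundle: ResultsBundle, outdir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for ax, (task, dv, unit) in zip(
        axes, (("gait_speed", "gait_speed", "cm/s"), ("step_length", "step_length", "cm"))
    ):
        sub = bundle.params[bundle.params["task"] == task]
        if sub.empty:
            continue
        means = sub.groupby(["content", "modulation"], observed=True)[dv].mean().unstack("modulation")
        means = means[[c for c in ("low", "mid", "high") if c in means.columns]]
        means.T.plot(ax=ax, marker="o")
        ax.set_title(task)
        ax.set_ylabel(f"{dv} ({unit})")
    fig.tight_layout()
    path = outdir / "modulation_means.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
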