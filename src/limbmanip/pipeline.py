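"""End-to-end study orchestration.

``run_study`` reproduces the full analysis on a cohort — either a file
tree written by :func:`limbmanip.synthetic_data.generate_cohort` or an
in-memory synthetic cohort — in the fixed stage order::

    segment -> filter -> rectify -> envelope -> normalize
            -> (per-phase metrics | index resampling) -> aggregate -> compare

and writes metric, comparison and index tables (TSV) plus overview
plots of mean +- sd muscle activation with the KMI/LCI overlay and
phase boundary lines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emg_metrics, stats
from .arm_kinematics import default_dh_table
from .emg_pipeline import (
    MUSCLES,
    EMGRecording,
    Marker,
    MVCTable,
    TrialSegmentation,
    bandpass_filter,
    envelope,
    mvc_normalize,
    read_emg_csv,
    read_markers_csv,
    read_mvc_csv,
    rectify,
    resample_trials,
    segment_trials,
)
from .manipulability import IndexTimeSeries, indices_over_trajectory, resample_series
from .pose_extraction import extract_sequence, read_skeleton_csv, segment_lengths
from .synthetic_data import (
    SCRIPTS,
    GeneratorConfig,
    generate_emg,
    generate_mvc_recording,
    generate_skeleton,
    participant_profile,
)

__all__ = ["RunConfig", "StudyResult", "run_study", "validate_inputs", "ValidationReport"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a study run depends on, loadable from YAML."""

    output_dir: str = "limbmanip_out"
    input_dir: str | None = None  # cohort tree; None -> generate in memory
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    band_hz: tuple[float, float] = (20.0, 300.0)
    filter_order: int = 8
    envelope_window: int = 3500
    kmi_definition: str = "yoshikawa_sqrt"
    ssc_threshold_uv: float = 100.0
    alpha: float = 0.05
    smooth_window: int = 5
    make_plots: bool = True
    compute_envelopes: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.band_hz[0] <= 0 or self.band_hz[1] <= self.band_hz[0]:
            raise ValueError("invalid filter band")
        if self.kmi_definition not in ("yoshikawa_sqrt", "det"):
            raise ValueError(f"unknown kmi_definition {self.kmi_definition!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(generator=gen, **raw)


@dataclass
class StudyResult:
    metrics: pd.DataFrame  # aggregated metric x muscle x phase table
    per_trial: pd.DataFrame  # one row per trial/metric/muscle/phase
    comparisons: pd.DataFrame
    mean_activation: dict[str, pd.DataFrame]  # exercise -> resampled mean curves
    output_dir: Path


def _participant_sources(cfg: RunConfig):
    """Yield (participant_id, mvc_table, dh_table, per-exercise payloads).

    Payload: dict exercise -> (skeleton_seq_or_None, recording, markers,
    phase_fractions).
    """
    if cfg.input_dir is not None:
        root = Path(cfg.input_dir)
        manifest = {}
        mpath = root / "manifest.json"
        if mpath.exists():
            manifest = json.loads(mpath.read_text())
        pdirs = sorted(d for d in root.iterdir() if d.is_dir() and d.name.startswith("participant_"))
        if not pdirs:
            raise FileNotFoundError(f"no participant_* directories under {root}")
        for pdir in pdirs:
            pid = int(pdir.name.split("_")[1])
            mvc_file = pdir / "mvc.csv"
            if not mvc_file.exists():
                raise FileNotFoundError(f"missing {mvc_file}")
            mvc = read_mvc_csv(mvc_file)
            payload = {}
            for name, script in SCRIPTS.items():
                edir = pdir / name
                if not edir.exists():
                    logger.warning("%s: missing exercise %s", pdir.name, name)
                    continue
                rec = read_emg_csv(edir / "emg.csv")
                markers = read_markers_csv(edir / "markers.csv")
                skel = read_skeleton_csv(edir / "skeleton.csv")
                fractions = tuple(
                    manifest.get("exercises", {}).get(name, script.phase_fractions)
                )
                payload[name] = (skel, rec, markers, fractions)
            yield pid, mvc, None, payload
    else:
        gen = cfg.generator
        for p in range(gen.n_participants):
            profile = participant_profile(gen, p)
            table = default_dh_table(profile["lengths"])
            from .emg_pipeline import compute_mvc

            mvc_measured = {}
            for mi, m in enumerate(MUSCLES):
                rec = generate_mvc_recording(gen, m, profile["mvc_uv"], (p, 800 + mi))
                mvc_measured[m] = compute_mvc(rec, m, band=cfg.band_hz)
            payload = {}
            for ei, (name, script) in enumerate(SCRIPTS.items()):
                rec, markers, truth = generate_emg(
                    script, gen, mvc=profile["mvc_uv"], rng_key=(p, ei)
                )
                # one skeleton stream matching the jittered trial timeline
                frames = []
                t_off = 0.0
                from .synthetic_data import _camera_isometry, _rng, scale_script

                camera = _camera_isometry(_rng(gen, 901, p))
                for info in truth["trials"]:
                    scaled = scale_script(script, info["duration_scale"])
                    seq, _ = generate_skeleton(
                        scaled, gen, table=table,
                        rng=_rng(gen, p, ei, info["trial"], 700), camera=camera,
                    )
                    for f in seq.frames:
                        frames.append(replace(f, timestamp=f.timestamp + t_off))
                    t_off += scaled.duration
                from .pose_extraction import SkeletonSequence

                payload[name] = (
                    SkeletonSequence(tuple(frames)),
                    rec,
                    markers,
                    script.phase_fractions,
                )
            yield p + 1, MVCTable(mvc_measured), table, payload


def run_study(cfg: RunConfig) -> StudyResult:
    """Run the whole analysis and write its outputs.

    Deterministic given the config (and generator seed): rerunning with
    the same config reproduces byte-identical TSV files.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"run config: {cfg}"]

    per_trial_rows = []
    activation_curves: dict[str, dict[str, list[np.ndarray]]] = {}
    index_curves: dict[str, list[np.ndarray]] = {}
    lci_curves: dict[str, list[np.ndarray]] = {}

    idx_dir = out / "indices"
    idx_dir.mkdir(exist_ok=True)

    for pid, mvc, dh_table, payload in _participant_sources(cfg):
        for exercise, (skel, rec, markers, fractions) in payload.items():
            seg = segment_trials(rec, markers, phase_fractions=fractions)
            filtered = {
                m: bandpass_filter(
                    rec.channels[m], rec.rate, band=cfg.band_hz, order=cfg.filter_order
                )
                for m in MUSCLES
            }
            if cfg.compute_envelopes:
                normalized = {
                    m: mvc_normalize(
                        envelope(rectify(filtered[m]), cfg.envelope_window), mvc[m]
                    )
                    for m in MUSCLES
                }
            else:
                normalized = None

            # per-phase + whole-trial metrics on the signed filtered signal
            for w in seg.trials:
                for m in MUSCLES:
                    tbl = emg_metrics.metrics_per_phase(
                        filtered[m], seg, w, threshold=cfg.ssc_threshold_uv, muscle=m
                    )
                    tbl["participant"] = pid
                    tbl["exercise"] = exercise
                    tbl["trial"] = w.trial_id
                    per_trial_rows.append(tbl)

            # manipulability indices on the skeleton timeline
            index_series = None
            if skel is not None and len(skel) > 1:
                poses = extract_sequence(skel, smooth_window=cfg.smooth_window)
                if dh_table is None:
                    dh_table = default_dh_table(segment_lengths(skel))
                index_series = indices_over_trajectory(
                    dh_table, poses, definition=cfg.kmi_definition
                )
                pd.DataFrame(
                    {
                        "time_s": index_series.timestamps,
                        "kmi": index_series.kmi,
                        "lci": index_series.lci,
                    }
                ).to_csv(
                    idx_dir / f"participant_{pid:02d}_{exercise}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.8g",
                )

            # activity-window curves, resampled to a common length later
            for w in seg.trials:
                a0, a1 = w.activity_start, w.activity_end
                if normalized is not None:
                    for m in MUSCLES:
                        activation_curves.setdefault(exercise, {}).setdefault(
                            m, []
                        ).append(normalized[m][a0:a1])
                if index_series is not None:
                    t0, t1 = a0 / rec.rate, a1 / rec.rate
                    mask = (index_series.timestamps >= t0) & (
                        index_series.timestamps <= t1
                    )
                    if np.count_nonzero(mask) >= 2:
                        sub = IndexTimeSeries(
                            index_series.timestamps[mask],
                            index_series.kmi[mask],
                            index_series.lci[mask],
                        )
                        rs = resample_series(sub, 500)
                        index_curves.setdefault(exercise, []).append(rs.kmi)
                        lci_curves.setdefault(exercise, []).append(rs.lci)

    per_trial = pd.concat(per_trial_rows, ignore_index=True)
    metrics_tables = []
    comparisons = []
    for exercise, sub in per_trial.groupby("exercise"):
        agg = emg_metrics.aggregate(sub)
        agg.insert(0, "exercise", exercise)
        metrics_tables.append(agg)
        means = emg_metrics.participant_means(sub)
        for (metric, phase), cell in means.groupby(["metric", "phase"]):
            samples = {
                m: g["value"].to_numpy() for m, g in cell.groupby("muscle")
            }
            if len(samples) < 2:
                continue
            res = stats.compare_muscles(
                samples, alpha=cfg.alpha, metric=metric, phase=phase
            )
            df = stats.comparisons_frame(res)
            df.insert(0, "exercise", exercise)
            comparisons.append(df)
    metrics = pd.concat(metrics_tables, ignore_index=True)
    comparisons = pd.concat(comparisons, ignore_index=True)

    emg_metrics.write_metrics_tsv(metrics, out / "metrics.tsv")
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format="%.6g")

    mean_activation = {}
    for exercise in sorted(set(per_trial["exercise"])):
        cols = {}
        if exercise in activation_curves:
            for m in MUSCLES:
                curves, _ = resample_trials(activation_curves[exercise][m], 500)
                arr = np.vstack(curves)
                cols[f"{m}_mean"] = arr.mean(axis=0)
                cols[f"{m}_sd"] = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1])
        if exercise in index_curves:
            karr = np.vstack(index_curves[exercise])
            carr = np.vstack(lci_curves[exercise])
            cols["kmi_mean"] = karr.mean(axis=0)
            cols["kmi_sd"] = karr.std(axis=0, ddof=1) if len(karr) > 1 else np.zeros(karr.shape[1])
            cols["lci_mean"] = carr.mean(axis=0)
            cols["lci_sd"] = carr.std(axis=0, ddof=1) if len(carr) > 1 else np.zeros(carr.shape[1])
        if cols:
            df = pd.DataFrame(cols)
            df.insert(0, "fraction", np.linspace(0, 1, len(df)))
            mean_activation[exercise] = df
            df.to_csv(
                out / f"mean_activation_{exercise}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            if cfg.make_plots:
                _overview_plot(
                    df,
                    SCRIPTS[exercise].phase_fractions if exercise in SCRIPTS else (),
                    out / f"overview_{exercise}.png",
                    exercise,
                )

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return StudyResult(metrics, per_trial, comparisons, mean_activation, out)


def _overview_plot(df: pd.DataFrame, fractions, path, title) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
    x = df["fraction"]
    for m in MUSCLES:
        if f"{m}_mean" in df:
            mu, sd = df[f"{m}_mean"], df[f"{m}_sd"]
            ax1.plot(x, mu, label=m.upper())
            ax1.fill_between(x, mu - sd, mu + sd, alpha=0.15)
    ax1.set_ylabel("activation (fraction of MVC)")
    ax1.legend(ncol=4, fontsize=8)
    if "kmi_mean" in df:
        ax2.plot(x, df["kmi_mean"], color="tab:red", label="KMI")
        ax2.fill_between(
            x,
            df["kmi_mean"] - df["kmi_sd"],
            df["kmi_mean"] + df["kmi_sd"],
            color="tab:red",
            alpha=0.15,
        )
        ax2b = ax2.twinx()
        ax2b.plot(x, df["lci_mean"], color="tab:purple", label="LCI")
        ax2b.set_ylabel("LCI")
    ax2.set_ylabel("KMI")
    ax2.set_xlabel("normalized trial time")
    for ax in (ax1, ax2):
        for f in fractions:
            ax.axvline(f, color="tab:blue", lw=0.8, alpha=0.7)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def synthetic_cohort_summary(
    gen: GeneratorConfig, resample_points: int = 400
) -> dict:
    """Qualitative study summary on an in-memory synthetic cohort.

    Generates the full cohort (``gen.n_participants`` x 2 exercises x
    ``gen.n_trials``) and reduces it to the quantities the study's
    qualitative findings rest on, per exercise:

    * ``kmi_mean`` / ``lci_mean``: cohort-mean manipulability index
      series over the activity window (each trial's skeleton-derived
      series resampled to ``resample_points``),
    * ``phase_fractions``: phase boundaries on that normalized axis,
    * ``top_hits`` / ``top_total``: in how many trial-phases the muscle
      designed to be most active also had the highest band-passed RMS.
    """
    from .emg_metrics import rms as _rms
    from .synthetic_data import _camera_isometry, _rng, scale_script

    out: dict = {}
    acc: dict = {}
    for p in range(gen.n_participants):
        profile = participant_profile(gen, p)
        table = default_dh_table(profile["lengths"])
        camera = _camera_isometry(_rng(gen, 901, p))
        for ei, (name, script) in enumerate(SCRIPTS.items()):
            slot = acc.setdefault(
                name, {"kmi": [], "lci": [], "hits": 0, "total": 0}
            )
            rec, markers, truth = generate_emg(
                script, gen, mvc=profile["mvc_uv"], rng_key=(p, ei)
            )
            seg = segment_trials(rec, markers, script.phase_fractions)
            filtered = {
                m: bandpass_filter(rec.channels[m], rec.rate) for m in MUSCLES
            }
            for ti, w in enumerate(seg.trials):
                for pi, (s, e) in enumerate(seg.phase_windows(w)):
                    designed = script.designed_top_muscle(pi, profile["mvc_uv"])
                    top = max(MUSCLES, key=lambda m: _rms(filtered[m][s:e]))
                    slot["total"] += 1
                    slot["hits"] += top == designed
                scaled = scale_script(script, truth["trials"][ti]["duration_scale"])
                seq, _ = generate_skeleton(
                    scaled, gen, table=table,
                    rng=_rng(gen, p, ei, ti, 700), camera=camera,
                )
                poses = extract_sequence(seq)
                idx = indices_over_trajectory(table, poses)
                t0 = scaled.rest_before
                t1 = t0 + scaled.activity_duration
                mask = (idx.timestamps >= t0) & (idx.timestamps <= t1)
                sub = IndexTimeSeries(
                    idx.timestamps[mask], idx.kmi[mask], idx.lci[mask]
                )
                rs = resample_series(sub, resample_points)
                slot["kmi"].append(rs.kmi)
                slot["lci"].append(rs.lci)
    for name, slot in acc.items():
        out[name] = {
            "kmi_mean": np.vstack(slot["kmi"]).mean(axis=0),
            "lci_mean": np.vstack(slot["lci"]).mean(axis=0),
            "phase_fractions": SCRIPTS[name].phase_fractions,
            "top_hits": slot["hits"],
            "top_total": slot["total"],
        }
    return out


# ---------------------------------------------------------------------------
# input validation


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate_inputs(tree) -> ValidationReport:
    """Schema/units/rate checks over a cohort file tree (report only)."""
    report = ValidationReport()
    root = Path(tree)
    if not root.exists():
        report.errors.append(f"{root}: does not exist")
        return report
    pdirs = sorted(
        d for d in root.iterdir() if d.is_dir() and d.name.startswith("participant_")
    )
    if not pdirs:
        report.errors.append(f"{root}: no participant_* directories")
    for pdir in pdirs:
        mvc_file = pdir / "mvc.csv"
        if not mvc_file.exists():
            report.errors.append(f"{mvc_file}: missing")
        else:
            try:
                read_mvc_csv(mvc_file)
            except (ValueError, KeyError) as e:
                report.errors.append(str(e))
        for name in SCRIPTS:
            edir = pdir / name
            if not edir.exists():
                report.warnings.append(f"{edir}: missing exercise directory")
                continue
            n_samples = None
            try:
                rec = read_emg_csv(edir / "emg.csv")
                n_samples = rec.n_samples
                if not (0.95 <= rec.rate / 1500.0 <= 1.05):
                    report.warnings.append(
                        f"{edir / 'emg.csv'}: rate {rec.rate:.0f} Hz differs from nominal 1500"
                    )
            except FileNotFoundError:
                report.errors.append(f"{edir / 'emg.csv'}: missing")
            except ValueError as e:
                report.errors.append(str(e))
            try:
                markers = read_markers_csv(edir / "markers.csv")
                kinds = {"trigger_start", "trigger_end", "activity_start", "activity_end"}
                bad = [m for m in markers if m.kind not in kinds]
                if bad:
                    report.errors.append(
                        f"{edir / 'markers.csv'}: unknown marker kinds {sorted({m.kind for m in bad})}"
                    )
                if n_samples is not None and any(
                    not (0 <= m.sample_index <= n_samples) for m in markers
                ):
                    report.errors.append(
                        f"{edir / 'markers.csv'}: marker outside recording"
                    )
            except FileNotFoundError:
                report.errors.append(f"{edir / 'markers.csv'}: missing")
            except ValueError as e:
                report.errors.append(str(e))
            try:
                skel = read_skeleton_csv(edir / "skeleton.csv")
                t = skel.timestamps
                if len(t) > 1:
                    dt = np.diff(t)
                    if not np.all(dt > 0):
                        report.errors.append(
                            f"{edir / 'skeleton.csv'}: non-monotone timestamps"
                        )
                    else:
                        rate = 1.0 / np.median(dt)
                        if not (0.8 <= rate / 30.0 <= 1.2):
                            report.warnings.append(
                                f"{edir / 'skeleton.csv'}: rate {rate:.1f} Hz differs from nominal 30"
                            )
            except FileNotFoundError:
                report.errors.append(f"{edir / 'skeleton.csv'}: missing")
            except ValueError as e:
                report.errors.append(str(e))
    return report
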