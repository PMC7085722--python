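"""End-to-end driver: simulate → preprocess → calibrate → detect → report.

Every artifact is reproducible from (config, seed).  Calibration uses the
placement each movement loads most (bottom vertical for flexion, top for
extension and pelvic tilt, the contralateral diagonal for lateral flexion
and rotation) plus the two-predictor "both" variant on the same rows;
detection reports per-repetition onsets, the flexion response-time
difference and rule-based movement labels scored against ground truth.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path

import numpy as np

from .calibration import calibrate_movement
from .core import (
    CollinearityError,
    DegenerateFitError,
    Movement,
    Placement,
    PipelineError,
    TimeSeries,
)
from .detection import (
    DetectionThresholds,
    OnsetEvent,
    classify_movement,
    detect_onsets,
    response_time_difference,
)
from .io import (
    PipelineConfig,
    write_aligned_csv,
    write_json,
    write_session,
)
from .preprocessing import AlignedPair, preprocess_session
from .synthetic import (
    RepetitionTruth,
    SyntheticSession,
    default_coupling,
    default_profiles,
    default_session_sensor,
    generate_session,
    SessionScript,
)

logger = logging.getLogger(__name__)

__all__ = ["PREDICTOR_MAP", "BOTH_MAP", "run_pipeline", "detect_session"]

#: Primary calibration predictor per movement (the placement it loads most).
PREDICTOR_MAP: dict[Movement, str] = {
    Movement.FLEXION: Placement.BOTTOM_VERTICAL.value,
    Movement.EXTENSION: Placement.TOP_VERTICAL.value,
    Movement.ANTERIOR_PELVIC_TILT: Placement.TOP_VERTICAL.value,
    Movement.POSTERIOR_PELVIC_TILT: Placement.TOP_VERTICAL.value,
    Movement.LEFT_LATERAL_FLEXION: Placement.RIGHT_DIAGONAL.value,
    Movement.RIGHT_LATERAL_FLEXION: Placement.LEFT_DIAGONAL.value,
    Movement.LEFT_ROTATION: Placement.RIGHT_DIAGONAL.value,
    Movement.RIGHT_ROTATION: Placement.LEFT_DIAGONAL.value,
}

#: Channel pair used for the two-predictor ("both") fit per movement.
BOTH_MAP: dict[Movement, tuple[str, str]] = {
    m: (
        (Placement.TOP_VERTICAL.value, Placement.BOTTOM_VERTICAL.value)
        if PREDICTOR_MAP[m] in (Placement.TOP_VERTICAL.value, Placement.BOTTOM_VERTICAL.value)
        else (Placement.LEFT_DIAGONAL.value, Placement.RIGHT_DIAGONAL.value)
    )
    for m in Movement
}


def _rows_for_movement(
    aligned: AlignedPair, truth: list[RepetitionTruth], movement: Movement
) -> np.ndarray:
    reps = [r for r in truth if r.movement == movement]
    t_ms = aligned.seconds.astype(float) * 1000.0
    mask = np.zeros(len(aligned), dtype=bool)
    for r in reps:
        mask |= (t_ms >= r.start_ms) & (t_ms < r.end_ms)
    return mask


def _windowed_onsets(
    seconds_ms: np.ndarray,
    values: np.ndarray,
    channel: str,
    truth: list[RepetitionTruth],
    threshold: float,
    use_skin_onset: bool,
    compensate_drift: bool,
) -> list[OnsetEvent]:
    """First threshold crossing inside each repetition window.

    With drift compensation the rest level is re-estimated per repetition
    from the rest seconds preceding the true onset (up to 1 s before it,
    to keep the pre-stretch out of the estimate); otherwise the session
    baseline (rest level 0 on change/angle series) is used.
    """
    events: list[OnsetEvent] = []
    for r in sorted(truth, key=lambda r: r.rep_id):
        onset_ref = r.skin_onset_ms if use_skin_onset else r.angle_onset_ms
        window = (seconds_ms >= r.start_ms) & (seconds_ms < r.end_ms)
        rest = 0.0
        if compensate_drift:
            rest_mask = (seconds_ms >= r.start_ms) & (seconds_ms < onset_ref - 1000.0)
            if np.any(rest_mask):
                rest = float(values[rest_mask].mean())
        idx = np.flatnonzero(window & (np.abs(values - rest) > threshold))
        if len(idx):
            i = idx[0]
            events.append(
                OnsetEvent(
                    channel=channel,
                    onset_time_s=float(seconds_ms[i] / 1000.0),
                    direction=int(np.sign(values[i] - rest)),
                    rep_id=r.rep_id,
                )
            )
    return events


def detect_session(
    aligned: AlignedPair,
    truth: list[RepetitionTruth],
    thresholds: DetectionThresholds | None = None,
    refractory_s: float = 3.0,
    compensate_drift: bool = True,
) -> dict:
    """Detection stage: onsets, response-time differences, movement labels.

    Onsets are located per repetition window with the rest level
    re-estimated before each repetition (drift compensation), so slow
    adhesive-slip drift does not hold a channel permanently outside the
    threshold band over a long multi-movement session.
    """
    thresholds = thresholds or DetectionThresholds()
    seconds_ms = aligned.seconds.astype(float) * 1000.0
    angle_onsets = _windowed_onsets(
        seconds_ms, aligned.angle_values, "angle", truth, thresholds.angle_deg,
        use_skin_onset=False, compensate_drift=compensate_drift,
    )
    channel_onsets: dict[str, list[OnsetEvent]] = {
        name: _windowed_onsets(
            seconds_ms, values, name, truth, thresholds.resistance_ohm,
            use_skin_onset=True, compensate_drift=compensate_drift,
        )
        for name, values in aligned.eskin_values.items()
    }

    # response-time difference per movement on its primary channel,
    # paired repetition by repetition
    response: dict[str, float | None] = {}
    for movement in sorted({r.movement for r in truth}, key=lambda m: m.value):
        channel = PREDICTOR_MAP[movement]
        rep_ids = {r.rep_id for r in truth if r.movement == movement}
        a = [ev for ev in angle_onsets if ev.rep_id in rep_ids]
        e = [ev for ev in channel_onsets.get(channel, []) if ev.rep_id in rep_ids]
        common = {ev.rep_id for ev in a} & {ev.rep_id for ev in e}
        a = [ev for ev in a if ev.rep_id in common]
        e = [ev for ev in e if ev.rep_id in common]
        try:
            response[movement.value] = response_time_difference(e, a)
        except PipelineError as exc:
            logger.warning("response-time pairing failed for %s: %s", movement.value, exc)
            response[movement.value] = None

    # rule-based label per repetition window (drift-referenced traces)
    labels = []
    t_ms = seconds_ms
    for r in sorted(truth, key=lambda r: r.rep_id):
        mask = (t_ms >= r.start_ms) & (t_ms < r.end_ms)
        rest_mask = (t_ms >= r.start_ms) & (t_ms < r.skin_onset_ms - 1000.0)
        channels = {}
        for name, values in aligned.eskin_values.items():
            if name not in {p.value for p in Placement}:
                continue
            rest = float(values[rest_mask].mean()) if (
                compensate_drift and np.any(rest_mask)
            ) else 0.0
            channels[Placement(name)] = values[mask] - rest
        label = classify_movement(channels, resistance_threshold=thresholds.resistance_ohm)
        labels.append(
            {
                "rep_id": r.rep_id,
                "truth": r.movement.value,
                "label": label.label,
                "confidence": label.confidence,
                "correct": label.label == r.movement.value,
            }
        )
    accuracy = float(np.mean([l["correct"] for l in labels])) if labels else None
    return {
        "angle_onsets": angle_onsets,
        "channel_onsets": channel_onsets,
        "response_time_s": response,
        "labels": labels,
        "label_accuracy": accuracy,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write artifacts under ``config.out_dir``.

    Returns the report dictionary that is also written to ``report.json``.
    Any stage error aborts with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("eskin_lpm")
    root.addHandler(handler)
    stage = "simulate"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        profiles = default_profiles()
        script = SessionScript(
            profiles=[profiles[m] for m in config.movements],
            reps_per_set=config.reps_per_set,
            n_sets=config.n_sets,
        )
        session = generate_session(
            script,
            default_coupling(),
            config.sensor or default_session_sensor(),
            adc=config.adc,
            eskin_rate_hz=config.eskin_rate_hz,
            angle_rate_range=config.angle_rate_range,
            angle_rate_hz=config.angle_rate_hz,
            noise_sd_adu=config.noise_sd_adu,
            angle_noise_sd_deg=config.angle_noise_sd_deg,
            onset_lead_s=config.onset_lead_s,
            rest_resistance=config.rest_resistance,
            quantize=config.quantize,
            seed=config.seed,
        )
        write_session(session, out)
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        aligned = preprocess_session(
            session.eskin_streams,
            session.angle_stream,
            kalman=config.kalman,
            smooth=config.smooth,
            baseline_window_s=config.baseline_window_s,
            adc=config.adc,
        )
        write_aligned_csv(out / "aligned.csv", aligned)
        timings[stage] = time.perf_counter() - t0

        stage = "calibrate"
        t0 = time.perf_counter()
        calibration: dict[str, dict] = {}
        for movement in config.movements:
            entry: dict[str, dict] = {}
            primary = PREDICTOR_MAP[movement]
            variants = {primary: (primary,), "both": BOTH_MAP[movement]}
            for name, predictors in variants.items():
                try:
                    model, stats, report = calibrate_movement(
                        aligned,
                        session.truth,
                        movement,
                        predictors,
                        n_train=config.n_train,
                        n_test=config.n_test,
                    )
                except (CollinearityError, DegenerateFitError) as exc:
                    # e.g. idealised noiseless channels are exactly
                    # proportional; record the degenerate variant, keep going
                    logger.warning("%s/%s fit degenerate: %s", movement.value, name, exc)
                    entry[name] = {"error": str(exc)}
                    continue
                entry[name] = {
                    "predictors": list(model.predictors),
                    "coef": list(model.coef),
                    "intercept": model.intercept,
                    "r": stats.r,
                    "r2": stats.r2,
                    "adj_r2": stats.adj_r2,
                    "p_value": stats.p_value,
                    "n": stats.n,
                    "mae_deg": report.mae,
                    "n_test": report.n_test,
                }
            calibration[movement.value] = entry
        write_json(out / "models.json", calibration)
        timings[stage] = time.perf_counter() - t0

        stage = "detect"
        t0 = time.perf_counter()
        detection = detect_session(
            aligned, session.truth, config.thresholds, config.refractory_s
        )
        events_rows = []
        for name, events in detection["channel_onsets"].items():
            for ev in events:
                events_rows.append(
                    {"channel": name, "onset_s": ev.onset_time_s,
                     "direction": ev.direction, "rep_id": ev.rep_id}
                )
        for ev in detection["angle_onsets"]:
            events_rows.append(
                {"channel": "angle", "onset_s": ev.onset_time_s,
                 "direction": ev.direction, "rep_id": ev.rep_id}
            )
        import pandas as pd

        pd.DataFrame(events_rows).to_csv(out / "events.csv", index=False)
        pd.DataFrame(detection["labels"]).to_csv(out / "labels.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        for name, dt in timings.items():
            logger.info("stage %s took %.3fs", name, dt)
        # timings go to the run log only, so report.json is byte-identical
        # across runs with the same (config, seed)
        report = {
            "seed": config.seed,
            "angle_rate_hz": session.angle_rate_hz,
            "n_aligned_seconds": int(len(aligned)),
            "n_repetitions": len(session.truth),
            "stream_samples": {
                p.value: int(len(s)) for p, s in session.eskin_streams.items()
            }
            | {"angle": int(len(session.angle_stream))},
            "calibration": calibration,
            "response_time_s": detection["response_time_s"],
            "label_accuracy": detection["label_accuracy"],
        }
        write_json(out / "report.json", report)
        return report
    except PipelineError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
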