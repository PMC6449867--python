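"""End-to-end composition: raw night -> feature matrix -> staged hypnogram."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

from .config import RunConfig
from .io_core import (
    AudioRecording,
    ImuRecording,
    align_to_epochs,
    read_audio,
    read_imu,
    resample_audio,
    write_hypnogram,
)
from .cardiac import cardiac_feature_block, extract_beats
from .movement import extract_movement, movement_feature_block
from .respiratory import extract_breaths, respiratory_feature_block
from .staging import EpochFeatureMatrix, assemble_features, load_model, predict_stages
from .validation import sleep_summary

log = logging.getLogger(__name__)

__all__ = ["extract_night_features", "run_pipeline"]


def extract_night_features(
    audio: AudioRecording,
    imu: ImuRecording,
    cfg: RunConfig | None = None,
    subject_id: str = "",
) -> EpochFeatureMatrix:
    """Run all three extraction chains and assemble the 30-feature matrix.

    The epoch grid is the longest span covered by *both* modalities;
    audio at rates other than 5 kHz is resampled first so all filter
    designs see their reference rate.
    """
    cfg = (cfg or RunConfig()).validate()
    audio = resample_audio(audio)
    duration = min(audio.duration, imu.duration)
    grid = align_to_epochs(duration)
    breaths, env = extract_breaths(audio, cfg.resp)
    resp_block, _ = respiratory_feature_block(breaths, env, grid, cfg.resp)
    beats = extract_beats(audio, cfg.cardiac)
    card_block, _ = cardiac_feature_block(beats, grid, cfg.cardiac)
    _, positions = extract_movement(imu, cfg.imu)
    move_block, _ = movement_feature_block(imu, positions, grid, cfg.imu)
    return assemble_features(resp_block, card_block, move_block, grid, subject_id)


def run_pipeline(
    audio_path,
    imu_path,
    model_path,
    system_id: str,
    out_hypnogram,
    out_summary,
    cfg: RunConfig | None = None,
) -> None:
    """File-level pipeline: stage one night and write hypnogram + summary.

    On any failure, partial outputs are removed before the error is
    re-raised so a crashed run leaves no half-written files.
    """
    cfg = (cfg or RunConfig()).validate()
    try:
        audio = read_audio(audio_path)
        imu = read_imu(imu_path)
        model = load_model(model_path)
        features = extract_night_features(audio, imu, cfg)
        hyp, _ = predict_stages(
            model, features, system_id, cfg.staging.median_filter_epochs
        )
        write_hypnogram(hyp, out_hypnogram)
        from .io_core import Hypnogram

        # collapse to wake/sleep for the summary: any non-wake label is sleep
        s2 = Hypnogram(["W" if l == "W" else "S" for l in hyp.labels], "s2")
        summary = sleep_summary(s2)
        with open(out_summary, "w") as fh:
            json.dump(asdict(summary), fh, indent=2)
    except Exception:
        for path in (out_hypnogram, out_summary):
            if path and os.path.exists(path):
                os.remove(path)
        raise
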