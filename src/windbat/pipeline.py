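"""CSV-level pipeline: call-event tables in, buzz/social/song tables out."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import pandas as pd

from . import __version__
from .events import (
    Assignment,
    CallEvent,
    ClassifierRules,
    SongElementRef,
    TriggeredRecording,
    SONG_ELEMENT,
    assemble_song_events,
    classify_sequence,
    detect_feeding_buzzes,
    detect_social_and_song_elements,
)

__all__ = ["load_events_csv", "recordings_from_frame", "classify_recordings", "rules_hash"]

EVENT_COLUMNS = [
    "recording_id",
    "turbine_id",
    "night_date",
    "time_s",
    "duration_ms",
    "start_freq_khz",
    "end_freq_khz",
    "peak_freq_khz",
    "sweep_rate_khz_per_ms",
    "received_level_db_spl",
    "category",
]


def load_events_csv(path) -> list[TriggeredRecording]:
    """Read a call-event table and group it into triggered recordings."""
    return recordings_from_frame(pd.read_csv(path))


def recordings_from_frame(df: pd.DataFrame) -> list[TriggeredRecording]:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    recordings = []
    for rec_id, grp in df.groupby("recording_id", sort=True):
        grp = grp.sort_values("time_s")
        events = [
            CallEvent(
                time_s=float(r.time_s),
                duration_ms=float(r.duration_ms),
                start_freq_khz=float(r.start_freq_khz),
                end_freq_khz=float(r.end_freq_khz),
                peak_freq_khz=float(r.peak_freq_khz),
                sweep_rate_khz_per_ms=float(r.sweep_rate_khz_per_ms),
                received_level_db_spl=float(r.received_level_db_spl),
                category=str(r.category),
                truth_species=(
                    str(r.truth_species)
                    if "truth_species" in df.columns and pd.notna(r.truth_species)
                    else None
                ),
            )
            for r in grp.itertuples(index=False)
        ]
        recordings.append(
            TriggeredRecording(
                recording_id=str(rec_id),
                turbine_id=str(grp["turbine_id"].iloc[0]),
                night_date=str(grp["night_date"].iloc[0]),
                trigger_time_s=float(grp["time_s"].iloc[0]),
                events=events,
                valid=bool(grp["valid"].iloc[0]) if "valid" in df.columns else True,
            )
        )
    return recordings


def rules_hash(rules: ClassifierRules) -> str:
    payload = json.dumps(rules.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def classify_recordings(
    recordings: list[TriggeredRecording],
    rules: ClassifierRules | None = None,
) -> dict:
    """Run the full classification chain over triggered recordings.

    Returns a dict with ``buzzes``, ``events`` (relabelled), ``song_events``
    DataFrames and a JSON-serializable run ``manifest``.
    """
    rules = rules or ClassifierRules()
    buzz_rows, event_rows, song_events = [], [], []
    refs_by_turbine_night: dict[tuple[str, str], list[SongElementRef]] = {}

    for rec in recordings:
        assignment: Assignment = classify_sequence(rec.events, rules)
        for bz in detect_feeding_buzzes(rec, rules):
            buzz_rows.append(asdict(bz))
        labelled = detect_social_and_song_elements(rec, rules, assignment)
        for ev in labelled:
            row = asdict(ev)
            row.update(
                recording_id=rec.recording_id,
                turbine_id=rec.turbine_id,
                night_date=rec.night_date,
                assignment=assignment.label,
                assignment_level=assignment.level,
                valid=rec.valid,
            )
            event_rows.append(row)
            if ev.category == SONG_ELEMENT:
                refs_by_turbine_night.setdefault(
                    (rec.turbine_id, rec.night_date), []
                ).append(
                    SongElementRef(
                        time_s=ev.time_s,
                        recording_id=rec.recording_id,
                        turbine_id=rec.turbine_id,
                        species_or_group=assignment.label,
                    )
                )

    for (turbine_id, night), refs in sorted(refs_by_turbine_night.items()):
        for ev in assemble_song_events(refs, rules):
            song_events.append(
                {
                    "turbine_id": turbine_id,
                    "night_date": night,
                    "species_or_group": ev.species_or_group,
                    "start_time_s": ev.start_time_s,
                    "end_time_s": ev.end_time_s,
                    "duration_s": ev.duration_s,
                    "n_elements": ev.n_elements,
                    "recording_ids": ";".join(ev.recording_ids),
                }
            )

    buzzes = pd.DataFrame(
        buzz_rows,
        columns=[
            "recording_id",
            "start_time_s",
            "end_time_s",
            "n_calls",
            "min_pulse_interval_ms",
            "assignment",
            "assignment_level",
        ],
    )
    events_df = pd.DataFrame(event_rows)
    songs_df = pd.DataFrame(
        song_events,
        columns=[
            "turbine_id",
            "night_date",
            "species_or_group",
            "start_time_s",
            "end_time_s",
            "duration_s",
            "n_elements",
            "recording_ids",
        ],
    )
    manifest = {
        "version": __version__,
        "rules_hash": rules_hash(rules),
        "song_event_max_gap_s": rules.song_event_max_gap_s,
        "n_recordings": len(recordings),
        "n_events": int(len(events_df)),
        "n_buzzes": int(len(buzzes)),
        "n_song_events": int(len(songs_df)),
    }
    return {
        "buzzes": buzzes,
        "events": events_df,
        "song_events": songs_df,
        "manifest": manifest,
    }
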