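"""Rule-based classifier: trigger filter, species bands, buzzes, song."""

import itertools

import pytest

from windbat.events import (
    ECHOLOCATION,
    SOCIAL_CALL,
    SONG_ELEMENT,
    Assignment,
    CallEvent,
    ClassifierRules,
    SongElementRef,
    TriggeredRecording,
    apply_trigger_filter,
    assemble_song_events,
    classify_group,
    classify_sequence,
    detect_feeding_buzzes,
    detect_social_and_song_elements,
)

RULES = ClassifierRules()


def echo(t, fend, duration=5.0, sweep=-5.0):
    return CallEvent(
        time_s=t,
        duration_ms=duration,
        start_freq_khz=fend + duration * abs(sweep),
        end_freq_khz=fend,
        peak_freq_khz=fend + 2.0,
        sweep_rate_khz_per_ms=sweep,
        received_level_db_spl=60.0,
        category=ECHOLOCATION,
    )


def vocal(t, category, peak=20.0):
    return CallEvent(
        time_s=t,
        duration_ms=15.0,
        start_freq_khz=peak + 4.0,
        end_freq_khz=peak - 2.0,
        peak_freq_khz=peak,
        sweep_rate_khz_per_ms=-0.5,
        received_level_db_spl=60.0,
        category=category,
    )


def recording(events, rec_id="r1"):
    return TriggeredRecording(
        recording_id=rec_id,
        turbine_id="T1",
        night_date="2021-08-01",
        trigger_time_s=events[0].time_s if events else 0.0,
        events=events,
    )


# ---------------------------------------------------------------------------
# trigger filter
# ---------------------------------------------------------------------------
def test_trigger_filter_accepts_typical_fm_call():
    assert apply_trigger_filter(echo(0.0, 45.0, duration=5.0, sweep=-5.0), RULES)


def test_trigger_filter_accepts_cf_like_call():
    ev = CallEvent(
        time_s=0.0,
        duration_ms=10.0,
        start_freq_khz=21.0,
        end_freq_khz=20.0,
        peak_freq_khz=20.5,
        sweep_rate_khz_per_ms=-0.1,
        received_level_db_spl=50.0,
    )
    assert apply_trigger_filter(ev, RULES)


def test_trigger_filter_rejects_out_of_band():
    ev = CallEvent(
        time_s=0.0,
        duration_ms=5.0,
        start_freq_khz=10.0,
        end_freq_khz=5.0,
        peak_freq_khz=8.0,
        sweep_rate_khz_per_ms=-1.0,
        received_level_db_spl=50.0,
    )
    assert not apply_trigger_filter(ev, RULES)


def test_trigger_filter_rejects_too_steep_sweep():
    ev = CallEvent(
        time_s=0.0,
        duration_ms=2.0,
        start_freq_khz=80.0,
        end_freq_khz=40.0,
        peak_freq_khz=50.0,
        sweep_rate_khz_per_ms=-20.0,
        received_level_db_spl=50.0,
    )
    assert not apply_trigger_filter(ev, RULES)


def test_trigger_filter_duration_bounds():
    short = echo(0.0, 45.0, duration=0.5, sweep=-5.0)
    long = echo(0.0, 45.0, duration=40.0, sweep=-5.0)
    assert not apply_trigger_filter(short, RULES)
    assert not apply_trigger_filter(long, RULES)


# ---------------------------------------------------------------------------
# species / group classification by end frequency
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "fends,label,level",
    [
        ((20.0, 21.0), "Nyctalus noctula", "species"),
        ((23.0, 28.0), "Nyctaloid", "group"),
        ((21.0, 25.0), "Nyctaloid", "group"),  # straddles Nnoc + Nyctaloid bins
        ((35.0, 41.0), "Pipistrellus nathusii", "species"),
        ((45.0, 46.0), "Pipistrellus pipistrellus", "species"),
        ((52.0, 60.0), "Pipistrellus pygmaeus", "species"),
        ((41.0, 43.0), "Pipistrellus spp.", "group"),  # straddles Pnat + Ppip
        ((29.5, 29.5), "Chiroptera", "unknown"),  # deliberate gap (29, 30]
        ((20.0, 45.0), "Chiroptera", "unknown"),  # cross-group
    ],
)
def test_classify_sequence_examples(fends, label, level):
    events = [echo(0.1 * i, f) for i, f in enumerate(fends)]
    got = classify_sequence(events, RULES)
    assert got == Assignment(label, level)


def test_classify_sequence_boundaries():
    # bin edges: Nnoc < 22; Nyctaloid (22, 29]; gap (29, 30]; Pnat (30, 42]
    assert classify_sequence([echo(0, 21.99), echo(0.1, 21.99)]).label == "Nyctalus noctula"
    # exactly 22 kHz lies in neither band (Nnoc is strictly < 22, the
    # Nyctaloid-group bin is open at 22) -> unidentified
    assert classify_sequence([echo(0, 22.0), echo(0.1, 22.0)]).label == "Chiroptera"
    assert classify_sequence([echo(0, 22.01), echo(0.1, 22.01)]).label == "Nyctaloid"
    assert classify_sequence([echo(0, 29.0), echo(0.1, 29.0)]).label == "Nyctaloid"
    assert classify_sequence([echo(0, 29.5), echo(0.1, 29.5)]).label == "Chiroptera"
    assert classify_sequence([echo(0, 30.0), echo(0.1, 30.0)]).label == "Chiroptera"
    assert classify_sequence([echo(0, 30.01), echo(0.1, 30.01)]).label == "Pipistrellus nathusii"
    assert classify_sequence([echo(0, 42.0), echo(0.1, 42.0)]).label == "Pipistrellus nathusii"
    assert classify_sequence([echo(0, 42.01), echo(0.1, 42.01)]).label == "Pipistrellus pipistrellus"
    assert classify_sequence([echo(0, 51.0), echo(0.1, 51.0)]).label == "Pipistrellus pipistrellus"
    assert classify_sequence([echo(0, 51.01), echo(0.1, 51.01)]).label == "Pipistrellus pygmaeus"


def test_classify_sequence_needs_two_calls():
    assert classify_sequence([echo(0, 45.0)]).level == "unknown"


def test_classify_group_detector_bands():
    assert classify_group([20.0, 30.0, 32.9]) == "Nyctaloid"
    assert classify_group([33.0, 50.0]) == "Pipistrelloid"
    assert classify_group([30.0, 40.0]) == "Chiroptera"  # straddles the bands
    assert classify_group([70.0]) == "Chiroptera"  # outside both bands


# ---------------------------------------------------------------------------
# feeding buzzes
# ---------------------------------------------------------------------------
def buzz_oracle(times_ms, max_int=10.0, min_run=3):
    """Brute-force window scan for maximal qualifying interval runs."""
    runs = []
    n = len(times_ms)
    i = 0
    while i < n - 1:
        if times_ms[i + 1] - times_ms[i] <= max_int:
            j = i
            while j < n - 1 and times_ms[j + 1] - times_ms[j] <= max_int:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def make_times(intervals_ms):
    t, out = 0.0, [0.0]
    for dt in intervals_ms:
        t += dt
        out.append(t)
    return out


@pytest.mark.parametrize(
    "intervals",
    [
        [200, 150, 9, 8, 7, 200],  # exactly 3 short intervals -> one buzz
        [200, 150, 9, 8, 200],  # only 2 short intervals -> none
        [200, 9, 9, 9, 200, 8, 8, 8, 8, 150],  # two separate buzzes
        [10, 10, 10],  # boundary: exactly at threshold
        [10.01, 10.01, 10.01],  # just above threshold -> none
        [200] * 6,
        [5] * 10,
    ],
)
def test_buzz_detection_matches_window_oracle(intervals):
    times_ms = make_times(intervals)
    events = [echo(t / 1000.0, 45.0) for t in times_ms]
    rec = recording(events)
    got = detect_feeding_buzzes(rec, RULES)
    want = buzz_oracle(times_ms)
    assert len(got) == len(want)
    for bz, (i, j) in zip(got, want):
        assert bz.start_time_s == pytest.approx(times_ms[i] / 1000.0)
        assert bz.end_time_s == pytest.approx(times_ms[j] / 1000.0)
        assert bz.n_calls == j - i + 1


def test_buzz_assignment_from_preceding_search_calls():
    times_ms = make_times([200, 150, 9, 8, 7])
    events = [echo(t / 1000.0, 45.0) for t in times_ms]
    [bz] = detect_feeding_buzzes(recording(events), RULES)
    assert bz.assignment == "Pipistrellus pipistrellus"
    assert bz.assignment_level == "species"


def test_buzz_single_search_call_falls_back_to_group():
    times_ms = make_times([200, 9, 8, 7])
    events = [echo(t / 1000.0, 45.0) for t in times_ms]
    [bz] = detect_feeding_buzzes(recording(events), RULES)
    assert bz.assignment == "Pipistrelloid"
    assert bz.assignment_level == "group"


def test_buzz_requires_sorted_events():
    events = [echo(0.5, 45.0), echo(0.1, 45.0)]
    rec = recording([echo(0.0, 45.0)])
    rec.events = events  # bypass constructor check to exercise the guard
    with pytest.raises(ValueError):
        detect_feeding_buzzes(rec, RULES)


# ---------------------------------------------------------------------------
# social calls vs song elements
# ---------------------------------------------------------------------------
def test_short_pip_song_run_downgraded_to_social():
    events = [echo(0.0, 45.0), echo(0.2, 45.0)] + [
        vocal(0.5 + 0.3 * i, SONG_ELEMENT) for i in range(4)
    ]
    out = detect_social_and_song_elements(recording(events), RULES)
    assert [e.category for e in out[2:]] == [SOCIAL_CALL] * 4


def test_five_element_pip_song_run_kept():
    events = [echo(0.0, 45.0), echo(0.2, 45.0)] + [
        vocal(0.5 + 0.3 * i, SONG_ELEMENT) for i in range(5)
    ]
    out = detect_social_and_song_elements(recording(events), RULES)
    assert [e.category for e in out[2:]] == [SONG_ELEMENT] * 5


def test_echolocation_does_not_break_song_run():
    events = [echo(0.0, 45.0), echo(0.2, 45.0)]
    t = 0.5
    for i in range(5):
        events.append(vocal(t, SONG_ELEMENT))
        t += 0.2
        if i == 2:
            events.append(echo(t, 45.0))
            t += 0.2
    out = detect_social_and_song_elements(recording(events), RULES)
    assert sum(e.category == SONG_ELEMENT for e in out) == 5


def test_social_call_breaks_song_run():
    events = [echo(0.0, 45.0), echo(0.2, 45.0)]
    t = 0.5
    for i in range(6):
        events.append(vocal(t, SONG_ELEMENT))
        t += 0.2
        if i == 2:
            events.append(vocal(t, SOCIAL_CALL))
            t += 0.2
    out = detect_social_and_song_elements(recording(events), RULES)
    # runs of 3 and 3, both below the 5-element minimum -> all social
    assert sum(e.category == SONG_ELEMENT for e in out) == 0


def test_nyctaloid_song_has_no_minimum_run():
    events = [echo(0.0, 20.0), echo(0.3, 20.0), vocal(0.6, SONG_ELEMENT, peak=16.0)]
    out = detect_social_and_song_elements(recording(events), RULES)
    assert out[-1].category == SONG_ELEMENT


def test_relabelling_conserves_length_and_times():
    events = [echo(0.0, 45.0), echo(0.2, 45.0)] + [
        vocal(0.5 + 0.3 * i, SONG_ELEMENT) for i in range(3)
    ]
    out = detect_social_and_song_elements(recording(events), RULES)
    assert len(out) == len(events)
    assert [e.time_s for e in out] == [e.time_s for e in events]
    assert {ECHOLOCATION: 2}.items() <= _count(out).items()


def _count(events):
    d = {}
    for e in events:
        d[e.category] = d.get(e.category, 0) + 1
    return d


# ---------------------------------------------------------------------------
# song-event assembly vs brute-force partition oracle
# ---------------------------------------------------------------------------
def assembly_oracle(times, max_gap):
    """All maximal clusterings where successive gaps <= max_gap (unique)."""
    clusters = []
    cur = [times[0]]
    for t in times[1:]:
        if t - cur[-1] <= max_gap:
            cur.append(t)
        else:
            clusters.append(cur)
            cur = [t]
    clusters.append(cur)
    return clusters


@pytest.mark.parametrize(
    "times",
    [
        [0.0, 1.0, 2.0, 10.0, 11.0],
        [0.0, 5.0, 10.0, 15.0],  # gaps exactly at threshold -> one event
        [0.0, 5.01],  # just over -> two events
        [0.0],
        [0.0, 0.1, 0.2, 0.3, 20.0, 20.1, 40.0],
    ],
)
def test_assembly_matches_partition_oracle(times):
    refs = [
        SongElementRef(time_s=t, recording_id="r", turbine_id="T1", species_or_group="Pipistrellus nathusii")
        for t in times
    ]
    got = assemble_song_events(refs, RULES)
    want = assembly_oracle(times, RULES.song_event_max_gap_s)
    assert len(got) == len(want)
    for ev, cluster in zip(got, want):
        assert ev.start_time_s == cluster[0]
        assert ev.end_time_s == cluster[-1]
        assert ev.n_elements == len(cluster)


def test_assembly_exhaustive_small_gap_patterns():
    """Exhaustive oracle comparison over all gap patterns of length 4."""
    for gaps in itertools.product([1.0, 4.9, 5.0, 5.1, 12.0], repeat=4):
        times = make_times([g * 1000.0 for g in gaps])
        times = [t / 1000.0 for t in times]
        refs = [
            SongElementRef(time_s=t, recording_id="r", turbine_id="T1", species_or_group="X")
            for t in times
        ]
        got = assemble_song_events(refs, RULES)
        want = assembly_oracle(times, RULES.song_event_max_gap_s)
        assert [ev.n_elements for ev in got] == [len(c) for c in want], gaps


def test_assembly_groups_by_label():
    refs = [
        SongElementRef(0.0, "r1", "T1", "A"),
        SongElementRef(1.0, "r1", "T1", "B"),
        SongElementRef(2.0, "r1", "T1", "A"),
    ]
    events = assemble_song_events(refs, RULES)
    labels = sorted(ev.species_or_group for ev in events)
    assert labels == ["A", "B"]
    a = [ev for ev in events if ev.species_or_group == "A"][0]
    assert a.n_elements == 2  # merged across the interleaved B element


def test_assembly_rejects_multiple_turbines():
    refs = [SongElementRef(0.0, "r1", "T1", "A"), SongElementRef(1.0, "r2", "T2", "A")]
    with pytest.raises(ValueError):
        assemble_song_events(refs, RULES)


def test_assembly_spans_recordings():
    refs = [SongElementRef(0.0, "r1", "T1", "A"), SongElementRef(3.0, "r2", "T1", "A")]
    [ev] = assemble_song_events(refs, RULES)
    assert ev.recording_ids == ("r1", "r2")
    assert ev.duration_s == pytest.approx(3.0)


def test_call_event_validation():
    with pytest.raises(ValueError):
        CallEvent(
            time_s=0.0,
            duration_ms=-1.0,
            start_freq_khz=40.0,
            end_freq_khz=20.0,
            peak_freq_khz=30.0,
            sweep_rate_khz_per_ms=-5.0,
            received_level_db_spl=50.0,
        )
    with pytest.raises(ValueError):
        CallEvent(
            time_s=0.0,
            duration_ms=5.0,
            start_freq_khz=20.0,
            end_freq_khz=40.0,  # upward while sweep negative
            peak_freq_khz=30.0,
            sweep_rate_khz_per_ms=-5.0,
            received_level_db_spl=50.0,
        )
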