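"""Rule-based classification of nacelle-height bat call events.

Works on parameterized call-event streams (one row per vocalization, with
timing, frequency and category measurements) rather than raw audio.  The
operations mirror the processing chain used for nacelle monitoring data:

1. a trigger filter decides whether an event looks like a bat call at all,
2. echolocation sequences are assigned to species or acoustic species
   groups from their end frequencies,
3. feeding buzzes are detected as runs of pulse intervals <= 10 ms
   (repetition rate >= 100 calls/s),
4. social vocalizations are split into social calls and song elements
   (Pipistrelloid and Plecotus song requires >= 5 consecutive elements),
5. temporally successive song elements are merged into song events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "ECHOLOCATION",
    "SOCIAL_CALL",
    "SONG_ELEMENT",
    "CallEvent",
    "TriggeredRecording",
    "TriggerFilterSettings",
    "ClassifierRules",
    "Assignment",
    "FeedingBuzz",
    "SongElementRef",
    "SongEvent",
    "apply_trigger_filter",
    "classify_sequence",
    "classify_group",
    "detect_feeding_buzzes",
    "detect_social_and_song_elements",
    "assemble_song_events",
]

ECHOLOCATION = "echolocation"
SOCIAL_CALL = "social_call"
SONG_ELEMENT = "song_element"
_CATEGORIES = frozenset({ECHOLOCATION, SOCIAL_CALL, SONG_ELEMENT})

UNKNOWN_LABEL = "Chiroptera"


@dataclass(frozen=True)
class CallEvent:
    """One parameterized bat vocalization."""

    time_s: float
    duration_ms: float
    start_freq_khz: float
    end_freq_khz: float
    peak_freq_khz: float
    sweep_rate_khz_per_ms: float
    received_level_db_spl: float
    category: str = ECHOLOCATION
    truth_species: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration_ms) and self.duration_ms > 0):
            raise ValueError(f"duration_ms must be finite and > 0: {self.duration_ms}")
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown category: {self.category!r}")
        if self.sweep_rate_khz_per_ms < 0 and self.end_freq_khz > self.start_freq_khz:
            raise ValueError("downward-FM call with end frequency above start frequency")


@dataclass
class TriggeredRecording:
    """A triggered sound file: pre/post-trigger buffers and its events."""

    recording_id: str
    turbine_id: str
    night_date: str
    trigger_time_s: float
    events: list[CallEvent] = field(default_factory=list)
    pre_trigger_s: float = 0.3
    post_trigger_s: float = 1.0
    valid: bool = True  # microphone sensitivity within +-6 dB of calibration

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"events of recording {self.recording_id!r} not time-sorted")
        if times and times[0] < self.trigger_time_s - self.pre_trigger_s - 1e-9:
            raise ValueError(
                f"event before pre-trigger window in recording {self.recording_id!r}"
            )


@dataclass(frozen=True)
class TriggerFilterSettings:
    """Bat-call trigger filter: FM/CF duration, sweep-rate and band criteria.

    Defaults are the recording-time dialect (15-80 kHz); the identification
    dialect uses 15-100 kHz.
    """

    fm_min_duration_ms: float = 1.0
    fm_max_duration_ms: float = 30.0
    fm_min_sweep_khz_per_ms: float = -9.0
    fm_max_sweep_khz_per_ms: float = -1.0
    cf_min_duration_ms: float = 2.0
    cf_max_duration_ms: float = 30.0
    cf_min_sweep_khz_per_ms: float = -2.0
    cf_max_sweep_khz_per_ms: float = 1.0
    freq_range_khz: tuple[float, float] = (15.0, 80.0)


# species-level end-frequency bins: (label, lo, hi, lo_inclusive, hi_inclusive)
_SPECIES_BINS: tuple[tuple[str, float, float, bool, bool], ...] = (
    ("Nyctalus noctula", 8.0, 22.0, True, False),       # F_end < 22
    ("Nyctaloid", 22.0, 29.0, False, True),             # >22 and <=29 (group bin)
    # (29, 30] is a deliberate gap -> Chiroptera
    ("Pipistrellus nathusii", 30.0, 42.0, False, True),  # >30 and <=42
    ("Pipistrellus pipistrellus", 42.0, 51.0, False, True),
    ("Pipistrellus pygmaeus", 51.0, 65.0, False, False),  # >51
)

_BIN_GROUP = {
    "Nyctalus noctula": "Nyctaloid",
    "Nyctaloid": "Nyctaloid",
    "Pipistrellus nathusii": "Pipistrelloid",
    "Pipistrellus pipistrellus": "Pipistrelloid",
    "Pipistrellus pygmaeus": "Pipistrelloid",
}


@dataclass(frozen=True)
class ClassifierRules:
    """All thresholds of the rule-based classifier (configurable)."""

    group_bands: dict = field(
        default_factory=lambda: {
            "Nyctaloid": (8.0, 33.0),        # [8, 33) kHz
            "Pipistrelloid": (33.0, 65.0),   # [33, 65) kHz
        }
    )
    buzz_max_pulse_interval_ms: float = 10.0
    buzz_min_intervals: int = 3
    min_search_calls_for_id: int = 2
    min_consecutive_song_elements_pip: int = 5
    song_event_max_gap_s: float = 5.0
    trigger_filter: TriggerFilterSettings = field(default_factory=TriggerFilterSettings)

    def __post_init__(self) -> None:
        if not self.buzz_max_pulse_interval_ms > 0:
            raise ValueError("buzz_max_pulse_interval_ms must be positive")
        if self.min_consecutive_song_elements_pip < 1:
            raise ValueError("min_consecutive_song_elements_pip must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Assignment:
    """Species (-group) assignment of a call sequence."""

    label: str
    level: str  # 'species' | 'group' | 'unknown'


@dataclass(frozen=True)
class FeedingBuzz:
    recording_id: str
    start_time_s: float
    end_time_s: float
    n_calls: int
    min_pulse_interval_ms: float
    assignment: str
    assignment_level: str


@dataclass(frozen=True)
class SongElementRef:
    """A song-eligible element with its provenance, ready for assembly."""

    time_s: float
    recording_id: str
    turbine_id: str
    species_or_group: str


@dataclass(frozen=True)
class SongEvent:
    species_or_group: str
    start_time_s: float
    end_time_s: float
    n_elements: int
    recording_ids: tuple[str, ...]

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.start_time_s


def apply_trigger_filter(event: CallEvent, rules: ClassifierRules) -> bool:
    """True iff the event satisfies the FM or CF trigger criteria and lies
    (at least partly) inside the filter's frequency range."""
    tf = rules.trigger_filter
    vals = (
        event.duration_ms,
        event.start_freq_khz,
        event.end_freq_khz,
        event.sweep_rate_khz_per_ms,
    )
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite call parameters")

    lo, hi = sorted((event.start_freq_khz, event.end_freq_khz))
    band_ok = hi >= tf.freq_range_khz[0] and lo <= tf.freq_range_khz[1]
    fm_ok = (
        tf.fm_min_duration_ms <= event.duration_ms <= tf.fm_max_duration_ms
        and tf.fm_min_sweep_khz_per_ms
        <= event.sweep_rate_khz_per_ms
        <= tf.fm_max_sweep_khz_per_ms
    )
    cf_ok = (
        tf.cf_min_duration_ms <= event.duration_ms <= tf.cf_max_duration_ms
        and tf.cf_min_sweep_khz_per_ms
        <= event.sweep_rate_khz_per_ms
        <= tf.cf_max_sweep_khz_per_ms
    )
    return band_ok and (fm_ok or cf_ok)


def _species_bin(fend_khz: float) -> str | None:
    for label, lo, hi, lo_inc, hi_inc in _SPECIES_BINS:
        above = fend_khz >= lo if lo_inc else fend_khz > lo
        below = fend_khz <= hi if hi_inc else fend_khz < hi
        if above and below:
            return label
    return None


def classify_group(end_freqs_khz, rules: ClassifierRules | None = None) -> str:
    """Coarse acoustic species group from end frequencies (detector-style
    half-open bands, Nyctaloid [8, 33) / Pipistrelloid [33, 65) kHz)."""
    rules = rules or ClassifierRules()
    groups = set()
    for f in end_freqs_khz:
        hit = None
        for name, (lo, hi) in rules.group_bands.items():
            if lo <= f < hi:
                hit = name
                break
        groups.add(hit)
    if len(groups) == 1 and None not in groups:
        return groups.pop()
    return UNKNOWN_LABEL


def classify_sequence(events, rules: ClassifierRules | None = None) -> Assignment:
    """Species (-group) assignment of an echolocation call sequence.

    Species label when all measured end frequencies fall into a single
    species bin; group label when they straddle adjacent species bins of
    one group; 'Chiroptera' when ambiguous across groups or inside the
    deliberate (29, 30] kHz gap.
    """
    rules = rules or ClassifierRules()
    echo = [e for e in events if e.category == ECHOLOCATION]
    if len(echo) < rules.min_search_calls_for_id:
        return Assignment(UNKNOWN_LABEL, "unknown")

    bins = {_species_bin(e.end_freq_khz) for e in echo}
    if None in bins:
        return Assignment(UNKNOWN_LABEL, "unknown")
    if len(bins) == 1:
        label = bins.pop()
        level = "group" if label == "Nyctaloid" else "species"
        return Assignment(label, level)
    groups = {_BIN_GROUP[b] for b in bins}
    if groups == {"Pipistrelloid"}:
        return Assignment("Pipistrellus spp.", "group")
    if groups == {"Nyctaloid"}:
        return Assignment("Nyctaloid", "group")
    return Assignment(UNKNOWN_LABEL, "unknown")


def detect_feeding_buzzes(
    rec: TriggeredRecording, rules: ClassifierRules | None = None
) -> list[FeedingBuzz]:
    """Feeding buzzes: maximal runs of >= ``buzz_min_intervals`` consecutive
    echolocation pulse intervals <= ``buzz_max_pulse_interval_ms``.

    The species assignment comes from the search-phase calls between the
    previous buzz (or the recording start) and the buzz itself.
    """
    rules = rules or ClassifierRules()
    echo = [e for e in rec.events if e.category == ECHOLOCATION]
    times = [e.time_s for e in echo]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be time-sorted")
    if len(echo) < 2:
        return []

    intervals_ms = [
        (t1 - t0) * 1000.0 for t0, t1 in zip(times, times[1:])
    ]
    buzzes: list[FeedingBuzz] = []
    runs: list[tuple[int, int]] = []  # [start_call_idx, end_call_idx] inclusive
    i = 0
    n_int = len(intervals_ms)
    while i < n_int:
        if intervals_ms[i] <= rules.buzz_max_pulse_interval_ms:
            j = i
            while j + 1 < n_int and intervals_ms[j + 1] <= rules.buzz_max_pulse_interval_ms:
                j += 1
            if j - i + 1 >= rules.buzz_min_intervals:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1

    prev_end = -1
    for start, end in runs:
        search = echo[prev_end + 1 : start]
        if len(search) >= rules.min_search_calls_for_id:
            assignment = classify_sequence(search, rules)
        elif search:
            grp = _BIN_GROUP.get(_species_bin(search[-1].end_freq_khz) or "", None)
            assignment = (
                Assignment(grp, "group") if grp else Assignment(UNKNOWN_LABEL, "unknown")
            )
        else:
            assignment = Assignment(UNKNOWN_LABEL, "unknown")
        buzz_calls = echo[start : end + 1]
        buzzes.append(
            FeedingBuzz(
                recording_id=rec.recording_id,
                start_time_s=buzz_calls[0].time_s,
                end_time_s=buzz_calls[-1].time_s,
                n_calls=len(buzz_calls),
                min_pulse_interval_ms=min(intervals_ms[start:end]),
                assignment=assignment.label,
                assignment_level=assignment.level,
            )
        )
        prev_end = end
    return buzzes


def _pip_song_rule_applies(assignment: Assignment) -> bool:
    # The minimum-run rule covers Pipistrelloid assignments and, conservatively,
    # Plecotus and unidentified sequences; Nyctaloid song has no minimum run.
    if assignment.label.startswith("Plecotus"):
        return True
    if _BIN_GROUP.get(assignment.label) == "Nyctaloid" or assignment.label == "Nyctaloid":
        return False
    return True


def detect_social_and_song_elements(
    rec: TriggeredRecording,
    rules: ClassifierRules | None = None,
    assignment: Assignment | None = None,
) -> list[CallEvent]:
    """Relabel social vocalizations: song elements stay song-eligible only
    when the run-length rule for the assigned species group is met,
    otherwise they are downgraded to social calls.

    Runs of song elements may be interspersed with echolocation calls (as
    in natural song sequences) but are broken by social calls.  Returns a
    new event list of identical length and order.
    """
    rules = rules or ClassifierRules()
    if assignment is None:
        assignment = classify_sequence(rec.events, rules)
    needs_min_run = _pip_song_rule_applies(assignment)
    min_run = rules.min_consecutive_song_elements_pip if needs_min_run else 1

    out = list(rec.events)
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if 0 < len(run_idx) < min_run:
            for k in run_idx:
                e = out[k]
                out[k] = CallEvent(
                    time_s=e.time_s,
                    duration_ms=e.duration_ms,
                    start_freq_khz=e.start_freq_khz,
                    end_freq_khz=e.end_freq_khz,
                    peak_freq_khz=e.peak_freq_khz,
                    sweep_rate_khz_per_ms=e.sweep_rate_khz_per_ms,
                    received_level_db_spl=e.received_level_db_spl,
                    category=SOCIAL_CALL,
                    truth_species=e.truth_species,
                )

    for idx, e in enumerate(rec.events):
        if e.category == SONG_ELEMENT:
            run.append(idx)
        elif e.category == SOCIAL_CALL:
            flush(run)
            run = []
        # echolocation calls interleave without breaking the run
    flush(run)
    return out


def assemble_song_events(
    elements: list[SongElementRef], rules: ClassifierRules | None = None
) -> list[SongEvent]:
    """Merge song-eligible elements of one turbine-night into song events.

    Consecutive elements with the same assignment and inter-element gap
    <= ``song_event_max_gap_s`` form one event, which may span recordings.
    """
    rules = rules or ClassifierRules()
    if not elements:
        return []
    turbines = {el.turbine_id for el in elements}
    if len(turbines) > 1:
        raise ValueError(f"elements from multiple turbines: {sorted(turbines)}")

    events: list[SongEvent] = []
    by_label: dict[str, list[SongElementRef]] = {}
    for el in elements:
        by_label.setdefault(el.species_or_group, []).append(el)
    for label in sorted(by_label):
        els = sorted(by_label[label], key=lambda el: el.time_s)
        cluster: list[SongElementRef] = [els[0]]
        for el in els[1:]:
            if el.time_s - cluster[-1].time_s <= rules.song_event_max_gap_s:
                cluster.append(el)
            else:
                events.append(_make_song_event(label, cluster))
                cluster = [el]
        events.append(_make_song_event(label, cluster))
    events.sort(key=lambda ev: (ev.start_time_s, ev.species_or_group))
    return events


def _make_song_event(label: str, cluster: list[SongElementRef]) -> SongEvent:
    rec_ids = []
    for el in cluster:
        if el.recording_id not in rec_ids:
            rec_ids.append(el.recording_id)
    return SongEvent(
        species_or_group=label,
        start_time_s=cluster[0].time_s,
        end_time_s=cluster[-1].time_s,
        n_elements=len(cluster),
        recording_ids=tuple(rec_ids),
    )
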