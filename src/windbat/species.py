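"""Per-species acoustic and kinematic constants.

The packaged parameter table covers the seven species (-groups) for which
song flight has been documented at nacelle height in Central Europe.  Song
peak frequencies span 14.0-26.4 kHz and source levels 72-108 dB peSPL at
1 m; the provenance column states, per row, which entries are published
values or calibrated against published detection distances and which are
literature-plausible placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["SpeciesProfile", "load_species_table", "default_profiles"]


@dataclass(frozen=True)
class SpeciesProfile:
    """Acoustic and kinematic constants for one species (-group)."""

    species: str
    group: str
    song_peak_freq_khz: float
    song_source_level_db: float
    flight_speed_m_s: float | None = None
    #: echolocation end-frequency band (kHz) used for species identification
    fend_band_khz: tuple[float, float] | None = None
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        if not (5.0 <= self.song_peak_freq_khz <= 100.0):
            raise ValueError(
                f"song peak frequency out of range: {self.song_peak_freq_khz}"
            )
        if not self.song_source_level_db > 0:
            raise ValueError("source level must be positive")
        if self.flight_speed_m_s is not None and not self.flight_speed_m_s > 0:
            raise ValueError("flight speed must be positive")


def load_species_table() -> pd.DataFrame:
    """Packaged species parameter table as a DataFrame."""
    with resources.files("windbat.data").joinpath("species_params.csv").open() as fh:
        return pd.read_csv(fh)


def default_profiles() -> dict[str, SpeciesProfile]:
    """The seven singing species (-groups), keyed by species name."""
    table = load_species_table()
    out: dict[str, SpeciesProfile] = {}
    for row in table.itertuples(index=False):
        out[row.species] = SpeciesProfile(
            species=row.species,
            group=row.group,
            song_peak_freq_khz=float(row.song_peak_freq_khz),
            song_source_level_db=float(row.song_source_level_db),
            flight_speed_m_s=float(row.flight_speed_m_s),
            fend_band_khz=(float(row.fend_lo_khz), float(row.fend_hi_khz)),
            provenance=str(row.provenance),
        )
    return out
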