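"""Music stimulus library: loading, motivational rating, and song selection.

The packaged stimulus table lists 117 songs pre-selected for running
(clear beat, tempo nominally inside the 130-200 BPM band that covers
recreational runners' cadences).  Songs are rated per listener with the
six-item Brunel Music Rating Inventory 2 (BMRI-2, 1-7 Likert per item);
the top-rated songs form a personal playlist, and for each running
sequence the highest-rated playlist song whose tempo lies within 5 % of
the runner's current cadence is chosen.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import EligibilityError, FormatError, ValidationError

#: nominal tempo band of the library, BPM
NOMINAL_RANGE = (130.0, 200.0)

#: relative tempo window around the runner's cadence for song eligibility
TEMPO_WINDOW = 0.05

REQUIRED_COLUMNS = ["id", "artist", "title", "label", "year", "tempo_bpm"]


@dataclass(frozen=True)
class Song:
    """One stimulus: identity, provenance and (stable) tempo in BPM."""

    id: int
    artist: str
    title: str
    label: str
    year: int
    tempo: float

    def __post_init__(self):
        if self.tempo <= 0:
            raise ValidationError(f"song {self.id}: tempo must be positive, got {self.tempo}")


@dataclass
class StimulusLibrary:
    """Ordered song collection with a nominal tempo range."""

    songs: list[Song]
    nominal_range: tuple[float, float] = NOMINAL_RANGE

    def __post_init__(self):
        ids = [s.id for s in self.songs]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate song ids in library")

    def __len__(self) -> int:
        return len(self.songs)

    def __getitem__(self, song_id: int) -> Song:
        for s in self.songs:
            if s.id == song_id:
                return s
        raise KeyError(song_id)

    def out_of_range_ids(self) -> list[int]:
        """Ids of songs whose tempo falls outside the nominal range.

        Such rows are retained on load (the packaged table itself contains
        one: id 117 at 210 BPM) but flagged so protocols can exclude them.
        """
        lo, hi = self.nominal_range
        return [s.id for s in self.songs if not (lo <= s.tempo <= hi)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.id, s.artist, s.title, s.label, s.year, s.tempo) for s in self.songs],
            columns=REQUIRED_COLUMNS,
        )


@dataclass(frozen=True)
class BmriRating:
    """Six BMRI-2 item responses (1-7 Likert) for one song."""

    song_id: int
    items: tuple[int, ...]

    def __post_init__(self):
        if len(self.items) != 6:
            raise ValidationError(f"BMRI-2 requires exactly 6 items, got {len(self.items)}")
        for it in self.items:
            if not 1 <= int(it) <= 7:
                raise ValidationError(f"BMRI-2 item {it} outside 1..7")


def load_library(table_source, nominal_range: tuple[float, float] = NOMINAL_RANGE) -> StimulusLibrary:
    """Load a stimulus table (CSV path, buffer, or DataFrame) into a library.

    Row order is preserved.  Out-of-range tempos are retained, not dropped;
    query :meth:`StimulusLibrary.out_of_range_ids` to flag them.

    Raises
    ------
    FormatError
        on a missing column, an empty table, or a non-numeric tempo
        (naming the offending row).
    """
    if isinstance(table_source, pd.DataFrame):
        df = table_source.copy()
    else:
        df = pd.read_csv(table_source, dtype={"artist": str, "title": str, "label": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stimulus table missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError("stimulus table has no rows")

    songs = []
    for idx, row in df.iterrows():
        try:
            tempo = float(row["tempo_bpm"])
        except (TypeError, ValueError):
            raise FormatError(
                f"row {idx} (id={row['id']!r}): tempo {row['tempo_bpm']!r} is not numeric"
            ) from None
        songs.append(
            Song(
                id=int(row["id"]),
                artist=str(row["artist"]),
                title=str(row["title"]),
                label=str(row["label"]),
                year=int(row["year"]),
                tempo=tempo,
            )
        )
    return StimulusLibrary(songs=songs, nominal_range=nominal_range)


def packaged_library() -> StimulusLibrary:
    """The 117-song stimulus table shipped with the package."""
    ref = importlib.resources.files("gaitsync").joinpath("data/stimulus_table.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_library(fh)


def write_library(library: StimulusLibrary, path) -> None:
    """Write a library back to CSV; round-trips bit-exactly with load_library."""
    df = library.to_frame()
    # keep integer tempos integer so the packaged table round-trips
    df["tempo_bpm"] = df["tempo_bpm"].map(lambda v: int(v) if float(v).is_integer() else v)
    df.to_csv(path, index=False)


def bmri2_score(rating: BmriRating) -> int:
    """Sum of the six BMRI-2 items; range 6..42."""
    return int(sum(rating.items))


def load_ratings(source) -> list[BmriRating]:
    """Read ratings CSV with columns song_id,i1..i6."""
    df = pd.read_csv(source)
    cols = ["song_id", "i1", "i2", "i3", "i4", "i5", "i6"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"ratings table missing column(s): {', '.join(missing)}")
    return [
        BmriRating(song_id=int(r.song_id), items=(int(r.i1), int(r.i2), int(r.i3), int(r.i4), int(r.i5), int(r.i6)))
        for r in df.itertuples()
    ]


def select_playlist(
    library: StimulusLibrary, ratings: Iterable[BmriRating], n: int
) -> list[Song]:
    """The ``n`` songs with highest BMRI-2 score, best first.

    Ties broken deterministically by lower song id.
    """
    ratings = list(ratings)
    if n < 1:
        raise ValidationError("playlist size must be >= 1")
    ids = {s.id for s in library.songs}
    for r in ratings:
        if r.song_id not in ids:
            raise ValidationError(f"rating references unknown song id {r.song_id}")
    if n > len(ratings):
        raise ValidationError(f"requested {n} songs but only {len(ratings)} were rated")
    ranked = sorted(ratings, key=lambda r: (-bmri2_score(r), r.song_id))
    return [library[r.song_id] for r in ranked[:n]]


def pick_song(playlist: Sequence[Song], cadence: float) -> Song:
    """Highest-ranked playlist song whose tempo is within 5 % of ``cadence``.

    The window is measured relative to the cadence, boundary inclusive:
    a song is eligible iff ``|tempo - cadence| / cadence <= 0.05``.  After
    selection the playback tempo is adjusted to match the cadence exactly,
    so the window only bounds how much time-stretching is needed.

    Raises
    ------
    EligibilityError
        if no song qualifies; carries the nearest-tempo song as ``fallback``.
    """
    if cadence <= 0:
        raise ValidationError("cadence must be positive")
    if not playlist:
        raise ValidationError("playlist is empty")
    for song in playlist:
        if abs(song.tempo - cadence) / cadence <= TEMPO_WINDOW:
            return song
    nearest = min(playlist, key=lambda s: abs(s.tempo - cadence))
    raise EligibilityError(
        f"no playlist song within {TEMPO_WINDOW:.0%} of cadence {cadence:.1f} SPM "
        f"(nearest: id {nearest.id} at {nearest.tempo:.0f} BPM)",
        fallback=nearest,
    )
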