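import pytest

from tpsmap import LibraryMeta, ReadStartTrack


def make_track(
    entries: dict[tuple[str, int], float],
    *,
    treatment: str = "TEX_MINUS",
    replicon: str = "chr",
    length: int | None = None,
    library_id: str = "lib",
) -> ReadStartTrack:
    """Build a one-replicon track from {(strand, position): count}."""
    track = ReadStartTrack(
        meta=LibraryMeta(library_id=library_id, treatment=treatment),
        lengths={replicon: length},
    )
    for (strand, pos), count in entries.items():
        track.add(replicon, strand, pos, count)
    track.sync_total()
    return track


@pytest.fixture
def track_factory():
    return make_track
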