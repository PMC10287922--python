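"""From mapped fragments to normalized per-nucleotide cleavage signal.

Both library types report the same cleavage coordinate: a cleavage between
positions p and p+1 is indexed at p. In the cP library the last nucleotide of
a fragment lies immediately upstream of the cleavage site, so a fragment
(start, end) increments position ``end``; in the OH library the first
nucleotide lies immediately downstream, so a fragment increments
``start - 1``. An OH fragment starting at position 1 carries the native
transcript 5' end, not a cleavage, and is skipped with a warning.

Raw counts are normalized per transcript by the mean of the 90th–98th
percentile band of the counts (the top 2% are treated as outliers and
excluded), then capped at 7. Positions inside a library's blind end — the
first 11 nt for cP, the last 12 nt for OH, a consequence of the 12-nt
minimum mappable fragment length — are masked to NaN.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np

from .types import (
    CP_BLIND_5P,
    LIB_CP,
    LIB_OH,
    OH_BLIND_3P,
    CoverageReport,
    FragmentRecord,
    NormalizedTrack,
    RawCountTrack,
    TranscriptRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_CAP = 7.0
DEFAULT_MIN_FRACTION = 0.75
DEFAULT_MIN_MEAN = 2.5


def count_cleavage(
    fragments: Iterable[FragmentRecord],
    transcript: TranscriptRecord,
    library: str,
    replicate: str,
) -> RawCountTrack:
    """Tally cleavage events per position for one transcript/library/replicate.

    Fragments for other transcripts, libraries or replicates are ignored, so
    an unfiltered fragment list may be passed directly.
    """
    counts = np.zeros(transcript.length, dtype=int)
    n_skipped = 0
    for frag in fragments:
        if (
            frag.transcript_id != transcript.id
            or frag.library != library
            or frag.replicate != replicate
        ):
            continue
        if frag.end > transcript.length:
            raise ValueError(
                f"fragment {frag} extends beyond transcript {transcript.id!r} "
                f"(length {transcript.length})"
            )
        if library == LIB_CP:
            counts[frag.end - 1] += 1
        else:  # OH: cleavage site is start - 1
            if frag.start == 1:
                n_skipped += 1
                continue
            counts[frag.start - 2] += 1
    if n_skipped:
        logger.warning(
            "%s/%s/%s: skipped %d OH fragment(s) starting at position 1 "
            "(transcript 5' end is not a cleavage site)",
            transcript.id, library, replicate, n_skipped,
        )
    return RawCountTrack(transcript.id, library, replicate, counts)


def blind_end_mask(transcript_length: int, library: str) -> set[int]:
    """Positions (1-based) where the given library carries no mappable signal.

    cP fragments shorter than the mapping floor are lost, blinding the first
    11 positions; OH fragments blind the last 12.
    """
    if library == LIB_CP:
        masked = set(range(1, CP_BLIND_5P + 1))
    elif library == LIB_OH:
        masked = set(range(max(1, transcript_length - OH_BLIND_3P + 1), transcript_length + 1))
    else:
        raise ValueError(f"unknown library {library!r}")
    if transcript_length < 2 * len(masked):
        logger.warning(
            "transcript of length %d: blind end leaves <50%% of the %s track informative",
            transcript_length, library,
        )
    return masked


def coverage_filter(
    track: RawCountTrack,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_mean: float = DEFAULT_MIN_MEAN,
) -> CoverageReport:
    """Check the two coverage criteria for detailed structural analysis:
    at least ``min_fraction`` of positions carry reads, and the mean number of
    read starts per position is at least ``min_mean``.
    """
    length = track.length
    fraction = float(np.count_nonzero(track.counts)) / length
    mean = float(track.counts.sum()) / length
    return CoverageReport(
        track.transcript_id,
        fraction,
        mean,
        bool(fraction >= min_fraction and mean >= min_mean),
    )


def percentile_normalizer(counts: np.ndarray) -> float:
    """Mean of the 90th–98th percentile band of the counts.

    The largest ``ceil(0.02 L)`` values are discarded as outliers and the next
    ``max(1, round(0.08 L))`` values from the top are averaged, in the style of
    outlier-trimmed probing-signal normalization.
    """
    length = len(counts)
    ordered = np.sort(counts)[::-1]
    n_drop = math.ceil(0.02 * length)
    n_band = max(1, round(0.08 * length))
    band = ordered[n_drop : n_drop + n_band]
    if len(band) == 0:
        raise ValueError("transcript too short to form a percentile band")
    return float(band.mean())


def normalize(
    track: RawCountTrack,
    cap: float = DEFAULT_CAP,
    covered_only: bool = False,
) -> NormalizedTrack:
    """Normalize a raw count track to the signal S_i in [0, cap].

    ``covered_only`` restricts the percentile band to positions with nonzero
    counts (default is all positions). Blind-end positions of the track's
    library are masked to NaN after scaling.
    """
    counts = track.counts
    basis = counts[counts > 0] if covered_only else counts
    if len(basis) == 0:
        raise ValueError(f"{track.transcript_id}: no covered positions to normalize")
    normalizer = percentile_normalizer(basis)
    if normalizer == 0:
        raise ValueError(f"{track.transcript_id}: transcript too sparse to normalize")
    values = np.minimum(counts / normalizer, cap).astype(float)
    for pos in blind_end_mask(track.length, track.library):
        values[pos - 1] = np.nan
    return NormalizedTrack(track.transcript_id, track.library, values, normalizer, track.replicate)


def replicate_mean(tracks: Sequence[NormalizedTrack], strict: bool = False) -> NormalizedTrack:
    """Position-wise mean of replicate tracks.

    By default a position is averaged over the replicates where it is defined;
    NaN results only where every replicate is NaN. With ``strict=True`` any
    NaN replicate propagates.
    """
    if not tracks:
        raise ValueError("replicate_mean requires at least one track")
    tid, lib = tracks[0].transcript_id, tracks[0].library
    for tr in tracks[1:]:
        if tr.transcript_id != tid or tr.library != lib:
            raise ValueError("replicate tracks must share transcript and library")
        if tr.length != tracks[0].length:
            raise ValueError("replicate tracks must share length")
    stacked = np.vstack([tr.values for tr in tracks])
    if strict:
        mean = stacked.mean(axis=0)
    else:
        import warnings

        with warnings.catch_warnings():
            # all-NaN columns (e.g. blind ends) are legitimately NaN
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            mean = np.nanmean(stacked, axis=0)
    normalizer = float(np.mean([tr.normalizer for tr in tracks]))
    return NormalizedTrack(tid, lib, mean, normalizer, replicate=None)
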