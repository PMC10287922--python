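"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* FASTA — transcript sequences (T normalized to U, uppercased).
* Dot-bracket text — reference/predicted structures, three lines per record:
  an ``>id`` line, the sequence line, the structure line.
* Fragment TSV — one mapped cleavage fragment per line, tab-separated columns
  ``transcript_id  start  end  library  replicate`` with 1-based inclusive
  coordinates and library in {cP, OH}.
* Track TSV — per-position tables (counts, normalized signal, probabilities,
  pseudo-energies) with a single header line; masked values written as "NA".

A small utility projects genome-space fragment alignments onto single-interval
(unspliced) transcript annotations, which is all a bacterial transcriptome
needs; spliced projection is out of scope.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    LIBRARIES,
    FragmentRecord,
    NormalizedTrack,
    RawCountTrack,
    ReferenceStructure,
    TranscriptRecord,
    UnpairedProfile,
    pairs_from_dotbracket,
)

NA = "NA"
_FLOAT_FMT = "{:.6g}"


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path) -> list[TranscriptRecord]:
    """Read transcript sequences from a FASTA file.

    Sequences are uppercased with T normalized to U. The record id is the
    first whitespace-delimited token of the header. Duplicate ids and empty
    sequences raise ``ValueError``.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    current_id: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = _normalize_rna("".join(chunks))
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {current_id!r}")
        if current_id in seen:
            raise ValueError(f"duplicate FASTA id {current_id!r}")
        seen.add(current_id)
        records.append(TranscriptRecord(current_id, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise ValueError("FASTA header with no id")
                chunks = []
            else:
                if current_id is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line.strip())
        flush()
    return records


def write_fasta(path, transcripts: Iterable[TranscriptRecord]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n{t.sequence}\n")


def read_dotbracket(path) -> list[ReferenceStructure]:
    """Read dot-bracket records (``>id`` / sequence / structure line triples).

    The sequence line may be omitted (two-line records are accepted when the
    second line is already a structure). Structure and sequence lengths must
    agree; unbalanced parentheses raise with the offending position.
    """
    structures: list[ReferenceStructure] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"expected '>' header, got {header!r}")
        tid = header[1:].split()[0]
        i += 1
        if i >= len(lines):
            raise ValueError(f"truncated record {tid!r}")
        body = lines[i]
        i += 1
        if set(body) <= set("().") and body:
            seq, struct = None, body
        else:
            seq = body
            if i >= len(lines):
                raise ValueError(f"missing structure line for {tid!r}")
            struct = lines[i]
            i += 1
        if seq is not None and len(seq) != len(struct):
            raise ValueError(
                f"{tid!r}: sequence length {len(seq)} != structure length {len(struct)}"
            )
        try:
            pairs = pairs_from_dotbracket(struct)
        except ValueError as exc:
            raise ValueError(f"{tid!r}: {exc}") from exc
        structures.append(ReferenceStructure(tid, struct, pairs))
    return structures


def write_dotbracket(path, records: Sequence[tuple]) -> None:
    """Write (id, sequence, dotbracket) triples; sequence may be None."""
    with open(path, "w") as fh:
        for rec in records:
            tid, seq, db = rec
            fh.write(f">{tid}\n")
            if seq is not None:
                fh.write(f"{seq}\n")
            fh.write(f"{db}\n")


FRAGMENT_COLUMNS = ["transcript_id", "start", "end", "library", "replicate"]


def read_fragments(
    path, transcripts: Optional[Sequence[TranscriptRecord]] = None
) -> list[FragmentRecord]:
    """Read fragment records from a tab-separated file.

    Columns: transcript_id, start, end, library, replicate (1-based inclusive
    coordinates). When ``transcripts`` is supplied, coordinates are validated
    against transcript lengths and unknown transcript ids raise.
    """
    lengths = {t.id: t.length for t in transcripts} if transcripts else None
    fragments: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:5] == FRAGMENT_COLUMNS:
                continue  # tolerated header
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: expected 5 columns, got {len(fields)}")
            tid, start_s, end_s, lib, rep = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            frag = FragmentRecord(tid, start, end, lib, rep)  # validates bounds/library
            if lengths is not None:
                if tid not in lengths:
                    raise ValueError(f"line {lineno}: unknown transcript {tid!r}")
                if end > lengths[tid]:
                    raise ValueError(
                        f"line {lineno}: end {end} exceeds length of {tid!r} "
                        f"({lengths[tid]})"
                    )
            fragments.append(frag)
    return fragments


def write_fragments(path, fragments: Iterable[FragmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FRAGMENT_COLUMNS) + "\n")
        for f in fragments:
            fh.write(f"{f.transcript_id}\t{f.start}\t{f.end}\t{f.library}\t{f.replicate}\n")


def _fmt(value: float) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return NA
    return _FLOAT_FMT.format(value)


def write_count_tracks(path, tracks: Sequence[RawCountTrack], sequences=None) -> None:
    """Write raw count tracks as TSV: transcript_id, pos, nt, library, replicate, count."""
    seqmap = {t.id: t.sequence for t in sequences} if sequences else {}
    with open(path, "w") as fh:
        fh.write("transcript_id\tpos\tnt\tlibrary\treplicate\tcount\n")
        for tr in tracks:
            seq = seqmap.get(tr.transcript_id)
            for pos in range(1, tr.length + 1):
                nt = seq[pos - 1] if seq else NA
                fh.write(
                    f"{tr.transcript_id}\t{pos}\t{nt}\t{tr.library}\t"
                    f"{tr.replicate}\t{int(tr.counts[pos - 1])}\n"
                )


def read_count_tracks(path) -> list[RawCountTrack]:
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for (tid, lib, rep), grp in df.groupby(
        ["transcript_id", "library", "replicate"], sort=False
    ):
        grp = grp.sort_values("pos")
        length = int(grp["pos"].max())
        counts = np.zeros(length, dtype=int)
        counts[grp["pos"].to_numpy() - 1] = grp["count"].to_numpy()
        tracks.append(RawCountTrack(str(tid), str(lib), str(rep), counts))
    return tracks


def write_normalized_tracks(path, tracks: Sequence[NormalizedTrack]) -> None:
    """TSV: transcript_id, pos, library, replicate, signal, normalizer."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tpos\tlibrary\treplicate\tsignal\tnormalizer\n")
        for tr in tracks:
            rep = tr.replicate if tr.replicate is not None else NA
            norm = _fmt(tr.normalizer)
            for pos in range(1, tr.length + 1):
                fh.write(
                    f"{tr.transcript_id}\t{pos}\t{tr.library}\t{rep}\t"
                    f"{_fmt(float(tr.values[pos - 1]))}\t{norm}\n"
                )


def read_normalized_tracks(path) -> list[NormalizedTrack]:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    tracks = []
    for (tid, lib, rep), grp in df.groupby(
        ["transcript_id", "library", "replicate"], sort=False, dropna=False
    ):
        grp = grp.sort_values("pos")
        length = int(grp["pos"].max())
        values = np.full(length, np.nan)
        values[grp["pos"].to_numpy() - 1] = grp["signal"].to_numpy(dtype=float)
        normalizer = float(grp["normalizer"].iloc[0])
        rep_out = None if (isinstance(rep, float) and math.isnan(rep)) else str(rep)
        tracks.append(NormalizedTrack(str(tid), str(lib), values, normalizer, rep_out))
    return tracks


def write_unpaired_profiles(path, profiles: Sequence[UnpairedProfile]) -> None:
    """TSV: transcript_id, pos, q, source."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tpos\tq\tsource\n")
        for pr in profiles:
            for pos in range(1, pr.length + 1):
                fh.write(
                    f"{pr.transcript_id}\t{pos}\t{_fmt(float(pr.q[pos - 1]))}\t"
                    f"{pr.source[pos - 1]}\n"
                )


def read_unpaired_profiles(path) -> list[UnpairedProfile]:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    profiles = []
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("pos")
        length = int(grp["pos"].max())
        q = np.full(length, np.nan)
        q[grp["pos"].to_numpy() - 1] = grp["q"].to_numpy(dtype=float)
        source = np.full(length, "none", dtype=object)
        source[grp["pos"].to_numpy() - 1] = grp["source"].to_numpy()
        profiles.append(UnpairedProfile(str(tid), q, source))
    return profiles


def write_pseudo_energies(path, transcript_id: str, dg: np.ndarray) -> None:
    """TSV of applied pseudo-energies: transcript_id, pos, dG_kcal_mol."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tpos\tdG_kcal_mol\n")
        for pos in range(1, len(dg) + 1):
            fh.write(f"{transcript_id}\t{pos}\t{_fmt(float(dg[pos - 1]))}\n")


# ---------------------------------------------------------------------------
# Genome-space projection utility (single-interval transcripts)
# ---------------------------------------------------------------------------

def project_genomic_fragments(
    intervals: Iterable[tuple],
    annotation: pd.DataFrame,
    library: str,
    replicate: str,
) -> list[FragmentRecord]:
    """Project genome-space read-pair extents onto transcript coordinates.

    ``intervals`` are (chrom, start, end, strand) with 1-based inclusive
    genomic coordinates. ``annotation`` is a DataFrame with columns
    transcript_id, chrom, start, end, strand describing unspliced transcripts.
    Only read pairs fully contained in a single annotated transcript on the
    annotated strand are kept; minus-strand transcripts flip the coordinates.
    """
    if library not in LIBRARIES:
        raise ValueError(f"unknown library {library!r}")
    fragments = []
    ann = annotation.reset_index(drop=True)
    for chrom, gstart, gend, strand in intervals:
        hit = ann[
            (ann["chrom"] == chrom)
            & (ann["strand"] == strand)
            & (ann["start"] <= gstart)
            & (ann["end"] >= gend)
        ]
        if len(hit) != 1:
            continue  # unassigned or ambiguous
        row = hit.iloc[0]
        if strand == "+":
            tstart = gstart - row["start"] + 1
            tend = gend - row["start"] + 1
        else:
            tstart = row["end"] - gend + 1
            tend = row["end"] - gstart + 1
        fragments.append(
            FragmentRecord(str(row["transcript_id"]), int(tstart), int(tend), library, replicate)
        )
    return fragments
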