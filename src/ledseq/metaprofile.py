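"""Start-codon-aligned metaprofiles of mRNA cleavage signal.

Eligible mRNAs (a 50-nt window upstream of the AUG free of other annotated
genes, and sufficient read coverage) are aligned at the start codon and the
normalized signal is averaged per meta-position. The meta-coordinate runs
from -48 to 180 with no position 0; position 1 is the A of the AUG. Region
means (5'-UTR -48..-1, CDS 1-60, CDS 61-180) are compared with two-sided
Welch t-tests, and codon-position (frame) means quantify the periodicity of
the signal inside coding sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CoverageReport, NormalizedTrack

UPSTREAM_WINDOW = 50
META_MIN, META_MAX = -48, 180

#: Meta-coordinate axis (no position 0).
META_POSITIONS = tuple(m for m in range(META_MIN, META_MAX + 1) if m != 0)


@dataclass
class MetaProfile:
    """Aligned signal matrix: one row per mRNA, one column per meta-position."""

    library: str
    positions: tuple  # meta coordinates
    values: np.ndarray  # (n_transcripts, n_positions), NaN where undefined
    transcript_ids: list

    @property
    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    @property
    def n_transcripts(self) -> np.ndarray:
        return np.isfinite(self.values).sum(axis=0)

    def position_index(self, meta_pos: int) -> int:
        return self.positions.index(meta_pos)


def select_mrnas(
    annotation: pd.DataFrame,
    coverage: Mapping[str, CoverageReport],
    upstream_window: int = UPSTREAM_WINDOW,
) -> list[str]:
    """Eligible mRNA ids: upstream window free of other genes, coverage OK.

    ``annotation`` columns: gene_id, start, end, strand, kind, cds_start
    (1-based genomic, + strand supported for meta-analysis). ``coverage``
    maps gene_id to the coverage report of the relevant library track.
    """
    eligible = []
    mrnas = annotation[annotation["kind"] == "mRNA"]
    for _, row in mrnas.iterrows():
        tid = row["gene_id"]
        if row["strand"] != "+":
            continue  # minus-strand meta-alignment not supported
        win_start = row["cds_start"] - upstream_window
        win_end = row["cds_start"] - 1
        others = annotation[annotation["gene_id"] != tid]
        overlaps = (
            (others["start"] <= win_end) & (others["end"] >= win_start)
        ).any()
        if overlaps:
            continue
        report = coverage.get(tid)
        if report is None or not report.passes:
            continue
        eligible.append(str(tid))
    return eligible


def build_profile(
    tracks: Mapping[str, NormalizedTrack],
    annotation: pd.DataFrame,
    eligible: Sequence[str],
    library: str,
) -> MetaProfile:
    """Align replicate-averaged tracks at the start codon.

    Per-transcript blind-end positions are already NaN in normalized tracks
    and are thereby excluded from every per-position mean.
    """
    if not eligible:
        raise ValueError("no eligible mRNAs to build a metaprofile from")
    ann = annotation.set_index("gene_id")
    n_pos = len(META_POSITIONS)
    values = np.full((len(eligible), n_pos), np.nan)
    kept_ids = []
    for r, tid in enumerate(eligible):
        track = tracks.get(tid)
        if track is None:
            continue
        row = ann.loc[tid]
        cds_tx = int(row["cds_start"]) - int(row["start"]) + 1  # transcript coords
        for c, m in enumerate(META_POSITIONS):
            pos = cds_tx + m - 1 if m >= 1 else cds_tx + m
            if 1 <= pos <= track.length:
                values[r, c] = track.values[pos - 1]
        kept_ids.append(tid)
    return MetaProfile(library, META_POSITIONS, values, list(eligible))


REGIONS = {
    "UTR": (META_MIN, -1),
    "CDS_1_60": (1, 60),
    "CDS_61_180": (61, 180),
}


def _region_columns(profile: MetaProfile, region: str) -> np.ndarray:
    lo, hi = REGIONS[region]
    return np.array([i for i, m in enumerate(profile.positions) if lo <= m <= hi])


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def region_stats(profile: MetaProfile, by_transcript: bool = False) -> dict:
    """Region means and two-sided Welch t-tests between region pairs.

    Default pools per-position profile means; ``by_transcript`` instead uses
    one mean per transcript per region (more conservative units).
    """
    samples = {}
    for region in REGIONS:
        cols = _region_columns(profile, region)
        if by_transcript:
            with np.errstate(invalid="ignore"):
                samples[region] = np.nanmean(profile.values[:, cols], axis=1)
        else:
            samples[region] = profile.mean[cols]
    out = {"means": {}, "tests": {}}
    for region, vals in samples.items():
        finite = vals[np.isfinite(vals)]
        out["means"][region] = float(finite.mean()) if len(finite) else float("nan")
    for pair in (("UTR", "CDS_1_60"), ("CDS_1_60", "CDS_61_180")):
        stat, pval = _welch(samples[pair[0]], samples[pair[1]])
        out["tests"][f"{pair[0]}_vs_{pair[1]}"] = {"statistic": stat, "pvalue": pval}
    return out


def codon_periodicity(profile: MetaProfile) -> dict:
    """Frame-resolved means inside the CDS and in a 5'-UTR pseudo-frame.

    CDS meta-positions 1..180 are grouped by codon position ((m-1) mod 3)+1;
    the UTR gets an arbitrary pseudo-frame as the no-periodicity control.
    Pairwise two-sided Welch t-tests compare frames on per-position means.
    """
    out = {}
    for region, frame_of in (
        ("CDS", lambda m: (m - 1) % 3 + 1),
        ("UTR", lambda m: (m - META_MIN) % 3 + 1),
    ):
        lo, hi = (1, META_MAX) if region == "CDS" else (META_MIN, -1)
        frames: dict[int, list[float]] = {1: [], 2: [], 3: []}
        mean = profile.mean
        for i, m in enumerate(profile.positions):
            if lo <= m <= hi and np.isfinite(mean[i]):
                frames[frame_of(m)].append(float(mean[i]))
        means = {f: (float(np.mean(v)) if v else float("nan")) for f, v in frames.items()}
        tests = {}
        for f1, f2 in ((1, 2), (2, 3), (1, 3)):
            stat, pval = _welch(np.array(frames[f1]), np.array(frames[f2]))
            tests[f"{f1}_vs_{f2}"] = {"statistic": stat, "pvalue": pval}
        out[region] = {"frame_means": means, "tests": tests}
    return out


def write_profile(path, profile: MetaProfile, stats_out: Optional[dict] = None) -> None:
    """TSV: meta_pos, mean_signal, n_transcripts (means to 6 significant digits)."""
    mean, n = profile.mean, profile.n_transcripts
    with open(path, "w") as fh:
        fh.write("meta_pos\tmean_signal\tn_transcripts\n")
        for i, m in enumerate(profile.positions):
            val = "NA" if math.isnan(mean[i]) else f"{mean[i]:.6g}"
            fh.write(f"{m}\t{val}\t{int(n[i])}\n")
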