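"""End-to-end pipeline glue: fragments -> counts -> signal -> q -> folds.

These helpers chain the per-module operations for whole datasets and carry
the benchmark evaluation used to quantify how much the probing signal
improves MFE structure prediction.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from . import cleavage_signal as cs
from .calibration import (
    CalibrationModelSet,
    assemble_calibration_table,
    fit_calibration,
    predict_unpaired,
)
from .folding_constraints import (
    PseudoEnergyConfig,
    fold_with_constraints,
    select_constraints,
)
from .structure_eval import aggregate, compare_dotbrackets
from .types import (
    LIBRARIES,
    LIB_CP,
    LIB_OH,
    FragmentRecord,
    NormalizedTrack,
    TranscriptRecord,
)

CONDITIONS = ("none", "cP", "OH", "both")


def count_all(
    fragments: Sequence[FragmentRecord],
    transcripts: Sequence[TranscriptRecord],
    replicates: Sequence[str],
) -> dict:
    """RawCountTrack per (transcript, library, replicate)."""
    by_key: dict[tuple, list] = {}
    for frag in fragments:
        by_key.setdefault(
            (frag.transcript_id, frag.library, frag.replicate), []
        ).append(frag)
    tracks = {}
    for t in transcripts:
        for lib in LIBRARIES:
            for rep in replicates:
                tracks[(t.id, lib, rep)] = cs.count_cleavage(
                    by_key.get((t.id, lib, rep), []), t, lib, rep
                )
    return tracks


def normalize_and_average(
    count_tracks: Mapping[tuple, object],
    cap: float = cs.DEFAULT_CAP,
) -> tuple[dict, dict]:
    """Normalize each replicate track and average replicates.

    Returns (per_replicate, averaged): per_replicate keyed by
    (tid, lib, rep), averaged by (tid, lib). Tracks that cannot be
    normalized (all-zero) are dropped.
    """
    per_replicate: dict = {}
    grouped: dict[tuple, list] = {}
    for (tid, lib, rep), track in count_tracks.items():
        try:
            norm = cs.normalize(track, cap=cap)
        except ValueError:
            continue
        per_replicate[(tid, lib, rep)] = norm
        grouped.setdefault((tid, lib), []).append(norm)
    averaged = {
        key: cs.replicate_mean(tracks) for key, tracks in grouped.items()
    }
    return per_replicate, averaged


def coverage_reports(
    count_tracks: Mapping[tuple, object],
    min_fraction: float = cs.DEFAULT_MIN_FRACTION,
    min_mean: float = cs.DEFAULT_MIN_MEAN,
) -> dict:
    """Per (transcript, library): True iff every replicate passes coverage."""
    verdict: dict[tuple, bool] = {}
    reports: dict[tuple, list] = {}
    for (tid, lib, _rep), track in count_tracks.items():
        reports.setdefault((tid, lib), []).append(
            cs.coverage_filter(track, min_fraction, min_mean)
        )
    for key, reps in reports.items():
        verdict[key] = all(r.passes for r in reps)
    return verdict


def replicate_correlation(
    per_replicate: Mapping[tuple, NormalizedTrack], library: str
) -> float:
    """Pearson correlation of the two replicates' normalized signal, pooled
    over all transcripts (positions defined in both replicates)."""
    xs, ys = [], []
    tids = sorted({tid for (tid, lib, _r) in per_replicate if lib == library})
    for tid in tids:
        reps = sorted(
            r for (t, lib, r) in per_replicate if t == tid and lib == library
        )
        if len(reps) < 2:
            continue
        v1 = per_replicate[(tid, library, reps[0])].values
        v2 = per_replicate[(tid, library, reps[1])].values
        ok = np.isfinite(v1) & np.isfinite(v2)
        xs.append(v1[ok])
        ys.append(v2[ok])
    if not xs:
        return float("nan")
    x, y = np.concatenate(xs), np.concatenate(ys)
    if len(x) < 2:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def calibrate_dataset(
    averaged: Mapping[tuple, NormalizedTrack],
    structures,
    transcripts,
    **fit_kwargs,
) -> CalibrationModelSet:
    cp_tracks = [tr for (tid, lib), tr in averaged.items() if lib == LIB_CP]
    oh_tracks = [tr for (tid, lib), tr in averaged.items() if lib == LIB_OH]
    table = assemble_calibration_table(cp_tracks, oh_tracks, structures, transcripts)
    return fit_calibration(table, **fit_kwargs)


def _blank_track(template: NormalizedTrack) -> NormalizedTrack:
    return NormalizedTrack(
        template.transcript_id,
        template.library,
        np.full(template.length, np.nan),
        template.normalizer,
    )


def predict_and_fold(
    transcript: TranscriptRecord,
    cp_track: Optional[NormalizedTrack],
    oh_track: Optional[NormalizedTrack],
    models: CalibrationModelSet,
    condition: str,
    config: Optional[PseudoEnergyConfig] = None,
    engine: str = "vienna",
) -> dict:
    """Fold one transcript under a constraint condition.

    Conditions: "none" (unconstrained), "cP" / "OH" (single-library signal),
    "both" (2D fusion in the interior, 1D at the blind ends).
    """
    if config is None:
        config = PseudoEnergyConfig(p0=models.p0)
    if condition == "none":
        return fold_with_constraints(
            transcript.sequence, None, engine, config.temperature_K
        )
    template = cp_track if cp_track is not None else oh_track
    if template is None:
        raise ValueError(f"{transcript.id}: no signal tracks available")
    use_cp = cp_track if condition in ("cP", "both") and cp_track is not None else _blank_track(template)
    use_oh = oh_track if condition in ("OH", "both") and oh_track is not None else _blank_track(template)
    profile = predict_unpaired(models, use_cp, use_oh, transcript)
    pe = select_constraints(profile, config)
    result = fold_with_constraints(transcript.sequence, pe, engine, config.temperature_K)
    result["profile"] = profile
    result["pseudo_energies"] = pe
    return result


def benchmark_evaluation(
    transcripts: Sequence[TranscriptRecord],
    structures,
    averaged: Mapping[tuple, NormalizedTrack],
    models: CalibrationModelSet,
    conditions: Sequence[str] = CONDITIONS,
    config: Optional[PseudoEnergyConfig] = None,
    engine: str = "vienna",
) -> dict:
    """Fold every transcript under every condition and score against the
    references. Returns {condition: {"per_transcript": [...], "summary": {...}}}."""
    struct_by_tid = {s.transcript_id: s for s in structures}
    results: dict = {}
    for condition in conditions:
        metrics = []
        for t in transcripts:
            cp = averaged.get((t.id, LIB_CP))
            oh = averaged.get((t.id, LIB_OH))
            fold = predict_and_fold(t, cp, oh, models, condition, config, engine)
            ref = struct_by_tid[t.id]
            metrics.append(
                compare_dotbrackets(fold["structure"], ref.dotbracket, t.id)
            )
        results[condition] = {
            "per_transcript": metrics,
            "summary": aggregate(metrics),
        }
    return results
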