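"""Calibration of normalized cleavage signal to unpaired probability.

The probability that a position is unpaired given its signal is estimated
empirically on a calibration set with known reference structures: positions
are pooled into signal bins and the fraction of unpaired positions per bin,
n_u / n, estimates p(S) (one library) or p(S_cP, S_OH) (both libraries).
To smooth reference-structure inaccuracies and sampling noise, sigmoids

    p(S)            = 1 / (1 + exp(-a*S + b)) + c
    p(S_cP, S_OH)   = 1 / (1 + exp(-a1*S_cP - a2*S_OH + b)) + c

are fitted to the binned estimates by nonlinear least squares. Cleavage
sites in CA dinucleotides behave differently from all others (a strong
library bias uncorrelated with structure), so CA and non-CA sites get
separate fits throughout. Predicted probabilities are clipped to [0, 1].

At transcript ends, where one library is blind, the corresponding 1D model
supplies q; in the interior the 2D fusion of both libraries is used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .types import (
    LIB_CP,
    LIB_OH,
    NormalizedTrack,
    ReferenceStructure,
    TranscriptRecord,
    UnpairedProfile,
)

logger = logging.getLogger(__name__)

#: Default 1D bin edges; denser near 0 where most of the signal mass lies.
DEFAULT_EDGES_1D = (0.0, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5, 2.5, 4.0, 7.0)
#: Coarser edges whose Cartesian product forms the 2D grid.
DEFAULT_EDGES_2D = (0.0, 0.1, 0.4, 1.0, 2.5, 7.0)
DEFAULT_MIN_BIN_COUNT = 20

CLASS_CA = "CA"
CLASS_OTHER = "other"
SITE_CLASSES = (CLASS_CA, CLASS_OTHER)


class CalibrationError(RuntimeError):
    pass


def classify_site(sequence: str, i: int) -> str:
    """Class of the cleavage site between positions i and i+1 (1-based).

    Returns "CA" iff sequence[i] == C and sequence[i+1] == A. The transcript
    3' end (i == L) is not a cleavage site and raises.
    """
    length = len(sequence)
    if not 1 <= i <= length - 1:
        raise ValueError(f"cleavage site index {i} out of range 1..{length - 1}")
    return CLASS_CA if sequence[i - 1] == "C" and sequence[i] == "A" else CLASS_OTHER


def site_classes(sequence: str) -> np.ndarray:
    """Vector of site classes for positions 1..L; position L (no downstream
    nucleotide) defaults to "other"."""
    length = len(sequence)
    classes = np.full(length, CLASS_OTHER, dtype=object)
    for i in range(1, length):
        if sequence[i - 1] == "C" and sequence[i] == "A":
            classes[i - 1] = CLASS_CA
    return classes


@dataclass(frozen=True)
class CalibrationBin:
    """One signal bin: empirical unpaired fraction p_hat = n_u / n.

    ``center`` is the mean signal of member positions — a scalar for 1D bins,
    an (S_cP, S_OH) pair for 2D cells. p_hat is NaN when n < min_bin_count.
    """

    center: tuple
    n_u: int
    n: int
    p_hat: float


@dataclass
class SigmoidModel:
    """A fitted sigmoid p(S) or p(S_cP, S_OH) for one site class.

    params: (a, b, c) for kind "oneD"; (a1, a2, b, c) for kind "twoD".
    """

    kind: str  # "oneD" | "twoD"
    site_class: str
    library: Optional[str]  # cP / OH for oneD, None for twoD
    params: tuple
    rss: float = float("nan")
    n_bins: int = 0

    def predict(self, s1, s2=None) -> np.ndarray:
        s1 = np.asarray(s1, dtype=float)
        if self.kind == "oneD":
            a, b, c = self.params
            z = -a * s1 + b
        else:
            if s2 is None:
                raise ValueError("twoD model needs both signals")
            a1, a2, b, c = self.params
            z = -a1 * s1 - a2 * np.asarray(s2, dtype=float) + b
        p = 1.0 / (1.0 + np.exp(z)) + c
        return np.clip(p, 0.0, 1.0)


def _sigmoid_1d(s, a, b, c):
    return 1.0 / (1.0 + np.exp(-a * s + b)) + c


def _sigmoid_2d(x, a1, a2, b, c):
    return 1.0 / (1.0 + np.exp(-a1 * x[0] - a2 * x[1] + b)) + c


def assemble_calibration_table(
    cp_tracks: Sequence[NormalizedTrack],
    oh_tracks: Sequence[NormalizedTrack],
    structures: Sequence[ReferenceStructure],
    transcripts: Sequence[TranscriptRecord],
) -> pd.DataFrame:
    """Join signals, pairing labels and site classes into one long table.

    One row per transcript position, with columns transcript_id, pos, S_cP,
    S_OH, unpaired, site_class. Tracks should be replicate-averaged.
    """
    seqs = {t.id: t.sequence for t in transcripts}
    structs = {s.transcript_id: s for s in structures}
    cp_by_tid = {t.transcript_id: t for t in cp_tracks}
    oh_by_tid = {t.transcript_id: t for t in oh_tracks}
    rows = []
    for tid in sorted(set(cp_by_tid) | set(oh_by_tid)):
        if tid not in structs or tid not in seqs:
            raise CalibrationError(f"missing structure or sequence for {tid!r}")
        struct, seq = structs[tid], seqs[tid]
        length = len(seq)
        if struct.length != length:
            raise CalibrationError(f"{tid!r}: structure/sequence length mismatch")
        unpaired = struct.unpaired_mask()
        classes = site_classes(seq)
        s_cp = cp_by_tid[tid].values if tid in cp_by_tid else np.full(length, np.nan)
        s_oh = oh_by_tid[tid].values if tid in oh_by_tid else np.full(length, np.nan)
        for pos in range(1, length + 1):
            rows.append(
                (tid, pos, s_cp[pos - 1], s_oh[pos - 1], bool(unpaired[pos - 1]),
                 classes[pos - 1])
            )
    return pd.DataFrame(
        rows, columns=["transcript_id", "pos", "S_cP", "S_OH", "unpaired", "site_class"]
    )


def _bin_index(values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def bin_signals(
    values: np.ndarray,
    labels: np.ndarray,
    edges: Sequence[float] = DEFAULT_EDGES_1D,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
) -> list[CalibrationBin]:
    """Pool (signal, unpaired) observations into 1D bins.

    NaN signals are excluded. Returns one bin per non-empty interval; p_hat is
    NaN for bins with fewer than ``min_bin_count`` members (those bins are
    excluded from fitting but retained for bookkeeping).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    idx = _bin_index(values, edges)
    bins = []
    for b in range(len(edges) - 1):
        members = idx == b
        n = int(members.sum())
        if n == 0:
            continue
        n_u = int(labels[members].sum())
        p_hat = n_u / n if n >= min_bin_count else float("nan")
        bins.append(CalibrationBin((float(values[members].mean()),), n_u, n, p_hat))
    return bins


def bin_signals_2d(
    values_cp: np.ndarray,
    values_oh: np.ndarray,
    labels: np.ndarray,
    edges: Sequence[float] = DEFAULT_EDGES_2D,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
) -> list[CalibrationBin]:
    """Pool observations into the Cartesian grid of 2D signal cells."""
    v1 = np.asarray(values_cp, dtype=float)
    v2 = np.asarray(values_oh, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = np.isfinite(v1) & np.isfinite(v2)
    v1, v2, labels = v1[ok], v2[ok], labels[ok]
    i1, i2 = _bin_index(v1, edges), _bin_index(v2, edges)
    nb = len(edges) - 1
    bins = []
    for b1 in range(nb):
        for b2 in range(nb):
            members = (i1 == b1) & (i2 == b2)
            n = int(members.sum())
            if n == 0:
                continue
            n_u = int(labels[members].sum())
            p_hat = n_u / n if n >= min_bin_count else float("nan")
            bins.append(
                CalibrationBin(
                    (float(v1[members].mean()), float(v2[members].mean())), n_u, n, p_hat
                )
            )
    return bins


def fit_sigmoid(
    bins: Sequence[CalibrationBin],
    kind: str,
    site_class: str = CLASS_OTHER,
    library: Optional[str] = None,
    weight_by_n: bool = False,
    initial: Optional[Sequence[float]] = None,
) -> SigmoidModel:
    """Least-squares sigmoid fit to binned unpaired fractions.

    Requires >= 4 usable (p_hat defined) bins for 1D fits and >= 6 for 2D.
    Fits are unweighted by default; ``weight_by_n`` weights each bin by the
    inverse square root of its member count.
    """
    usable = [b for b in bins if np.isfinite(b.p_hat)]
    min_needed = 4 if kind == "oneD" else 6
    if len(usable) < min_needed:
        raise CalibrationError(
            f"insufficient calibration data: {len(usable)} usable bins "
            f"(need >= {min_needed} for {kind})"
        )
    y = np.array([b.p_hat for b in usable])
    sigma = None
    if weight_by_n:
        sigma = 1.0 / np.sqrt(np.array([b.n for b in usable], dtype=float))
    # Slopes are bounded below by 0: more cleavage can only make a position
    # more likely to be unpaired, and unconstrained fits on sparse/collinear
    # bin grids can otherwise chase sign-flipped degenerate optima.
    if kind == "oneD":
        x = np.array([b.center[0] for b in usable])
        p_init = list(initial) if initial is not None else [1.0, 1.0, 0.1]
        func = _sigmoid_1d
        bounds = ([0.0, -50.0, -1.0], [100.0, 50.0, 1.0])
    elif kind == "twoD":
        x = np.array([[b.center[0] for b in usable], [b.center[1] for b in usable]])
        p_init = list(initial) if initial is not None else [1.0, 1.0, 1.0, 0.1]
        func = _sigmoid_2d
        bounds = ([0.0, 0.0, -50.0, -1.0], [100.0, 100.0, 50.0, 1.0])
    else:
        raise ValueError(f"unknown kind {kind!r}")
    try:
        popt, _ = curve_fit(
            func, x, y, p0=p_init, sigma=sigma, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise CalibrationError(
            f"sigmoid fit did not converge ({kind}, class {site_class}): {exc}"
        ) from exc
    resid = y - func(x, *popt)
    return SigmoidModel(
        kind, site_class, library, tuple(float(p) for p in popt),
        rss=float((resid**2).sum()), n_bins=len(usable),
    )


@dataclass
class CalibrationModelSet:
    """All fitted models (2 classes x {cP 1D, OH 1D, 2D}) plus the prior p0."""

    models: dict = field(default_factory=dict)  # (kind, library, site_class) -> SigmoidModel
    p0: float = float("nan")

    def get(self, kind: str, library: Optional[str], site_class: str) -> SigmoidModel:
        key = (kind, library, site_class)
        if key in self.models:
            return self.models[key]
        # Fall back to the pooled non-CA model when a class-specific fit was
        # impossible (small calibration sets may lack enough CA sites).
        alt = (kind, library, CLASS_OTHER)
        if alt in self.models:
            return self.models[alt]
        raise CalibrationError(f"no calibrated model for {key}")

    def has(self, kind: str, library: Optional[str], site_class: str) -> bool:
        return (kind, library, site_class) in self.models

    def to_json(self, path=None) -> str:
        payload = {
            "p0": self.p0,
            "models": [
                {
                    "kind": m.kind,
                    "library": m.library,
                    "site_class": m.site_class,
                    "params": list(m.params),
                    "rss": m.rss,
                    "n_bins": m.n_bins,
                }
                for m in self.models.values()
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CalibrationModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        models = {}
        for m in payload["models"]:
            model = SigmoidModel(
                m["kind"], m["site_class"], m["library"], tuple(m["params"]),
                rss=m.get("rss", float("nan")), n_bins=m.get("n_bins", 0),
            )
            models[(model.kind, model.library, model.site_class)] = model
        return cls(models=models, p0=float(payload["p0"]))


def prior_unpaired(table: pd.DataFrame) -> float:
    """Overall unpaired fraction p0 of the calibration set, over positions
    with at least one defined signal."""
    informative = table[np.isfinite(table["S_cP"]) | np.isfinite(table["S_OH"])]
    if len(informative) == 0:
        raise CalibrationError("no informative positions in calibration set")
    return float(informative["unpaired"].mean())


def fit_calibration(
    table: pd.DataFrame,
    edges_1d: Sequence[float] = DEFAULT_EDGES_1D,
    edges_2d: Sequence[float] = DEFAULT_EDGES_2D,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
    weight_by_n: bool = False,
) -> CalibrationModelSet:
    """Fit all six models from an assembled calibration table.

    Class-specific fits that fail for lack of data are logged and omitted;
    prediction then falls back to the pooled non-CA model of the same kind.
    """
    model_set = CalibrationModelSet(p0=prior_unpaired(table))
    for site_class in SITE_CLASSES:
        sub = table[table["site_class"] == site_class]
        for library, col in ((LIB_CP, "S_cP"), (LIB_OH, "S_OH")):
            try:
                bins = bin_signals(sub[col].to_numpy(), sub["unpaired"].to_numpy(),
                                   edges_1d, min_bin_count)
                model = fit_sigmoid(bins, "oneD", site_class, library, weight_by_n)
                model_set.models[("oneD", library, site_class)] = model
            except CalibrationError as exc:
                if site_class == CLASS_OTHER:
                    raise
                logger.warning("skipping 1D %s/%s fit: %s", library, site_class, exc)
        try:
            bins2 = bin_signals_2d(
                sub["S_cP"].to_numpy(), sub["S_OH"].to_numpy(),
                sub["unpaired"].to_numpy(), edges_2d, min_bin_count,
            )
            model2 = fit_sigmoid(bins2, "twoD", site_class, None, weight_by_n)
            model_set.models[("twoD", None, site_class)] = model2
        except CalibrationError as exc:
            if site_class == CLASS_OTHER:
                raise
            logger.warning("skipping 2D %s fit: %s", site_class, exc)
    return model_set


SOURCE_2D = "twoD"
SOURCE_CP = "cP_only"
SOURCE_OH = "OH_only"
SOURCE_NONE = "none"


def predict_unpaired(
    models: CalibrationModelSet,
    cp_track: NormalizedTrack,
    oh_track: NormalizedTrack,
    transcript: TranscriptRecord,
) -> UnpairedProfile:
    """Per-position unpaired probability q_i with source provenance.

    Interior positions with both signals use the 2D fusion model; positions
    inside one library's blind end fall back to the other library's 1D model;
    positions with neither signal get q = NaN and source "none".

    CA sites carry a structure-unrelated capture bias in the cP library, so
    when no CA-specific 2D fit is available (sparse calibration sets), the
    biased cP signal is ignored at CA sites and the OH 1D model is used
    instead of misreading the bias through the non-CA fusion model.
    """
    length = transcript.length
    if cp_track.length != length or oh_track.length != length:
        raise ValueError("track/transcript length mismatch")
    classes = site_classes(transcript.sequence)
    q = np.full(length, np.nan)
    source = np.full(length, SOURCE_NONE, dtype=object)
    s_cp, s_oh = cp_track.values, oh_track.values
    for i in range(length):
        cls = classes[i]
        has_cp, has_oh = np.isfinite(s_cp[i]), np.isfinite(s_oh[i])
        if has_cp and has_oh and cls == CLASS_CA and not models.has("twoD", None, cls):
            has_cp = False  # drop the bias-affected cP signal at CA sites
        if has_cp and has_oh:
            model = models.get("twoD", None, cls)
            q[i] = model.predict(s_cp[i], s_oh[i])
            source[i] = SOURCE_2D
        elif has_oh:
            model = models.get("oneD", LIB_OH, cls)
            q[i] = model.predict(s_oh[i])
            source[i] = SOURCE_OH
        elif has_cp:
            model = models.get("oneD", LIB_CP, cls)
            q[i] = model.predict(s_cp[i])
            source[i] = SOURCE_CP
    return UnpairedProfile(transcript.id, q, source)


def randomization_control(
    values: np.ndarray,
    labels: np.ndarray,
    groups: Optional[np.ndarray] = None,
    edges: Sequence[float] = DEFAULT_EDGES_1D,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
    seed: int = 0,
) -> tuple[SigmoidModel, float]:
    """Shuffle pairing labels (within each transcript when ``groups`` is
    given), refit the 1D sigmoid, and return (model, flatness statistic).

    The flatness statistic is max - min of the predicted p over the observed
    signal range; a structure-free signal yields a flat response curve.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool).copy()
    if groups is None:
        rng.shuffle(labels)
    else:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            sel = np.flatnonzero(groups == g)
            labels[sel] = labels[sel[rng.permutation(len(sel))]]
    bins = bin_signals(values, labels, edges, min_bin_count)
    model = fit_sigmoid(bins, "oneD", site_class="shuffled")
    return model, flatness_statistic(model, values)


def flatness_statistic(model: SigmoidModel, values: np.ndarray) -> float:
    """Range (max - min) of predicted p over the observed finite signals."""
    finite = np.asarray(values, dtype=float)
    finite = finite[np.isfinite(finite)]
    if len(finite) == 0:
        return float("nan")
    grid = np.linspace(finite.min(), finite.max(), 256)
    pred = model.predict(grid)
    return float(pred.max() - pred.min())
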