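"""Synthetic dual-library cleavage data with known ground truth.

The generator is a test harness emulating the empirical contrasts of
double-end lead probing, not a mechanistic claim: cleavage events at the
internal sites of a transcript follow a Poisson model whose rate is higher
at unpaired positions, every event emits both cleavage products (a 5'
fragment ending at the site and a 3' fragment starting just after it), CA
dinucleotide sites carry an extra capture bias in the cP channel only, and
fragments shorter than the 12-nt mapping floor are censored — which creates
the 11-nt (cP, 5') and 12-nt (OH, 3') blind ends naturally. Replicates
differ by a lognormal depth factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import CLASS_CA, site_classes
from .types import (
    LIB_CP,
    LIB_OH,
    FragmentRecord,
    ReferenceStructure,
    TranscriptRecord,
)

RNA_ALPHABET = ("A", "C", "G", "U")


@dataclass(frozen=True)
class SimulationConfig:
    """Rates and noise of the synthetic cleavage model.

    lambda_bg / lambda_str are mean background and structure-dependent
    cleavage events per site per replicate at unit depth; depth is a
    sequencing-depth multiplier; ca_multiplier (>= 1) inflates cP-channel
    capture at CA sites; replicate_noise_sd is the lognormal sd of the
    per-replicate depth factor.

    Two further lognormal noise sources make the signal realistically
    overlapping between paired and unpaired classes (real probing data show
    many unpaired positions with low signal): site_noise_sd scales the
    cleavage propensity per site, shared by both libraries and replicates
    (local conformation effects); capture_noise_sd scales the capture
    efficiency per site, library and replicate (each library prep is an
    independent ligation reaction). With capture_noise_sd == 0 and
    ca_multiplier == 1 the two
    libraries' pre-censoring counts are identical at every site (exact
    dual-end conservation); with either bias on, conservation holds for the
    shared event stream only.
    """

    lambda_bg: float = 0.5
    lambda_str: float = 5.0
    ca_multiplier: float = 3.0
    depth: float = 5.0
    replicate_noise_sd: float = 0.2
    site_noise_sd: float = 0.5
    capture_noise_sd: float = 0.3
    min_mappable_len: int = 12
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if min(self.lambda_bg, self.lambda_str, self.depth) < 0:
            raise ValueError("rates must be non-negative")
        if self.ca_multiplier < 1:
            raise ValueError("ca_multiplier must be >= 1")
        if self.min_mappable_len < 1:
            raise ValueError("min_mappable_len must be >= 1")
        if min(self.replicate_noise_sd, self.site_noise_sd, self.capture_noise_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of one simulated transcript.

    ``events`` holds the shared (dual-end) event count per internal site
    (index s-1 <-> site s, s in 1..L-1) per replicate; ``counts`` holds the
    per-library pre-censoring fragment counts per site, which differ from
    ``events`` only through the capture noise and the CA bias (and equal it
    exactly when both are disabled).
    """

    transcript_id: str
    unpaired: np.ndarray  # unpairedness per position (indicator or probability)
    events: dict = field(default_factory=dict)  # replicate -> int array (L-1)
    counts: dict = field(default_factory=dict)  # (library, replicate) -> int array (L-1)
    fragments_uncensored: list = field(default_factory=list)


def simulate_fragments(
    transcript: TranscriptRecord,
    unpaired: np.ndarray,
    config: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
    site_rate_multiplier: Optional[np.ndarray] = None,
    replicates: Optional[Sequence[str]] = None,
) -> tuple[list[FragmentRecord], SimTruth]:
    """Draw cleavage fragments for one transcript.

    ``unpaired`` is the ground-truth unpairedness per position (length L):
    either a boolean indicator or a real-valued probability in [0, 1] (e.g.
    the thermal-ensemble unpairedness — each cleavage event samples a
    different molecule of the ensemble). ``site_rate_multiplier`` optionally
    scales the event rate per site (length L-1), e.g. to model
    codon-position-dependent susceptibility. Returns the censored (mappable)
    fragments and the full ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng()
    length = transcript.length
    if len(unpaired) != length:
        raise ValueError("unpaired mask length mismatch")
    if length < 2 * config.min_mappable_len:
        import warnings

        warnings.warn(
            f"{transcript.id}: length {length} < twice the mapping floor; "
            "output will be mostly censored"
        )
    unpaired = np.asarray(unpaired, dtype=float)
    if unpaired.min() < 0 or unpaired.max() > 1:
        raise ValueError("unpairedness values must lie in [0, 1]")
    classes = site_classes(transcript.sequence)
    is_ca_site = classes[: length - 1] == CLASS_CA
    base_rate = config.lambda_bg + config.lambda_str * unpaired[: length - 1]
    if site_rate_multiplier is not None:
        if len(site_rate_multiplier) != length - 1:
            raise ValueError("site_rate_multiplier must have length L-1")
        base_rate = base_rate * np.asarray(site_rate_multiplier, dtype=float)
    # per-site cleavage propensity, shared by libraries and replicates
    if config.site_noise_sd > 0:
        sd = config.site_noise_sd
        base_rate = base_rate * rng.lognormal(-0.5 * sd * sd, sd, size=length - 1)
    ca_factor = np.where(is_ca_site, config.ca_multiplier, 1.0)

    if replicates is None:
        replicates = [f"r{k + 1}" for k in range(config.n_replicates)]
    truth = SimTruth(transcript.id, unpaired)
    observable: list[FragmentRecord] = []
    csd = config.capture_noise_sd
    unbiased = csd == 0 and config.ca_multiplier == 1
    for rep in replicates:
        sd = config.replicate_noise_sd
        depth_factor = config.depth * rng.lognormal(-0.5 * sd * sd, sd)
        lam = depth_factor * base_rate
        events = rng.poisson(lam)
        if unbiased:
            # both libraries observe the shared event stream exactly
            cp_counts = events.copy()
            oh_counts = events.copy()
        else:
            psi_cp = rng.lognormal(-0.5 * csd * csd, csd, size=length - 1) if csd > 0 else 1.0
            psi_oh = rng.lognormal(-0.5 * csd * csd, csd, size=length - 1) if csd > 0 else 1.0
            cp_counts = rng.poisson(lam * psi_cp * ca_factor)
            oh_counts = rng.poisson(lam * psi_oh)
        truth.events[rep] = events
        truth.counts[(LIB_CP, rep)] = cp_counts
        truth.counts[(LIB_OH, rep)] = oh_counts
        for s in range(1, length):
            for _ in range(int(cp_counts[s - 1])):
                frag = FragmentRecord(transcript.id, 1, s, LIB_CP, rep)
                truth.fragments_uncensored.append(frag)
                if frag.length >= config.min_mappable_len:
                    observable.append(frag)
            for _ in range(int(oh_counts[s - 1])):
                frag = FragmentRecord(transcript.id, s + 1, length, LIB_OH, rep)
                truth.fragments_uncensored.append(frag)
                if frag.length >= config.min_mappable_len:
                    observable.append(frag)
    return observable, truth


def simulate_from_structure(
    transcript: TranscriptRecord,
    structure: ReferenceStructure,
    config: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
    **kwargs,
) -> tuple[list[FragmentRecord], SimTruth]:
    """Convenience wrapper taking a dot-bracket reference as ground truth."""
    return simulate_fragments(
        transcript, structure.unpaired_mask(), config, rng, **kwargs
    )


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(RNA_ALPHABET, size=length))


def sample_true_structure(
    sequence: str, seed: int, temperature_K: float = 310.15
) -> tuple[str, np.ndarray]:
    """Draw a reference structure and the ensemble unpairedness of a sequence.

    Returns (dot-bracket, p_unpaired) where the dot-bracket is one seeded
    sample from the thermodynamic Boltzmann ensemble — playing the role of
    the molecule's actual (e.g. in vivo) structure, which generally differs
    from the single MFE prediction — and p_unpaired[i] is the equilibrium
    probability that position i+1 is unpaired. Cleavage events average over
    the ensemble (each event hits a different molecule), so rates follow
    p_unpaired while the reference is a single structure; the residual
    mismatch between the two mirrors the imperfection of real reference
    structures.
    """
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "Boltzmann sampling requires the ViennaRNA python module 'RNA'"
        ) from exc
    md = RNA.md()
    md.temperature = temperature_K - 273.15
    md.uniq_ML = 1  # required for stochastic backtracking
    fc = RNA.fold_compound(sequence, md)
    fc.pf()
    RNA.init_rand(int(seed) % (2**31 - 1))
    (structure,) = fc.pbacktrack(1)
    bpp = np.array(fc.bpp())  # (L+1)x(L+1), upper triangle, 1-based
    length = len(sequence)
    paired_prob = bpp[1:, 1:].sum(axis=0) + bpp[1:, 1:].sum(axis=1)
    p_unpaired = np.clip(1.0 - paired_prob[:length], 0.0, 1.0)
    return structure, p_unpaired


@dataclass
class Benchmark:
    transcripts: list  # TranscriptRecord
    structures: list  # ReferenceStructure (ground truth)
    fragments: list  # FragmentRecord (observable, all transcripts/reps/libs)
    truths: dict  # transcript_id -> SimTruth
    replicates: list

    @property
    def sequences(self) -> dict:
        return {t.id: t.sequence for t in self.transcripts}


def make_benchmark(
    n_transcripts: int = 20,
    length_range: tuple = (70, 300),
    config: SimulationConfig = SimulationConfig(),
    seed: int = 1,
) -> Benchmark:
    """Fully reproducible synthetic benchmark bundle.

    Random sequences receive a Boltzmann-sampled "true" structure, from which
    dual-library fragments are simulated for each replicate.
    """
    rng = np.random.default_rng(seed)
    transcripts, structures, fragments, truths = [], [], [], {}
    replicates = [f"r{k + 1}" for k in range(config.n_replicates)]
    for t in range(n_transcripts):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        tid = f"synth{t + 1:03d}"
        seq = random_sequence(length, rng)
        struct_seed = int(rng.integers(1, 2**31 - 1))
        db, _p_unpaired = sample_true_structure(seq, struct_seed)
        transcript = TranscriptRecord(tid, seq)
        structure = ReferenceStructure(tid, db)
        frags, truth = simulate_fragments(
            transcript, structure.unpaired_mask(), config, rng, replicates=replicates
        )
        transcripts.append(transcript)
        structures.append(structure)
        fragments.extend(frags)
        truths[tid] = truth
    return Benchmark(transcripts, structures, fragments, truths, replicates)


def inject_structure_violation(
    unpaired: np.ndarray, fraction: float, seed: int = 0
) -> np.ndarray:
    """Flip the pairing label of round(fraction * L) random positions.

    Models imperfect reference structures for robustness tests.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    unpaired = np.asarray(unpaired, dtype=bool).copy()
    n_flip = round(fraction * len(unpaired))
    if n_flip:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(unpaired), size=n_flip, replace=False)
        unpaired[idx] = ~unpaired[idx]
    return unpaired


# ---------------------------------------------------------------------------
# mRNA-style dataset for metaprofile analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MrnaSimConfig:
    """Region-structured unpairedness for synthetic mRNAs.

    Unpaired probabilities per region emulate the observed ordering
    (early CDS most open, late CDS least); third_position_rate_boost models
    the higher cleavage susceptibility of third codon positions in the CDS.
    """

    utr_len: int = 60
    cds_len: int = 300
    p_unpaired_utr: float = 0.40
    p_unpaired_cds_early: float = 0.50
    p_unpaired_cds_late: float = 0.35
    cds_early_codons: int = 20
    third_position_rate_boost: float = 1.4
    cleavage: SimulationConfig = SimulationConfig()


def make_mrna_dataset(
    n_mrnas: int = 30,
    config: MrnaSimConfig = MrnaSimConfig(),
    seed: int = 1,
):
    """Synthetic mRNA set with annotation for metaprofile analysis.

    Returns (transcripts, annotation DataFrame, fragments, truths). The
    annotation places each mRNA on its own stretch of a virtual genome
    (non-overlapping, + strand) with columns gene_id, start, end, strand,
    kind, cds_start; transcript position 1 corresponds to the gene start.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    length = config.utr_len + config.cds_len
    gap = 200
    transcripts, rows, fragments, truths = [], [], [], {}
    cursor = 1
    for m in range(n_mrnas):
        tid = f"mrna{m + 1:03d}"
        seq = list(random_sequence(length, rng))
        # enforce the AUG start codon at the CDS start
        seq[config.utr_len : config.utr_len + 3] = ["A", "U", "G"]
        seq = "".join(seq)
        p_unpaired = np.empty(length)
        p_unpaired[: config.utr_len] = config.p_unpaired_utr
        early_end = config.utr_len + 3 * config.cds_early_codons
        p_unpaired[config.utr_len : early_end] = config.p_unpaired_cds_early
        p_unpaired[early_end:] = config.p_unpaired_cds_late
        unpaired = rng.random(length) < p_unpaired
        # third-codon-position susceptibility boost (site s <-> position s)
        mult = np.ones(length - 1)
        for s in range(config.utr_len + 3, length, 3):  # 1-based site s = index+1
            if s <= length - 1:
                mult[s - 1] = config.third_position_rate_boost
        transcript = TranscriptRecord(tid, seq)
        frags, truth = simulate_fragments(
            transcript, unpaired, config.cleavage, rng, site_rate_multiplier=mult
        )
        transcripts.append(transcript)
        fragments.extend(frags)
        truths[tid] = truth
        rows.append(
            (tid, cursor, cursor + length - 1, "+", "mRNA", cursor + config.utr_len)
        )
        cursor += length + gap
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "strand", "kind", "cds_start"]
    )
    return transcripts, annotation, fragments, truths
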