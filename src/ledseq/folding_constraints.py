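"""Pseudo-energy soft constraints from unpaired probabilities.

The estimated probability q_i of position i being unpaired is converted into
a free-energy bonus for the unpaired state,

    dG_i = -R * T * c * ( ln(q_i / (1 - q_i)) - ln(p0 / (1 - p0)) )

a log-likelihood-ratio against the prior unpaired fraction p0 of the
calibration set. The tuning constant c sets the trust in the probing data
(default 1.2); p0 defaults to 0.42. Low signal cannot be distinguished from
missing data, so only positions with q_i > p0 — where the signal is actual
evidence for openness — receive a constraint; there dG < 0, stabilizing the
unpaired state during MFE folding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engines import FoldingEngine, get_engine
from .types import UnpairedProfile

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT = 0.0019872


@dataclass(frozen=True)
class PseudoEnergyConfig:
    """Parameters of the probability-to-energy conversion.

    c_scale weights the probing evidence; p0 is the prior unpaired fraction;
    temperature_K is the folding temperature (37 C default).
    """

    c_scale: float = 1.2
    p0: float = 0.42
    temperature_K: float = 310.15
    gas_constant: float = GAS_CONSTANT
    clip_eps: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must be in (0,1), got {self.p0}")
        if self.c_scale <= 0:
            raise ValueError(f"c_scale must be positive, got {self.c_scale}")
        if self.temperature_K <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature_K}")


@dataclass
class PseudoEnergyVector:
    """Per-position pseudo-energies with the applied-constraint mask."""

    transcript_id: str
    dG: np.ndarray  # kcal/mol, NaN where not applied
    applied: np.ndarray  # bool

    def as_engine_constraints(self) -> dict[int, float]:
        """1-based {position: energy} mapping for the folding engine."""
        return {
            i + 1: float(self.dG[i])
            for i in np.flatnonzero(self.applied)
        }


def pseudo_energy(q, config: PseudoEnergyConfig = PseudoEnergyConfig()) -> np.ndarray:
    """Log-odds pseudo-energy (kcal/mol) for unpaired probability q.

    q is clipped to [eps, 1-eps] before the log-odds; NaN propagates. The
    result is exactly 0 at q == p0, negative above, positive below.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    out = np.full(q.shape, np.nan)
    ok = np.isfinite(q)
    qc = np.clip(q[ok], config.clip_eps, 1.0 - config.clip_eps)
    rt_c = config.gas_constant * config.temperature_K * config.c_scale
    prior_logodds = np.log(config.p0 / (1.0 - config.p0))
    out[ok] = -rt_c * (np.log(qc / (1.0 - qc)) - prior_logodds)
    return float(out[0]) if scalar else out


def select_constraints(
    profile: UnpairedProfile, config: PseudoEnergyConfig = PseudoEnergyConfig()
) -> PseudoEnergyVector:
    """Apply the strict q_i > p0 rule and compute energies only there."""
    q = np.asarray(profile.q, dtype=float)
    applied = np.isfinite(q) & (q > config.p0)
    dg = np.full(q.shape, np.nan)
    if applied.any():
        dg[applied] = pseudo_energy(q[applied], config)
    return PseudoEnergyVector(profile.transcript_id, dg, applied)


def fold_with_constraints(
    sequence: str,
    pseudo_energies: Optional[PseudoEnergyVector] = None,
    engine: "FoldingEngine | str" = "vienna",
    temperature_K: float = 310.15,
) -> dict:
    """Soft-constrained MFE prediction through a registered folding engine.

    With no (or an empty) constraint set this is the engine's unconstrained
    MFE. Returns a dict with structure, mfe, engine name/version, and the
    number of applied constraints.
    """
    if isinstance(engine, str):
        engine = get_engine(engine)
    constraints: dict[int, float] = {}
    if pseudo_energies is not None:
        if len(pseudo_energies.dG) != len(sequence):
            raise ValueError(
                f"pseudo-energy vector length {len(pseudo_energies.dG)} != "
                f"sequence length {len(sequence)}"
            )
        constraints = pseudo_energies.as_engine_constraints()
    structure, mfe = engine.fold(sequence, constraints, temperature_K)
    return {
        "structure": structure,
        "mfe": mfe,
        "engine": engine.name,
        "engine_version": engine.version,
        "n_constraints": len(constraints),
    }
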