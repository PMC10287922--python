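"""Pluggable thermodynamic folding engines.

An engine turns (sequence, per-position unpaired-state pseudo-energies,
temperature) into an MFE dot-bracket structure. The contract is deliberately
generic: pseudo-energies attach to the *unpaired* state of a nucleotide as
soft constraints — no structure is forbidden, the energy landscape is tilted.

The reference adapter wraps the ViennaRNA programming interface (the ``RNA``
python module). Engines register under a short name; ``get_engine`` raises a
helpful error when the requested engine (or its backing library) is missing.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional

import numpy as np

_REGISTRY: dict[str, Callable[[], "FoldingEngine"]] = {}


class EngineUnavailableError(RuntimeError):
    pass


class FoldingEngine:
    """Interface: subclasses implement ``fold``."""

    name = "abstract"
    version = "unknown"

    def fold(
        self,
        sequence: str,
        unpaired_energies: Optional[Mapping[int, float]] = None,
        temperature_K: float = 310.15,
    ) -> tuple[str, float]:
        """Return (dot-bracket MFE structure, MFE in kcal/mol).

        ``unpaired_energies`` maps 1-based positions to soft-constraint
        energies (kcal/mol) added to the unpaired state of that position.
        """
        raise NotImplementedError


def register_engine(name: str, factory: Callable[[], FoldingEngine]) -> None:
    _REGISTRY[name] = factory


def get_engine(name: str = "vienna") -> FoldingEngine:
    if name not in _REGISTRY:
        raise EngineUnavailableError(
            f"no folding engine registered under {name!r}; register one with "
            f"ledseq.engines.register_engine(name, factory). Available: "
            f"{sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]()


class ViennaEngine(FoldingEngine):
    """MFE folding with ViennaRNA soft constraints (fc.sc_add_up)."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise EngineUnavailableError(
                "the ViennaRNA python module 'RNA' is not importable; install "
                "the ViennaRNA package with python bindings to use this engine"
            ) from exc
        self._RNA = RNA
        self.version = getattr(RNA, "__version__", "unknown")

    def fold(self, sequence, unpaired_energies=None, temperature_K=310.15):
        RNA = self._RNA
        md = RNA.md()
        md.temperature = temperature_K - 273.15
        fc = RNA.fold_compound(sequence, md)
        if unpaired_energies:
            for pos, energy in unpaired_energies.items():
                if not 1 <= pos <= len(sequence):
                    raise ValueError(
                        f"constraint position {pos} outside 1..{len(sequence)}"
                    )
                if np.isfinite(energy):
                    fc.sc_add_up(int(pos), float(energy))
        structure, mfe = fc.mfe()
        return structure, float(mfe)


register_engine("vienna", ViennaEngine)
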