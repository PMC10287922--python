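"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from ledseq import workflow as wf
from ledseq.simulate import SimulationConfig, make_benchmark


def oracle_pairs(dotbracket: str) -> set:
    """Independent O(n^2) pair matcher: for every '(' scan forward counting
    nesting depth until its partner ')'. Used as the brute-force oracle for
    stack-based pair extraction."""
    pairs = set()
    for i, ch in enumerate(dotbracket):
        if ch != "(":
            continue
        depth = 0
        for j in range(i + 1, len(dotbracket)):
            if dotbracket[j] == "(":
                depth += 1
            elif dotbracket[j] == ")":
                if depth == 0:
                    pairs.add((i + 1, j + 1))
                    break
                depth -= 1
    return pairs


def random_dotbracket(rng: np.random.Generator, length: int) -> str:
    """Random balanced dot-bracket string (minimum hairpin loop 3)."""
    chars = ["."] * length
    stack: list[int] = []
    for i in range(length):
        r = rng.random()
        if r < 0.35:
            stack.append(i)
            chars[i] = "("
        elif r < 0.65 and stack and i - stack[-1] > 3:
            chars[i] = ")"
            stack.pop()
    for i in stack:  # unmatched opens become dots
        chars[i] = "."
    return "".join(chars)


@pytest.fixture(scope="session")
def benchmark():
    """The 20-transcript synthetic benchmark under default study conditions."""
    return make_benchmark(20, (70, 300), SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark):
    """Benchmark carried through counting, normalization and calibration."""
    counts = wf.count_all(benchmark.fragments, benchmark.transcripts, benchmark.replicates)
    per_rep, averaged = wf.normalize_and_average(counts)
    models = wf.calibrate_dataset(averaged, benchmark.structures, benchmark.transcripts)
    return {
        "benchmark": benchmark,
        "counts": counts,
        "per_replicate": per_rep,
        "averaged": averaged,
        "models": models,
    }
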