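"""Deterministic per-stage random streams.

A pipeline run owns one integer seed; each stage draws from an independent
stream derived from that seed and a stable text label, so a stage rerun in
isolation reproduces exactly what it did inside the full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, label: str) -> int:
    """A child seed (< 2^31) derived from a run seed and a stage label."""
    return (int(seed) ^ zlib.crc32(label.encode("utf-8"))) & 0x7FFFFFFF


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Generator seeded from ``seed`` and a stable stage ``label``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))]))
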