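"""Small bookkeeping helpers shared across the pipeline."""

from __future__ import annotations

import math
from typing import Sequence

__all__ = ["parse_duration", "concatenated_run_trs", "retained_fraction", "n_pairs"]


def parse_duration(text: str) -> float:
    """Parse a ``mm:ss`` (or ``hh:mm:ss``) duration string into seconds."""
    parts = text.strip().split(":")
    if not 1 <= len(parts) <= 3 or any(p == "" for p in parts):
        raise ValueError(f"cannot parse duration {text!r}")
    seconds = 0.0
    for p in parts:
        seconds = seconds * 60.0 + float(p)
    return seconds


def concatenated_run_trs(durations: Sequence[str | float],
                         tr_seconds: float = 1.0) -> int:
    """Total TR count of several runs concatenated back to back.

    Durations may be ``mm:ss`` strings or numbers of seconds; each run
    contributes ceil(duration / TR) frames.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    total = 0
    for d in durations:
        seconds = parse_duration(d) if isinstance(d, str) else float(d)
        total += math.ceil(seconds / tr_seconds - 1e-9)
    return total


def retained_fraction(n_tr: int, n_censored: int) -> float:
    """Fraction of frames retained after censoring ``n_censored`` of
    ``n_tr`` time points."""
    if not 0 <= n_censored <= n_tr:
        raise ValueError("n_censored must be in [0, n_tr]")
    return (n_tr - n_censored) / n_tr


def n_pairs(n_subjects: int) -> int:
    """Number of unique subject pairs, n(n−1)/2."""
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    return n_subjects * (n_subjects - 1) // 2
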