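"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dloopmap import (
    CONVERTED,
    MISSING,
    UNCONVERTED,
    ConversionProfile,
    DonorReference,
    Strand,
    load_substrate,
)

_CHAR = {"c": CONVERTED, "u": UNCONVERTED, "m": MISSING}


def make_profile(
    status_str: str,
    positions=None,
    read_id: str = "r1",
    strand: Strand = Strand.TOP,
) -> ConversionProfile:
    """Build a profile from a 'cum' status string; default positions 0,1,2..."""
    statuses = np.array([_CHAR[ch] for ch in status_str], dtype=np.int8)
    if positions is None:
        positions = np.arange(len(statuses))
    positions = np.asarray(positions, dtype=np.int64)
    span = (int(positions[0]), int(positions[-1]) + 1) if len(positions) else (0, 0)
    return ConversionProfile(read_id, strand, span, positions, statuses)


def oracle_windows(statuses: np.ndarray, t: float, w: int) -> list[tuple[int, int]]:
    """Exhaustive enumeration of qualifying w-windows (profile-index pairs).

    Independent of the sliding implementation: walks every window of w
    consecutive scorable entries and checks the converted fraction.
    """
    scorable = [i for i, s in enumerate(statuses) if s != MISSING]
    out = []
    for k in range(len(scorable) - w + 1):
        win = scorable[k : k + w]
        conv = sum(1 for i in win if statuses[i] == CONVERTED)
        if conv + 1e-9 >= t * w:
            out.append((win[0], win[-1]))
    return out


def oracle_footprints(
    statuses: np.ndarray, positions: np.ndarray, t: float, w: int
) -> list[tuple[int, int]]:
    """Reference-position (start, end) pairs by brute-force window union.

    Unions qualifying windows in scorable-subsequence space, splits into
    maximal components, trims each to its outermost converted entries.
    """
    scorable = [i for i, s in enumerate(statuses) if s != MISSING]
    rank = {p: k for k, p in enumerate(scorable)}
    covered = sorted(
        {i for a, b in oracle_windows(statuses, t, w) for i in scorable
         if a <= i <= b}
    )
    if not covered:
        return []
    components: list[list[int]] = [[covered[0]]]
    for i in covered[1:]:
        if rank[i] == rank[components[-1][-1]] + 1:
            components[-1].append(i)
        else:
            components.append([i])
    out = []
    for comp in components:
        conv = [i for i in comp if statuses[i] == CONVERTED]
        if conv:
            out.append((int(positions[conv[0]]), int(positions[conv[-1]])))
    return out


@pytest.fixture(scope="session")
def ds931() -> DonorReference:
    return load_substrate("ds98-931")


@pytest.fixture(scope="session")
def ds607() -> DonorReference:
    return load_substrate("ds98-607")


@pytest.fixture()
def tiny_ref() -> DonorReference:
    return DonorReference("tiny", "ACCGA", 0, 5)
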