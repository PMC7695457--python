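"""Single-molecule D-loop footprint calling.

A footprint is a peak of C→T conversion along one read: a stretch where
the displaced strand was single-stranded long enough for bisulfite to
deaminate its cytosines.  The caller slides a window of ``w`` consecutive
scorable cytosines along the read's conversion profile and marks every
window whose converted fraction reaches ``t``; overlapping and adjacent
qualifying windows are merged, and each merged run is trimmed so that both
footprint boundaries are converted cytosines (the duplex-protected flanks
are unconverted, so extending into them would overstate the D-loop).

Window semantics: "consecutive" counts cytosines, not nucleotides, so the
genomic grain of the caller adapts to the local cytosine density.  With
the default ``t40w50`` preset (≥40% converted in 50 consecutive
cytosines), the minimal detectable D-loop is the tightest 50-cytosine run
of the reference strand — about 120–200 nt on typical amplicons.

MISSING cytosines (alignment gaps, non-C/T bases) are skipped when forming
runs by default: they neither count as converted nor unconverted.  The
strictly more conservative alternative — counting them as unconverted —
is available via ``CallerParams.missing_as_unconverted``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .align import CONVERTED, MISSING, ConversionProfile
from .reference import DonorReference, Strand

__all__ = ["CallerParams", "Footprint", "qualifying_windows", "call_footprints",
           "PRESETS"]

PRESETS = {
    "t40w50": (0.40, 50),
    "t25w20": (0.25, 20),
}


@dataclass(frozen=True)
class CallerParams:
    """Peak-calling threshold: fraction ``t`` over ``w`` consecutive cytosines.

    A window of ``w`` consecutive scorable cytosines qualifies when at
    least ``⌈t·w⌉`` of them are converted (a tie at exactly ``t``
    qualifies).  ``trim=False`` reports raw merged window unions instead
    of trimming boundaries to the outermost converted cytosines.
    """

    t: float = 0.40
    w: int = 50
    preset: str | None = "t40w50"
    trim: bool = True
    missing_as_unconverted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.t <= 1.0):
            raise ValueError(f"threshold fraction t={self.t} outside (0, 1]")
        if self.w < 2:
            raise ValueError(f"window w={self.w} must be >= 2")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "CallerParams":
        try:
            t, w = PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            ) from None
        return cls(t=t, w=w, preset=name, **overrides)

    @property
    def min_converted(self) -> int:
        """Integer criterion: smallest converted count that reaches ``t``."""
        # guard float artifacts like 0.4*50 == 20.000000000000004
        return int(math.ceil(self.t * self.w - 1e-9))


@dataclass(frozen=True)
class Footprint:
    """One called D-loop footprint on one read.

    ``start`` and ``end`` are reference nt positions, inclusive; under the
    default trimming both carry CONVERTED status.  ``n_cytosines`` and
    ``n_converted`` count strand cytosines of the profile inside
    ``[start, end]``.
    """

    read_id: str
    strand: Strand
    start: int
    end: int
    n_cytosines: int
    n_converted: int

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def conv_fraction(self) -> float:
        return self.n_converted / self.n_cytosines if self.n_cytosines else 0.0


def _scorable_view(profile: ConversionProfile, params: CallerParams):
    """Indices (into the profile) and converted mask of scorable cytosines."""
    if params.missing_as_unconverted:
        idx = np.arange(len(profile.statuses))
    else:
        idx = np.flatnonzero(profile.statuses != MISSING)
    conv = profile.statuses[idx] == CONVERTED
    return idx, conv


def qualifying_windows(
    profile: ConversionProfile, params: CallerParams
) -> list[tuple[int, int]]:
    """All qualifying ``w``-windows, as (first, last) profile-index pairs.

    Every run of ``w`` consecutive scorable cytosines whose converted
    count reaches the threshold is returned, in order.  Profiles with
    fewer than ``w`` scorable cytosines yield no windows.
    """
    idx, conv = _scorable_view(profile, params)
    w = params.w
    if len(idx) < w:
        return []
    counts = np.convolve(conv.astype(np.int32), np.ones(w, dtype=np.int32), "valid")
    starts = np.flatnonzero(counts >= params.min_converted)
    return [(int(idx[s]), int(idx[s + w - 1])) for s in starts]


def call_footprints(
    profile: ConversionProfile,
    params: CallerParams,
    ref: DonorReference | None = None,
) -> list[Footprint]:
    """Call D-loop footprints on one read.

    Overlapping/adjacent qualifying windows are merged into maximal
    covered runs (two footprints on the same read are separated by at
    least one cytosine not covered by any qualifying window); each run is
    trimmed to its outermost converted cytosines, and counts are taken
    over the trimmed reference range.  Footprints are returned in
    reference coordinate order.
    """
    idx, conv = _scorable_view(profile, params)
    w = params.w
    if len(idx) < w:
        return []
    counts = np.convolve(conv.astype(np.int32), np.ones(w, dtype=np.int32), "valid")
    starts = np.flatnonzero(counts >= params.min_converted)
    if len(starts) == 0:
        return []

    # merge windows [s, s+w-1] in scorable space: consecutive qualifying
    # starts overlap by construction; a gap > w between starts separates runs
    runs: list[tuple[int, int]] = []
    run_start = prev = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        if s <= prev + w:  # windows overlap or are adjacent
            prev = s
        else:
            runs.append((run_start, prev + w - 1))
            run_start = prev = s
    runs.append((run_start, prev + w - 1))

    footprints: list[Footprint] = []
    positions = profile.positions
    statuses = profile.statuses
    for a, b in runs:
        if params.trim:
            inside = np.arange(a, b + 1)
            conv_inside = inside[conv[a : b + 1]]
            if len(conv_inside) == 0:
                continue  # unreachable with t > 0, kept defensive
            a, b = int(conv_inside[0]), int(conv_inside[-1])
        lo_i, hi_i = int(idx[a]), int(idx[b])
        start, end = int(positions[lo_i]), int(positions[hi_i])
        in_range = statuses[lo_i : hi_i + 1]
        footprints.append(
            Footprint(
                read_id=profile.read_id,
                strand=profile.strand,
                start=start,
                end=end,
                n_cytosines=len(in_range),
                n_converted=int(np.count_nonzero(in_range == CONVERTED)),
            )
        )
    footprints.sort(key=lambda f: f.start)
    return footprints
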