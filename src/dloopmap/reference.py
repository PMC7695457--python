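"""Donor amplicon references for D-loop footprint mapping.

A donor is a double-stranded PCR amplicon.  By convention the *top* strand
is the displaced strand of the D-loop — the strand rendered single-stranded
by invasion and therefore the only strand exposed to non-denaturing
bisulfite conversion inside the D-loop.  All coordinates throughout the
package are positions on the top strand, 0-based and half-open for
intervals; human-readable reports convert to 1-based inclusive.

Cytosines of the bottom strand sit opposite top-strand guanines, so the
bottom-strand cytosine index is the list of ``G`` positions on the top
sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Strand",
    "DonorReference",
    "ReferenceError",
    "UndetectableRegionError",
    "load_reference",
    "load_substrate",
    "bundled_substrates",
    "min_window_span",
    "read_homology_bed",
]

_VALID_BASES = frozenset("ACGTN")


class Strand(str, enum.Enum):
    """Which donor strand a read represents, in top-strand coordinates."""

    TOP = "TOP"
    BOTTOM = "BOTTOM"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


class ReferenceError(ValueError):
    """Raised when a donor reference fails validation."""


class UndetectableRegionError(ValueError):
    """Raised when a region holds fewer cytosines than the caller window."""


@dataclass(frozen=True)
class DonorReference:
    """A validated donor amplicon with per-strand cytosine indices.

    Parameters
    ----------
    name:
        Record identifier.
    top_sequence:
        Uppercase top-strand sequence over ``{A,C,G,T,N}``.
    homology_start, homology_end:
        The interval homologous to the invading substrate, 0-based half-open
        on the top strand.  Genuine D-loop footprints lie inside it.
    """

    name: str
    top_sequence: str
    homology_start: int
    homology_end: int
    cytosine_index_top: np.ndarray = field(repr=False, default=None)
    cytosine_index_bottom: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        seq = self.top_sequence.upper()
        if not seq:
            raise ReferenceError(f"reference {self.name!r}: empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ReferenceError(
                f"reference {self.name!r}: non-ACGTN characters {sorted(bad)}"
            )
        if not (0 <= self.homology_start < self.homology_end <= len(seq)):
            raise ReferenceError(
                f"reference {self.name!r}: homology interval "
                f"[{self.homology_start}, {self.homology_end}) out of bounds "
                f"for length {len(seq)}"
            )
        arr = np.frombuffer(seq.encode(), dtype="S1")
        object.__setattr__(self, "top_sequence", seq)
        object.__setattr__(
            self, "cytosine_index_top", np.flatnonzero(arr == b"C")
        )
        object.__setattr__(
            self, "cytosine_index_bottom", np.flatnonzero(arr == b"G")
        )

    def __len__(self) -> int:
        return len(self.top_sequence)

    @property
    def bottom_sequence(self) -> str:
        """Bottom strand 5'→3' (reverse complement of the top strand)."""
        return str(Seq(self.top_sequence).reverse_complement())

    def cytosines(self, strand: Strand) -> np.ndarray:
        """Top-strand coordinates of the given strand's cytosines."""
        if Strand(strand) is Strand.TOP:
            return self.cytosine_index_top
        return self.cytosine_index_bottom

    def homology_relative(self, position: int) -> int:
        """Convert an amplicon coordinate to a homology-relative one."""
        return position - self.homology_start


def read_homology_bed(path: str | Path) -> tuple[int, int]:
    """Read a single-interval BED file giving the homology region.

    Only the first non-comment line is used; coordinates are BED-style
    0-based half-open.
    """
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ReferenceError(f"{path}: malformed BED line {line!r}")
        return int(parts[1]), int(parts[2])
    raise ReferenceError(f"{path}: no intervals found")


def load_reference(
    fasta_path: str | Path,
    homology: tuple[int, int] | str | Path | None = None,
    name: str | None = None,
) -> DonorReference:
    """Load one donor reference from a (possibly multi-record) FASTA.

    Parameters
    ----------
    fasta_path:
        FASTA file with the donor amplicon top-strand sequence.
    homology:
        Either an ``(start, end)`` tuple (0-based half-open), a path to a
        single-line BED file, or ``None`` to use the whole record.
    name:
        Record id to select when the FASTA holds several records; required
        in that case.
    """
    records = {r.id: r for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise ReferenceError(f"{fasta_path}: no FASTA records")
    if name is None:
        if len(records) > 1:
            raise ReferenceError(
                f"{fasta_path}: {len(records)} records; pass name= to select "
                f"one of {sorted(records)}"
            )
        record = next(iter(records.values()))
    else:
        try:
            record = records[name]
        except KeyError:
            raise ReferenceError(
                f"{fasta_path}: no record named {name!r}; "
                f"available: {sorted(records)}"
            ) from None
    seq = str(record.seq).upper()
    if homology is None:
        hom = (0, len(seq))
    elif isinstance(homology, (str, Path)):
        hom = read_homology_bed(homology)
    else:
        hom = (int(homology[0]), int(homology[1]))
    return DonorReference(record.id, seq, hom[0], hom[1])


def bundled_substrates() -> Path:
    """Path to the bundled FASTA of donor homology sequences.

    The records are the homologous-donor sequences for the ds98-* family of
    invasion substrates (98-nt duplex plus N nt of donor homology, an
    optional 78-nt heterologous 3' flap) and the 100-mer substrate.
    """
    return Path(__file__).parent / "data" / "substrates.fasta"


def load_substrate(name: str) -> DonorReference:
    """Load a bundled substrate donor sequence, homology = whole record."""
    return load_reference(bundled_substrates(), homology=None, name=name)


def min_window_span(
    ref: DonorReference,
    strand: Strand,
    w: int,
    region: tuple[int, int] | None = None,
) -> int:
    """Smallest genomic span (nt) of ``w`` consecutive strand cytosines.

    This is the shortest D-loop the consecutive-cytosine window caller can
    possibly detect in ``region`` at window size ``w``: a footprint must
    cover at least one full window, so its span is bounded below by the
    tightest run of ``w`` cytosines.

    Raises
    ------
    UndetectableRegionError
        If the region contains fewer than ``w`` cytosines on that strand.
    """
    if w < 1:
        raise ValueError(f"w must be positive, got {w}")
    positions = ref.cytosines(strand)
    if region is not None:
        lo, hi = region
        positions = positions[(positions >= lo) & (positions < hi)]
    if len(positions) < w:
        raise UndetectableRegionError(
            f"{ref.name} {Strand(strand).value}: region has "
            f"{len(positions)} cytosines < window w={w}; no D-loop is "
            "detectable there"
        )
    spans = positions[w - 1 :] - positions[: len(positions) - w + 1] + 1
    return int(spans.min())


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return str(Seq(seq).reverse_complement())
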