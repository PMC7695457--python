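"""Bisulfite-aware strand assignment and per-read conversion extraction.

Non-denaturing bisulfite converts cytosine to uracil only where the DNA is
single-stranded; after PCR and sequencing this reads as C→T on the strand
that was exposed.  A read from the displaced (top) strand therefore shows
C→T relative to the top reference inside a D-loop, while a read from the
protected bottom strand shows (in top-strand coordinates) G→A wherever its
own cytosines were converted.

Each read is scored under four hypotheses — {forward, reverse-complement}
× {top strand, bottom strand} — using edit-distance alignment in which the
hypothesis' conversion pair (ref C : read T for top, ref G : read A for
bottom) counts as a match.  Conversion evidence is hypothesis-specific:
C→T support under the bottom hypothesis is a mismatch, and vice versa,
which is what makes strand assignment work.

A read with no conversions at all is sequence-identical under both strand
hypotheses in its best orientation; such ties are resolved by the native
sequencing-orientation convention (a read stored 5'→3' as its molecule
aligns forward if it is the top strand, reverse if the bottom strand).
Any conversion evidence makes the call orientation-invariant.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np

from .reference import DonorReference, Strand, revcomp

__all__ = [
    "Orientation",
    "AlignParams",
    "StrandAssignment",
    "ConversionProfile",
    "ReadDropped",
    "MISSING",
    "UNCONVERTED",
    "CONVERTED",
    "STATUS_CHARS",
    "align_bisulfite",
    "extract_conversions",
    "process_reads",
    "profiles_from_sam",
]

# per-cytosine status codes (int8 arrays throughout)
MISSING = np.int8(0)
UNCONVERTED = np.int8(1)
CONVERTED = np.int8(2)
STATUS_CHARS = {int(MISSING): "m", int(UNCONVERTED): "u", int(CONVERTED): "c"}
_CHAR_STATUS = {v: np.int8(k) for k, v in STATUS_CHARS.items()}

# hypothesis-specific equivalence pairs (ref base, read base) scored as match
_EQ_TOP = [("C", "T"), ("T", "C")]
_EQ_BOTTOM = [("G", "A"), ("A", "G")]


class Orientation(str, enum.Enum):
    """Stored-read orientation relative to the top-strand reference."""

    FORWARD = "FORWARD"
    REVERSE = "REVERSE"

    def __str__(self) -> str:
        return self.value


class ReadDropped(Exception):
    """A read excluded from analysis; ``reason`` goes to the drop log."""

    def __init__(self, read_id: str, reason: str):
        super().__init__(f"{read_id}: {reason}")
        self.read_id = read_id
        self.reason = reason


@dataclass(frozen=True)
class AlignParams:
    """Strand-assignment parameters.

    min_length_frac:
        Minimum read length as a fraction of the amplicon length.
    identity_floor:
        Minimum fraction of read bases matched (under the best hypothesis,
        conversion pairs counting as matches) for the read to be kept.
    margin:
        Relative score margin between the best alignment and the best
        alignment in the opposite orientation; below it the read is called
        ambiguous.  Guards palindromic / low-complexity references where
        orientation itself is uncertain.
    """

    min_length_frac: float = 0.5
    identity_floor: float = 0.70
    margin: float = 0.05


@dataclass
class StrandAssignment:
    """Outcome of strand assignment for one read.

    ``strand`` is ``None`` for ambiguous reads, which are excluded from all
    downstream tallies and recorded in the drop log.  ``score_top`` and
    ``score_bottom`` are matched-base counts under the best orientation of
    each strand hypothesis.  ``aligned_span`` is the reference interval
    covered by the read, 0-based half-open.
    """

    read_id: str
    strand: Strand | None
    orientation: Orientation
    score_top: int
    score_bottom: int
    aligned_span: tuple[int, int]
    identity: float
    cigar: str = field(repr=False, default="")

    @property
    def ambiguous(self) -> bool:
        return self.strand is None


@dataclass
class ConversionProfile:
    """Per-read conversion status of every strand cytosine in the aligned span.

    ``positions`` are top-strand coordinates of that strand's cytosines
    within ``aligned_span``; ``statuses`` holds MISSING / UNCONVERTED /
    CONVERTED per position.  A cytosine is CONVERTED only when the aligned
    read base is the deaminated base (T at a top-strand C; A at a
    reference G for a bottom-strand cytosine), UNCONVERTED when it is the
    reference base, MISSING for any other base or an alignment gap.
    """

    read_id: str
    strand: Strand
    aligned_span: tuple[int, int]
    positions: np.ndarray
    statuses: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.statuses = np.asarray(self.statuses, dtype=np.int8)
        if len(self.positions) != len(self.statuses):
            raise ValueError("positions and statuses length mismatch")

    @property
    def n_scorable(self) -> int:
        return int(np.count_nonzero(self.statuses != MISSING))

    def status_string(self) -> str:
        return "".join(STATUS_CHARS[int(s)] for s in self.statuses)

    @classmethod
    def from_status_string(
        cls,
        read_id: str,
        strand: Strand,
        aligned_span: tuple[int, int],
        status_string: str,
        ref: DonorReference,
    ) -> "ConversionProfile":
        lo, hi = aligned_span
        pos = ref.cytosines(strand)
        pos = pos[(pos >= lo) & (pos < hi)]
        statuses = np.array([_CHAR_STATUS[c] for c in status_string], dtype=np.int8)
        return cls(read_id, Strand(strand), (lo, hi), pos, statuses)


def _edlib_score(query: str, target: str, equalities) -> int:
    """Matched-base count proxy: read length minus edit distance."""
    res = edlib.align(query, target, mode="HW", task="distance",
                      additionalEqualities=equalities)
    return len(query) - res["editDistance"]


_CIGAR_RE = re.compile(r"(\d+)([MIDX=])")


def _target_to_query(cigar: str, target_start: int, query: str) -> dict[int, str]:
    """Map reference position -> aligned read base ('' for deletions)."""
    mapping: dict[int, str] = {}
    t, q = target_start, 0
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in "M=X":
            for k in range(n):
                mapping[t + k] = query[q + k]
            t += n
            q += n
        elif op == "I":  # insertion in the read
            q += n
        elif op == "D":  # deletion: reference base unmatched
            for k in range(n):
                mapping[t + k] = ""
            t += n
    return mapping


def align_bisulfite(
    read_id: str,
    read: str,
    ref: DonorReference,
    params: AlignParams = AlignParams(),
) -> StrandAssignment:
    """Assign a read to the top or bottom donor strand.

    Evaluates the four orientation × strand-hypothesis alignments with free
    end gaps on the reference (the read lies within the amplicon), keeps
    the best, and applies the identity floor and the orientation ambiguity
    margin.

    Raises
    ------
    ReadDropped
        If the read is shorter than the configured minimum or falls below
        the identity floor under its best hypothesis.
    """
    read = read.upper()
    if len(read) < params.min_length_frac * len(ref):
        raise ReadDropped(read_id, "too_short")
    target = ref.top_sequence
    rc = revcomp(read)
    candidates = {
        (Orientation.FORWARD, Strand.TOP): _edlib_score(read, target, _EQ_TOP),
        (Orientation.FORWARD, Strand.BOTTOM): _edlib_score(read, target, _EQ_BOTTOM),
        (Orientation.REVERSE, Strand.TOP): _edlib_score(rc, target, _EQ_TOP),
        (Orientation.REVERSE, Strand.BOTTOM): _edlib_score(rc, target, _EQ_BOTTOM),
    }
    (best_orient, best_strand), best = max(
        candidates.items(), key=lambda kv: (kv[1], kv[0][0] is Orientation.FORWARD)
    )
    identity = best / len(read)
    if identity < params.identity_floor:
        raise ReadDropped(read_id, "low_identity")

    other_orient = (
        Orientation.REVERSE if best_orient is Orientation.FORWARD else Orientation.FORWARD
    )
    best_other_orient = max(
        candidates[(other_orient, s)] for s in (Strand.TOP, Strand.BOTTOM)
    )
    ambiguous = best <= 0 or (best - best_other_orient) < params.margin * best

    score_top = max(candidates[(o, Strand.TOP)] for o in Orientation)
    score_bottom = max(candidates[(o, Strand.BOTTOM)] for o in Orientation)
    if ambiguous:
        strand: Strand | None = None
    elif score_top != score_bottom:
        strand = Strand.TOP if score_top > score_bottom else Strand.BOTTOM
    else:
        # no conversion evidence: native-orientation convention
        strand = Strand.TOP if best_orient is Orientation.FORWARD else Strand.BOTTOM

    oriented = read if best_orient is Orientation.FORWARD else rc
    eq = _EQ_TOP if (strand or best_strand) is Strand.TOP else _EQ_BOTTOM
    path = edlib.align(oriented, target, mode="HW", task="path",
                       additionalEqualities=eq)
    t_start, t_end = path["locations"][0]
    return StrandAssignment(
        read_id=read_id,
        strand=strand,
        orientation=best_orient,
        score_top=score_top,
        score_bottom=score_bottom,
        aligned_span=(t_start, t_end + 1),
        identity=identity,
        cigar=path["cigar"] or "",
    )


def extract_conversions(
    assignment: StrandAssignment,
    read: str,
    ref: DonorReference,
) -> ConversionProfile:
    """Score every strand cytosine in the aligned span of one read.

    The read must carry a definite strand call.  Statuses follow the
    deaminated-base rule documented on :class:`ConversionProfile`.
    """
    if assignment.strand is None:
        raise ValueError(f"{assignment.read_id}: ambiguous read has no profile")
    strand = assignment.strand
    oriented = (
        read.upper()
        if assignment.orientation is Orientation.FORWARD
        else revcomp(read.upper())
    )
    lo, hi = assignment.aligned_span
    base_at = _target_to_query(assignment.cigar, lo, oriented)
    positions = ref.cytosines(strand)
    positions = positions[(positions >= lo) & (positions < hi)]
    deaminated, native = ("T", "C") if strand is Strand.TOP else ("A", "G")
    statuses = np.empty(len(positions), dtype=np.int8)
    for i, p in enumerate(positions):
        b = base_at.get(int(p), "")
        if b == deaminated:
            statuses[i] = CONVERTED
        elif b == native:
            statuses[i] = UNCONVERTED
        else:
            statuses[i] = MISSING
    return ConversionProfile(
        assignment.read_id, strand, (lo, hi), positions, statuses
    )


def process_reads(
    reads: Iterable[tuple[str, str]],
    ref: DonorReference,
    params: AlignParams = AlignParams(),
) -> tuple[list[ConversionProfile], list[StrandAssignment], list[tuple[str, str]]]:
    """Run strand assignment + conversion extraction over a read set.

    Returns (profiles, assignments, drops).  Ambiguous reads appear in the
    drop list with reason ``"ambiguous"`` and yield no profile; dropped
    reads (too short / low identity) likewise with their reasons.
    """
    profiles: list[ConversionProfile] = []
    assignments: list[StrandAssignment] = []
    drops: list[tuple[str, str]] = []
    for read_id, seq in reads:
        try:
            asn = align_bisulfite(read_id, seq, ref, params)
        except ReadDropped as exc:
            drops.append((exc.read_id, exc.reason))
            continue
        if asn.ambiguous:
            drops.append((read_id, "ambiguous"))
            continue
        assignments.append(asn)
        profiles.append(extract_conversions(asn, seq, ref))
    return profiles, assignments, drops


def profiles_from_sam(
    sam_path: str,
    ref: DonorReference,
) -> tuple[list[ConversionProfile], list[tuple[str, str]]]:
    """Bypass alignment: build profiles from a pre-aligned SAM/BAM file.

    The stored pairing is trusted; the strand hypothesis is chosen by
    counting matched bases under each (conversion pairs counting as
    matches), with the native-orientation convention breaking ties exactly
    as in :func:`align_bisulfite`.  Unmapped and secondary records are
    dropped.
    """
    import pysam

    profiles: list[ConversionProfile] = []
    drops: list[tuple[str, str]] = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                drops.append((rec.query_name, "unmapped_or_secondary"))
                continue
            pairs = rec.get_aligned_pairs()
            seq = (rec.query_sequence or "").upper()
            base_at: dict[int, str] = {}
            for qpos, rpos in pairs:
                if rpos is None:
                    continue
                base_at[rpos] = seq[qpos] if qpos is not None else ""
            scores = {}
            for strand, (deam, nat) in (
                (Strand.TOP, ("T", "C")),
                (Strand.BOTTOM, ("A", "G")),
            ):
                pos = ref.cytosines(strand)
                s = 0
                for rpos, b in base_at.items():
                    rbase = ref.top_sequence[rpos]
                    if b == rbase:
                        s += 1
                    elif rbase == nat and b == deam:
                        s += 1
                scores[strand] = s
            if scores[Strand.TOP] != scores[Strand.BOTTOM]:
                strand = max(scores, key=scores.get)
            else:
                strand = Strand.BOTTOM if rec.is_reverse else Strand.TOP
            lo = rec.reference_start
            hi = rec.reference_end or lo
            positions = ref.cytosines(strand)
            positions = positions[(positions >= lo) & (positions < hi)]
            deam, nat = ("T", "C") if strand is Strand.TOP else ("A", "G")
            statuses = np.empty(len(positions), dtype=np.int8)
            for i, p in enumerate(positions):
                b = base_at.get(int(p), "")
                statuses[i] = (
                    CONVERTED if b == deam else UNCONVERTED if b == nat else MISSING
                )
            profiles.append(
                ConversionProfile(rec.query_name, strand, (lo, hi), positions, statuses)
            )
    return profiles, drops
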