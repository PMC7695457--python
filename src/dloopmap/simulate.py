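"""Synthetic non-denaturing bisulfite long reads with D-loop ground truth.

The generator emulates the molecule pool the assay sequences: a mixture of
invaded donors carrying one D-loop and unpurified, uninvaded donors, each
contributing full-length amplicon reads from either strand.  On a
top-strand read of an invaded molecule, every cytosine inside the D-loop
interval converts independently with probability ``p_conv`` (displaced
ssDNA exposed to bisulfite).  Every strand cytosine outside that
protection — all cytosines of bottom-strand and uninvaded reads, and the
duplex flanks of invaded top reads — converts with the low background
probability ``p_bg``, emulating transient DNA breathing.  Sequencing
substitution errors are applied last.

What it deliberately does not model: bisulfite reaction kinetics,
incomplete conversion chemistry, PCR amplification bias, indel errors
(optional flag), or multi-invasion molecules.

All randomness flows from a single seeded generator in a fixed draw
order, so a config is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .caller import Footprint
from .reference import DonorReference, Strand, revcomp

__all__ = ["SimConfig", "simulate_sample", "write_fastq", "write_truth_bed",
           "RecoveryReport", "evaluate_recovery"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

TRUTH_COLUMNS = [
    "read_id", "molecule_id", "invaded", "strand", "orientation",
    "dloop_start", "dloop_end", "converted_positions",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    dloop_length:
        Fixed integer, or a ``{"mean", "sd", "min", "max"}`` mapping for a
        truncated normal (max bounded by the homology length).
    dloop_position:
        ``"uniform"`` places the D-loop uniformly within the homology;
        ``three_prime_weight`` in (0, 1] anchors that fraction of D-loops
        at the homology 3' end (mirroring the 3'-end enrichment of
        invasion), the rest uniform.
    strand_mode:
        ``random`` (fair coin per read), ``balanced`` (alternating, for
        stratified samples), ``top`` or ``bottom`` (single-strand pools).
    p_conv / p_bg:
        Per-cytosine conversion probability inside the D-loop on the
        displaced strand / background conversion anywhere unprotected.
    orientation_random:
        Store each read in a random orientation instead of the native
        molecule 5'→3' orientation.
    """

    n_reads: int = 1000
    frac_invaded: float = 0.2
    dloop_length: int | dict = 500
    dloop_position: str | dict = "uniform"
    p_conv: float = 0.7
    p_bg: float = 0.01
    sub_error: float = 0.0
    strand_mode: str = "random"
    orientation_random: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_invaded", "p_conv", "p_bg", "sub_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.strand_mode not in ("random", "balanced", "top", "bottom"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("reference", None)
        data.pop("substrate", None)
        return cls(**data)


def _sample_length(cfg: SimConfig, hom_len: int, rng: np.random.Generator) -> int:
    if isinstance(cfg.dloop_length, (int, float)):
        length = int(cfg.dloop_length)
        if length > hom_len or length < 1:
            raise ValueError(
                f"D-loop length {length} impossible for homology of {hom_len} nt"
            )
        return length
    spec = dict(cfg.dloop_length)
    lo = int(spec.get("min", 1))
    hi = int(spec.get("max", hom_len))
    hi = min(hi, hom_len)
    if lo > hi:
        raise ValueError(f"length model min {lo} > max {hi}")
    mean, sd = float(spec["mean"]), float(spec["sd"])
    # rejection sampling keeps all draws on the single seeded stream
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))
    raise ValueError("truncated-normal length model rejected 10000 draws")


def _sample_interval(
    cfg: SimConfig, length: int, ref: DonorReference, rng: np.random.Generator
) -> tuple[int, int]:
    """D-loop interval (inclusive), always within the homology."""
    hs, he = ref.homology_start, ref.homology_end
    anchored = False
    if isinstance(cfg.dloop_position, dict):
        w = float(cfg.dloop_position.get("three_prime_weight", 0.0))
        anchored = rng.random() < w
    elif cfg.dloop_position != "uniform":
        raise ValueError(f"unknown position model {cfg.dloop_position!r}")
    if anchored:
        start = he - length
    else:
        start = int(rng.integers(hs, he - length + 1))
    return start, start + length - 1


def simulate_sample(
    cfg: SimConfig, ref: DonorReference
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate reads and their ground truth.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` (native or randomized orientation per config)
    and ``truth`` a table with one row per read.  The D-loop interval is
    recorded only on top-strand reads of invaded molecules — the reads on
    which the footprint is observable; bottom-strand reads of invaded
    molecules are heteroduplex-protected and carry background only.
    """
    rng = np.random.default_rng(cfg.seed)
    hom_len = ref.homology_end - ref.homology_start
    top = np.frombuffer(ref.top_sequence.encode(), dtype="S1")
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    for i in range(cfg.n_reads):
        molecule_id = f"mol{i:06d}"
        read_id = f"read{i:06d}"
        invaded = bool(rng.random() < cfg.frac_invaded)
        if invaded:
            length = _sample_length(cfg, hom_len, rng)
            d_start, d_end = _sample_interval(cfg, length, ref, rng)
        else:
            d_start = d_end = None
        if cfg.strand_mode == "random":
            strand = Strand.TOP if rng.random() < 0.5 else Strand.BOTTOM
        elif cfg.strand_mode == "balanced":
            strand = Strand.TOP if i % 2 == 0 else Strand.BOTTOM
        else:
            strand = Strand.TOP if cfg.strand_mode == "top" else Strand.BOTTOM

        cpos = ref.cytosines(strand)
        u = rng.random(len(cpos))
        if invaded and strand is Strand.TOP:
            in_dloop = (cpos >= d_start) & (cpos <= d_end)
            convert = np.where(in_dloop, u < cfg.p_conv, u < cfg.p_bg)
        else:
            convert = u < cfg.p_bg
        converted = cpos[convert]

        seq = top.copy()
        if strand is Strand.TOP:
            seq[converted] = b"T"  # C -> T on the displaced strand
        else:
            seq[converted] = b"A"  # bottom C -> T reads as G -> A in top coords

        if cfg.sub_error > 0:
            err = np.flatnonzero(rng.random(len(seq)) < cfg.sub_error)
            if len(err):
                # replace with a uniformly chosen different base
                cur = seq[err]
                repl = _BASES[rng.integers(0, 3, size=len(err))]
                bump = repl == cur
                repl[bump] = _BASES[3]
                seq[err] = repl

        top_repr = seq.tobytes().decode()
        # native orientation: the read is the molecule 5'->3'
        native = top_repr if strand is Strand.TOP else revcomp(top_repr)
        if cfg.orientation_random and rng.random() < 0.5:
            stored, orientation = revcomp(native), "flipped"
        else:
            stored, orientation = native, "native"

        reads.append((read_id, stored))
        observable = invaded and strand is Strand.TOP
        rows.append(
            {
                "read_id": read_id,
                "molecule_id": molecule_id,
                "invaded": invaded,
                "strand": str(strand),
                "orientation": orientation,
                "dloop_start": d_start if observable else pd.NA,
                "dloop_end": d_end if observable else pd.NA,
                "converted_positions": ",".join(map(str, converted.tolist())),
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).astype(
        {"dloop_start": "Int64", "dloop_end": "Int64"}
    )
    return reads, truth


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with a constant quality character."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_bed(truth: pd.DataFrame, path: str | Path, name: str) -> None:
    """BED6 of truth D-loop intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for row in truth.itertuples():
            if pd.isna(row.dloop_start):
                continue
            fh.write(
                f"{name}\t{int(row.dloop_start)}\t{int(row.dloop_end) + 1}"
                f"\t{row.read_id}\t0\t+\n"
            )


@dataclass
class RecoveryReport:
    """Caller performance against simulator ground truth."""

    n_truth: int
    n_detected: int
    detection_rate: float | None
    n_bottom_reads: int
    n_bottom_with_call: int
    bottom_false_call_rate: float | None
    median_abs_start_error: float | None
    median_abs_end_error: float | None
    median_abs_span_error: float | None


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Min of the two mutual overlap fractions of inclusive intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def evaluate_recovery(
    footprints: Iterable[Footprint] | pd.DataFrame,
    truth: pd.DataFrame,
    min_reciprocal: float = 0.5,
) -> RecoveryReport:
    """Score called footprints against simulator truth.

    A truth D-loop counts as detected when some called footprint on the
    same read overlaps it reciprocally by at least ``min_reciprocal``
    (intersection ≥ that fraction of both intervals).  Boundary errors are
    medians of |called − truth| over detected D-loops, using the
    best-overlapping footprint.  The bottom false-call rate is the
    fraction of bottom-strand reads carrying any called footprint.
    """
    from .summarize import footprints_to_frame

    fp = (
        footprints
        if isinstance(footprints, pd.DataFrame)
        else footprints_to_frame(footprints)
    )
    by_read: dict[str, list[tuple[int, int]]] = {}
    for row in fp.itertuples():
        by_read.setdefault(row.read_id, []).append((int(row.start), int(row.end)))

    start_err, end_err, span_err = [], [], []
    n_truth = n_detected = 0
    for row in truth.itertuples():
        if pd.isna(row.dloop_start):
            continue
        n_truth += 1
        t_iv = (int(row.dloop_start), int(row.dloop_end))
        best, best_ov = None, 0.0
        for c_iv in by_read.get(row.read_id, []):
            ov = _reciprocal_overlap(t_iv, c_iv)
            if ov > best_ov:
                best, best_ov = c_iv, ov
        if best is not None and best_ov >= min_reciprocal:
            n_detected += 1
            start_err.append(abs(best[0] - t_iv[0]))
            end_err.append(abs(best[1] - t_iv[1]))
            span_err.append(
                abs((best[1] - best[0] + 1) - (t_iv[1] - t_iv[0] + 1))
            )

    bottom = truth[truth["strand"] == "BOTTOM"]
    n_bottom = len(bottom)
    n_bottom_call = int(bottom["read_id"].isin(by_read).sum())
    return RecoveryReport(
        n_truth=n_truth,
        n_detected=n_detected,
        detection_rate=(n_detected / n_truth) if n_truth else None,
        n_bottom_reads=n_bottom,
        n_bottom_with_call=n_bottom_call,
        bottom_false_call_rate=(n_bottom_call / n_bottom) if n_bottom else None,
        median_abs_start_error=float(np.median(start_err)) if start_err else None,
        median_abs_end_error=float(np.median(end_err)) if end_err else None,
        median_abs_span_error=float(np.median(span_err)) if span_err else None,
    )
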