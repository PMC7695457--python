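"""Sample-level summaries of called D-loop footprints.

The assay's headline statistic is the percentage of top-strand reads that
contain at least one footprint ("% D-loops"); because only the displaced
top strand is exposed to bisulfite inside a D-loop, the same percentage on
the bottom strand measures the false-call floor, and their ratio the
strand specificity of the assay.  Footprint spans feed length statistics
and length clusters; footprint intervals feed non-exclusive positional
bins across the homology region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import Footprint
from .reference import DonorReference, Strand

__all__ = [
    "SampleSummary",
    "summarize_sample",
    "default_cluster_edges",
    "assign_length_clusters",
    "bin_positions_nonexclusive",
    "order_reads_for_map",
    "pearson_r",
    "footprints_to_frame",
]

logger = logging.getLogger(__name__)


def footprints_to_frame(footprints: Iterable[Footprint]) -> pd.DataFrame:
    """Footprint list -> tidy table (one row per footprint)."""
    rows = [
        {
            "read_id": f.read_id,
            "strand": str(f.strand),
            "start": f.start,
            "end": f.end,
            "span_nt": f.span_nt,
            "n_cytosines": f.n_cytosines,
            "n_converted": f.n_converted,
            "conv_fraction": f.conv_fraction,
        }
        for f in footprints
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "strand", "start", "end", "span_nt",
            "n_cytosines", "n_converted", "conv_fraction",
        ],
    )


@dataclass
class SampleSummary:
    """Aggregated statistics for one sequencing sample."""

    n_total: dict[str, int]
    n_with_footprint: dict[str, int]
    pct_with_footprint: dict[str, float | None]
    strand_fold: float | None
    lengths: list[int]
    length_mean: float | None
    length_sd: float | None
    length_sem: float | None
    cluster_table: pd.DataFrame | None = None
    bin_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_with_footprint": self.n_with_footprint,
            "pct_with_footprint": self.pct_with_footprint,
            "strand_fold": self.strand_fold,
            "n_footprints": len(self.lengths),
            "length_mean": self.length_mean,
            "length_sd": self.length_sd,
            "length_sem": self.length_sem,
        }
        if self.cluster_table is not None:
            d["length_clusters"] = {
                r.cluster: {"count": int(r.count), "pct": float(r.pct)}
                for r in self.cluster_table.itertuples()
            }
        if self.bin_table is not None:
            d["position_bins"] = {
                f"{int(r.bin_start)}-{int(r.bin_end)}": float(r.pct)
                for r in self.bin_table.itertuples()
            }
        return d


def summarize_sample(
    footprints: Iterable[Footprint] | pd.DataFrame,
    read_tallies: Mapping[Strand | str, int],
    ref: DonorReference | None = None,
    cluster_edges: Sequence[int] | None = None,
    bin_nt: int = 100,
) -> SampleSummary:
    """Aggregate footprints into per-strand percentages and distributions.

    ``read_tallies`` maps each strand to the total assigned reads on it.
    "% D-loops" counts reads with at least one footprint, once; each
    footprint of a multi-footprint read still contributes individually to
    the length and position distributions.  The strand fold is
    pct_top/pct_bottom, infinite when no bottom-strand read has a
    footprint; a strand with zero reads has no percentage and the fold is
    undefined (``None``).  Length SD is the sample SD (n−1); SEM = SD/√n.
    Cluster and positional-bin tables are computed when ``ref`` is given.
    """
    fp = (
        footprints
        if isinstance(footprints, pd.DataFrame)
        else footprints_to_frame(footprints)
    )
    tallies = {str(Strand(k)): int(v) for k, v in read_tallies.items()}
    n_total = {s: tallies.get(s, 0) for s in ("TOP", "BOTTOM")}
    n_with = {
        s: int(fp.loc[fp["strand"] == s, "read_id"].nunique())
        for s in ("TOP", "BOTTOM")
    }
    pct = {
        s: (100.0 * n_with[s] / n_total[s]) if n_total[s] > 0 else None
        for s in ("TOP", "BOTTOM")
    }
    if pct["TOP"] is None or pct["BOTTOM"] is None:
        fold: float | None = None
    elif pct["BOTTOM"] == 0.0:
        fold = math.inf if pct["TOP"] > 0 else None
    else:
        fold = pct["TOP"] / pct["BOTTOM"]

    lengths = fp["span_nt"].tolist()
    if lengths:
        arr = np.asarray(lengths, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        sem = sd / math.sqrt(len(arr))
    else:
        mean = sd = sem = None

    cluster_table = bin_table = None
    if ref is not None and len(fp):
        edges = (
            list(cluster_edges)
            if cluster_edges is not None
            else default_cluster_edges(ref)
        )
        _, cluster_table = assign_length_clusters(fp["span_nt"], edges)
        bin_table = bin_positions_nonexclusive(fp, ref, bin_nt=bin_nt)

    return SampleSummary(
        n_total=n_total,
        n_with_footprint=n_with,
        pct_with_footprint=pct,
        strand_fold=fold,
        lengths=lengths,
        length_mean=mean,
        length_sd=sd,
        length_sem=sem,
        cluster_table=cluster_table,
        bin_table=bin_table,
    )


def default_cluster_edges(ref: DonorReference) -> list[int]:
    """Contiguous 250-nt length clusters up to the homology length.

    For a 931-nt homology this yields the clusters 0–249, 250–499,
    500–749 and 750–930.
    """
    hom_len = ref.homology_end - ref.homology_start
    edges = list(range(0, hom_len, 250))
    edges.append(hom_len)
    if len(edges) < 2:
        edges = [0, hom_len]
    return edges


def cluster_labels(edges: Sequence[int]) -> list[str]:
    return [f"{edges[i]}-{edges[i + 1] - 1}" for i in range(len(edges) - 1)]


def assign_length_clusters(
    spans: Sequence[int] | pd.Series,
    edges: Sequence[int],
) -> tuple[list[str], pd.DataFrame]:
    """Assign each footprint span to exactly one length cluster.

    Cluster ``i`` covers spans in ``[edges[i], edges[i+1])``; labels are
    inclusive ("0-249" covers 0 ≤ span ≤ 249).  Spans beyond the last edge
    fall into the final cluster with a warning.  Percentages are relative
    to the total footprints in the sample, so samples with different
    absolute D-loop levels remain comparable.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"cluster edges must be strictly increasing: {edges}")
    labels = cluster_labels(edges)
    spans = np.asarray(spans, dtype=np.int64)
    idx = np.searchsorted(edges, spans, side="right") - 1
    n_over = int(np.count_nonzero(idx >= len(labels)))
    if n_over:
        logger.warning(
            "%d footprint(s) longer than the last cluster edge %d; "
            "assigned to cluster %r", n_over, edges[-1], labels[-1],
        )
    idx = np.clip(idx, 0, len(labels) - 1)
    if np.any(spans < edges[0]):
        raise ValueError("footprint span below the first cluster edge")
    assigned = [labels[i] for i in idx]
    counts = pd.Series(assigned).value_counts()
    table = pd.DataFrame(
        {
            "cluster": labels,
            "count": [int(counts.get(l, 0)) for l in labels],
        }
    )
    total = table["count"].sum()
    table["pct"] = 100.0 * table["count"] / total if total else 0.0
    return assigned, table


def bin_positions_nonexclusive(
    footprints: pd.DataFrame | Iterable[Footprint],
    ref: DonorReference,
    bin_nt: int = 100,
) -> pd.DataFrame:
    """Non-exclusive positional binning across the homology region.

    Bins of ``bin_nt`` nt are anchored at the homology start (the last bin
    may be short); every footprint increments every bin its inclusive
    interval overlaps, and per-bin values are percentages of total
    footprints — so the values need not sum to 100.
    """
    fp = (
        footprints
        if isinstance(footprints, pd.DataFrame)
        else footprints_to_frame(footprints)
    )
    starts = np.arange(ref.homology_start, ref.homology_end, bin_nt)
    ends = np.minimum(starts + bin_nt, ref.homology_end)  # half-open
    n_fp = len(fp)
    counts = np.zeros(len(starts), dtype=np.int64)
    if n_fp:
        s = fp["start"].to_numpy()[:, None]
        e = fp["end"].to_numpy()[:, None]
        overlap = (s < ends[None, :]) & (e >= starts[None, :])
        counts = overlap.sum(axis=0)
    return pd.DataFrame(
        {
            "bin_start": starts,
            "bin_end": ends - 1,
            "count": counts,
            "pct": 100.0 * counts / n_fp if n_fp else 0.0,
        }
    )


def order_reads_for_map(
    footprints: pd.DataFrame | Iterable[Footprint],
    mode: str = "position",
    cluster_edges: Sequence[int] | None = None,
    ref: DonorReference | None = None,
) -> list[str]:
    """Deterministic row order for a footprint map.

    Each read is keyed by its first (leftmost) footprint.  Mode
    ``position`` orders reads 5'→3' by footprint start, ties broken by
    span (longest first) then read id; ``length_then_position`` groups
    reads by length cluster first, then orders by start within each
    cluster.
    """
    fp = (
        footprints
        if isinstance(footprints, pd.DataFrame)
        else footprints_to_frame(footprints)
    )
    if fp.empty:
        return []
    first = (
        fp.sort_values(["read_id", "start"])
        .groupby("read_id", as_index=False)
        .first()
    )
    if mode == "position":
        first = first.sort_values(
            ["start", "span_nt", "read_id"], ascending=[True, False, True]
        )
    elif mode == "length_then_position":
        if cluster_edges is None:
            if ref is None:
                raise ValueError("length_then_position needs cluster_edges or ref")
            cluster_edges = default_cluster_edges(ref)
        edges = list(cluster_edges)
        idx = np.clip(
            np.searchsorted(edges, first["span_nt"], side="right") - 1,
            0,
            len(edges) - 2,
        )
        first = first.assign(_cluster=idx).sort_values(
            ["_cluster", "start", "read_id"], ascending=[False, True, True]
        )
    else:
        raise ValueError(f"unknown ordering mode {mode!r}")
    return first["read_id"].tolist()


def pearson_r(pairs: Sequence[tuple[float, float]] | pd.DataFrame) -> float:
    """Product-moment correlation between assay and gel quantifications.

    Requires at least 3 pairs and non-zero variance on both axes.
    """
    if isinstance(pairs, pd.DataFrame):
        x = pairs.iloc[:, 0].to_numpy(dtype=float)
        y = pairs.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
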