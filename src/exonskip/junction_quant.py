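"""Junction-read-based isoform quantification.

Counts spliced alignments whose gap operator matches a junction exactly,
turns inclusion/skip junction counts into a skip ratio, scales a gene-level
normalized expression value into per-isoform expression, and summarizes a
cohort.

Counting rules: only primary, mapped, non-duplicate alignments are counted;
a gap matches a junction when its reference boundaries equal the junction's
``(gap_start, gap_end)`` exactly and the alignment has at least
``min_anchor`` aligned (match-operator) bases on each side of the gap.
Reads are counted regardless of orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 1000.0
DEFAULT_MIN_ANCHOR = 3

# CIGAR operation codes (pysam numeric encoding)
_CONSUMES_REF_ALIGNED = {0, 7, 8}   # M, =, X
_CONSUMES_REF_ONLY = {2}            # D
_GAP = 3                            # N


@dataclass(frozen=True)
class JunctionCounts:
    """Per-sample junction and library counts."""

    sample_id: str
    n_e3e4: int
    n_e3e5: int
    exon3_reads: int
    total_reads: int
    gene_deseq: float

    def __post_init__(self) -> None:
        for name in ("n_e3e4", "n_e3e5", "exon3_reads", "total_reads"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.exon3_reads > self.total_reads:
            raise ValueError("exon3_reads cannot exceed total_reads")
        if self.gene_deseq < 0:
            raise ValueError("gene_deseq must be non-negative")


@dataclass(frozen=True)
class IsoformExpression:
    """Per-sample isoform expression derived from the skip ratio.

    ``rel_level`` (skipping/inclusion expression ratio) is ``None`` when the
    inclusion expression is zero.
    """

    sample_id: str
    skip_ratio: float | None
    wt_expr: float
    de4_expr: float
    rel_level: float | None
    positive: bool


def spliced_gaps(
    cigartuples: Sequence[tuple[int, int]], reference_start: int
) -> list[tuple[int, int, int, int]]:
    """Extract gap operators from a CIGAR.

    Returns ``(gap_start, gap_end, left_anchor, right_anchor)`` per gap,
    where the anchors count aligned match-operator bases between this gap
    and the nearest read end or neighbouring gap.
    """
    segments: list[int] = [0]       # aligned bases per inter-gap segment
    gaps: list[tuple[int, int, int]] = []  # (start, end, segment index left of gap)
    pos = reference_start
    for op, length in cigartuples:
        if op in _CONSUMES_REF_ALIGNED:
            segments[-1] += length
            pos += length
        elif op in _CONSUMES_REF_ONLY:
            pos += length
        elif op == _GAP:
            gaps.append((pos, pos + length, len(segments) - 1))
            segments.append(0)
            pos += length
        # I, S, H, P do not consume reference
    return [
        (start, end, segments[i], segments[i + 1]) for start, end, i in gaps
    ]


def _iter_alignments(alignments) -> Iterator:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def count_junction_reads(
    alignments,
    junction: tuple[int, int],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> int:
    """Count primary, non-duplicate spliced alignments matching ``junction``.

    ``alignments`` may be a SAM/BAM path or an iterable of
    :class:`pysam.AlignedSegment`.  A read is counted when one of its gap
    operators has reference boundaries exactly equal to ``junction`` and at
    least ``min_anchor`` aligned bases flank the gap on both sides.
    Malformed records are skipped with a warning.
    """
    gap_start, gap_end = junction
    if gap_end <= gap_start:
        raise ValueError(f"junction end must exceed start, got {junction}")
    n = 0
    for read in _iter_alignments(alignments):
        try:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            cig = read.cigartuples
            if not cig:
                continue
            for g_start, g_end, left, right in spliced_gaps(cig, read.reference_start):
                if (
                    g_start == gap_start
                    and g_end == gap_end
                    and left >= min_anchor
                    and right >= min_anchor
                ):
                    n += 1
                    break
        except (ValueError, AttributeError) as exc:  # malformed record
            logger.warning("skipping malformed alignment record: %s", exc)
    return n


def count_total_reads(alignments) -> int:
    """Total mapped primary non-duplicate reads (library-size proxy)."""
    n = 0
    for read in _iter_alignments(alignments):
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        n += 1
    return n


def count_region_reads(alignments, reference_start: int, reference_end: int) -> int:
    """Count primary mapped reads with any aligned base in [start, end)."""
    n = 0
    for read in _iter_alignments(alignments):
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        for b_start, b_end in read.get_blocks():
            if b_start < reference_end and b_end > reference_start:
                n += 1
                break
    return n


def skip_ratio(n_e3e4: int, n_e3e5: int) -> float | None:
    """Fraction of junction evidence supporting skipping.

    Returns ``n_e3e5 / (n_e3e4 + n_e3e5)``, or ``None`` (undefined, distinct
    from 0) when both counts are zero.
    """
    if n_e3e4 < 0 or n_e3e5 < 0:
        raise ValueError("junction counts must be non-negative")
    total = n_e3e4 + n_e3e5
    if total == 0:
        return None
    return n_e3e5 / total


def exon3_deseq(exon3_reads: int, total_reads: int, gene_deseq: float) -> float:
    """Exon-level normalized expression: ``(exon3_reads / total_reads) * gene_deseq``."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if exon3_reads < 0:
        raise ValueError("exon3_reads must be non-negative")
    return (exon3_reads / total_reads) * gene_deseq


def isoform_expression(
    sample_id: str,
    skip_ratio: float | None,
    norm_expr: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> IsoformExpression:
    """Partition a normalized expression value between the two isoforms.

    The skipping isoform gets ``skip_ratio * norm_expr`` and the inclusion
    isoform the remainder; the sample is flagged positive when the skipping
    expression reaches ``cutoff`` (inclusive).  An undefined ratio (``None``)
    yields zero for both isoforms and a negative flag.
    """
    if norm_expr < 0:
        raise ValueError("norm_expr must be non-negative")
    if skip_ratio is None:
        return IsoformExpression(sample_id, None, 0.0, 0.0, None, False)
    if not 0.0 <= skip_ratio <= 1.0:
        raise ValueError(f"skip_ratio must lie in [0, 1], got {skip_ratio}")
    de4 = skip_ratio * norm_expr
    wt = (1.0 - skip_ratio) * norm_expr
    rel = de4 / wt if wt > 0 else None
    return IsoformExpression(sample_id, skip_ratio, wt, de4, rel, de4 >= cutoff)


def quantify_sample(
    sample_id: str,
    alignments,
    gene_model,
    gene_deseq: float,
    total_reads: int | None = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[JunctionCounts, IsoformExpression]:
    """Run the full per-sample quantification chain on one alignment file.

    When ``total_reads`` is not supplied it is counted from the file.
    """
    path = str(alignments)
    e3 = gene_model.exons[0]
    n_incl = count_junction_reads(path, gene_model.junction_inclusion, min_anchor)
    n_skip = count_junction_reads(path, gene_model.junction_skip, min_anchor)
    exon3_reads = count_region_reads(path, e3.start, e3.end)
    if total_reads is None:
        total_reads = count_total_reads(path)
    counts = JunctionCounts(sample_id, n_incl, n_skip, exon3_reads, total_reads, gene_deseq)
    ratio = skip_ratio(n_incl, n_skip)
    e3_expr = exon3_deseq(exon3_reads, total_reads, gene_deseq) if total_reads else 0.0
    expr = isoform_expression(sample_id, ratio, e3_expr, cutoff)
    return counts, expr


def cohort_summary(
    expr: Iterable[IsoformExpression],
    bin_width: float = 1000.0,
    rel_breaks: Sequence[float] = (0.10, 0.20),
) -> dict:
    """Cohort-level histograms and fractions.

    Returns histogram counts of inclusion and skipping expression in bins of
    ``bin_width``, the fraction of positive samples, and the fraction of
    samples whose relative level falls in each interval delimited by
    ``rel_breaks`` (samples with undefined relative level are excluded from
    the relative-level fractions but reported separately).
    """
    expr = list(expr)
    if not expr:
        raise ValueError("cohort is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    wt = np.array([e.wt_expr for e in expr])
    de4 = np.array([e.de4_expr for e in expr])
    top = max(wt.max(), de4.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] <= top:
        edges = np.append(edges, edges[-1] + bin_width)
    wt_hist, _ = np.histogram(wt, bins=edges)
    de4_hist, _ = np.histogram(de4, bins=edges)

    rel = [e.rel_level for e in expr if e.rel_level is not None]
    breaks = sorted(rel_breaks)
    rel_edges = [-math.inf, *breaks, math.inf]
    rel_fracs = []
    for lo, hi in zip(rel_edges, rel_edges[1:]):
        count = sum(1 for r in rel if lo <= r < hi) if rel else 0
        rel_fracs.append(count / len(rel) if rel else math.nan)

    return {
        "n": len(expr),
        "bin_edges": edges.tolist(),
        "wt_hist": wt_hist.tolist(),
        "de4_hist": de4_hist.tolist(),
        "positive_fraction": sum(e.positive for e in expr) / len(expr),
        "rel_breaks": breaks,
        "rel_fractions": rel_fracs,
        "rel_undefined": sum(1 for e in expr if e.rel_level is None),
    }
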