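"""Shared fixtures and independent oracles.

The SAM oracle here re-derives gap coordinates from raw SAM text with its
own CIGAR walker so junction counting can be checked against an
implementation that shares no code with the package.
"""

from __future__ import annotations

import re

import pytest

from exonskip.gene_model import Exon, GeneModel

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_SKIP_FLAGS = 0x4 | 0x100 | 0x400 | 0x800  # unmapped, secondary, duplicate, supplementary


def brute_force_junction_count(sam_path, junction, min_anchor=3) -> int:
    """Independent per-record junction counter operating on raw SAM text."""
    gap_start, gap_end = junction
    count = 0
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if int(fields[1]) & _SKIP_FLAGS:
                continue
            cigar = fields[5]
            if cigar == "*":
                continue
            ref = int(fields[3]) - 1  # SAM is 1-based
            run = 0           # aligned bases since read start or last gap
            runs = []         # aligned bases per inter-gap segment
            gaps = []
            for length, op in _CIGAR_RE.findall(cigar):
                length = int(length)
                if op in "M=X":
                    run += length
                    ref += length
                elif op == "D":
                    ref += length
                elif op == "N":
                    gaps.append((ref, ref + length))
                    runs.append(run)
                    run = 0
                    ref += length
            runs.append(run)
            for i, (g_s, g_e) in enumerate(gaps):
                if (
                    g_s == gap_start and g_e == gap_end
                    and runs[i] >= min_anchor and runs[i + 1] >= min_anchor
                ):
                    count += 1
                    break
    return count


@pytest.fixture
def gene_model() -> GeneModel:
    """Cassette model with exons at [100,200), [300,433), [500,600)."""
    return GeneModel(
        reference_name="chrT",
        strand="+",
        exons=(Exon("E3", 100, 200), Exon("E4", 300, 433), Exon("E5", 500, 600)),
    )


@pytest.fixture
def json_model_file(tmp_path):
    import json

    path = tmp_path / "model.json"
    path.write_text(json.dumps({
        "reference_name": "chrT",
        "strand": "+",
        "gene_id": "GENE1",
        "coordinate_system": "zero_half_open",
        "exons": [
            {"label": "E3", "start": 100, "end": 200},
            {"label": "E4", "start": 300, "end": 433},
            {"label": "E5", "start": 500, "end": 600},
        ],
    }))
    return path
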