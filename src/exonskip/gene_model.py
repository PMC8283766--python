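"""Gene model: exon coordinates and the two splice junctions of a cassette event.

A :class:`GeneModel` holds three labelled exons (the flanking upstream exon,
the cassette exon, and the flanking downstream exon) on one reference
sequence, plus the two junctions they define:

* the *inclusion* junction joining the upstream exon to the cassette exon, and
* the *skip* junction joining the upstream exon directly to the downstream
  exon.

All coordinates are 0-based half-open internally; every reader normalizes on
input.  Junctions are stored as ``(gap_start, gap_end)`` in reference
coordinates — the same convention a spliced alignment's gap operator uses —
so they can be compared to alignment gaps directly, regardless of strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


class GeneModelError(ValueError):
    """Raised when a gene-model file is missing data or fails validation."""


@dataclass(frozen=True)
class Exon:
    label: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GeneModelError(
                f"exon {self.label!r}: end ({self.end}) must be > start ({self.start})"
            )


@dataclass(frozen=True)
class GeneModel:
    """Three exons of one gene and the junctions of the cassette event.

    ``exons`` are in transcript order (upstream, cassette, downstream).
    ``junction_inclusion`` and ``junction_skip`` are ``(gap_start, gap_end)``
    reference-coordinate intervals spanning the introns that a spliced read
    supporting each isoform must bridge exactly.
    """

    reference_name: str
    strand: str
    exons: tuple[Exon, Exon, Exon]
    junction_inclusion: tuple[int, int] = field(init=False)
    junction_skip: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) != 3:
            raise GeneModelError("a cassette model needs exactly three exons")
        by_coord = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if b.start < a.end:
                raise GeneModelError(
                    f"exons {a.label!r} and {b.label!r} overlap"
                )
        e3, e4, e5 = self.exons
        if self.strand == "+":
            if not (e3.end <= e4.start and e4.end <= e5.start):
                raise GeneModelError(
                    "exons must be in ascending coordinate order on the + strand"
                )
            inclusion = (e3.end, e4.start)
            skip = (e3.end, e5.start)
        else:
            # transcript order runs right-to-left on the reference
            if not (e5.end <= e4.start and e4.end <= e3.start):
                raise GeneModelError(
                    "exons must be in descending coordinate order on the - strand"
                )
            inclusion = (e4.end, e3.start)
            skip = (e5.end, e3.start)
        object.__setattr__(self, "junction_inclusion", inclusion)
        object.__setattr__(self, "junction_skip", skip)

    @property
    def donor_position(self) -> int:
        """Reference coordinate shared by both junctions (edge of the upstream exon)."""
        return self.junction_inclusion[0] if self.strand == "+" else self.junction_inclusion[1]


def _model_from_labelled_exons(
    reference_name: str,
    strand: str,
    exons: Sequence[Exon],
    exon_labels: Sequence[str],
) -> GeneModel:
    by_label = {e.label: e for e in exons}
    missing = [lab for lab in exon_labels if lab not in by_label]
    if missing:
        raise GeneModelError(
            f"exon label(s) {missing} not found; available: {sorted(by_label)}"
        )
    picked = tuple(by_label[lab] for lab in exon_labels)
    return GeneModel(reference_name=reference_name, strand=strand, exons=picked)


def _load_json(path: Path, gene_id: str, exon_labels: Sequence[str]) -> GeneModel:
    """JSON exon-table dialect::

        {"reference_name": "chr20", "strand": "+", "gene_id": "GENE",
         "coordinate_system": "zero_half_open",   # or "one_inclusive"
         "exons": [{"label": "E3", "start": 100, "end": 200}, ...]}

    ``coordinate_system`` defaults to ``zero_half_open``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("gene_id") != gene_id:
        raise GeneModelError(
            f"gene {gene_id!r} not found in {path} (file declares {doc.get('gene_id')!r})"
        )
    system = doc.get("coordinate_system", "zero_half_open")
    if system not in ("zero_half_open", "one_inclusive"):
        raise GeneModelError(f"unknown coordinate_system {system!r}")
    offset = 1 if system == "one_inclusive" else 0
    exons = [
        Exon(label=e["label"], start=int(e["start"]) - offset, end=int(e["end"]))
        for e in doc["exons"]
    ]
    return _model_from_labelled_exons(
        doc["reference_name"], doc.get("strand", "+"), exons, exon_labels
    )


def _load_bed12(path: Path, gene_id: str, exon_labels: Sequence[str]) -> GeneModel:
    """BED12: the record whose name field equals ``gene_id`` provides the blocks.

    Blocks are labelled ``E1..En`` in transcript order (reversed on the
    - strand), then the requested labels are selected.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GeneModelError(f"{path}: not BED12 (found {len(fields)} columns)")
            if fields[3] != gene_id:
                continue
            chrom = fields[0]
            chrom_start = int(fields[1])
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(s) for s in fields[10].rstrip(",").split(",")]
            starts = [int(s) for s in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise GeneModelError(f"{path}: block count mismatch for {gene_id!r}")
            blocks = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            order = blocks if strand == "+" else blocks[::-1]
            exons = [
                Exon(label=f"E{i + 1}", start=s, end=e)
                for i, (s, e) in enumerate(order)
            ]
            return _model_from_labelled_exons(chrom, strand, exons, exon_labels)
    raise GeneModelError(f"gene {gene_id!r} not found in {path}")


def _load_gff3(path: Path, gene_id: str, exon_labels: Sequence[str]) -> GeneModel:
    """GFF3: exon features belonging to ``gene_id``.

    An exon belongs to the gene when ``gene_id``, ``gene``, ``Parent`` or
    ``ID`` mentions it.  Labels come from the ``Name`` (or ``exon_id``)
    attribute; unlabelled exons get ``E1..En`` in transcript order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    def belongs(feature) -> bool:
        for key in ("gene_id", "gene", "Parent", "ID"):
            for value in feature.attributes.get(key, []):
                if gene_id == value or value.endswith(f":{gene_id}") or value.startswith(f"{gene_id}."):
                    return True
        return False

    raw = [f for f in db.features_of_type("exon") if belongs(f)]
    if not raw:
        raise GeneModelError(f"gene {gene_id!r} has no exon features in {path}")
    strand = raw[0].strand if raw[0].strand in ("+", "-") else "+"
    raw.sort(key=lambda f: f.start, reverse=(strand == "-"))
    exons = []
    for i, f in enumerate(raw):
        names = f.attributes.get("Name", []) or f.attributes.get("exon_id", [])
        label = names[0] if names else f"E{i + 1}"
        # GFF3 is 1-based inclusive
        exons.append(Exon(label=label, start=f.start - 1, end=f.end))
    return _model_from_labelled_exons(raw[0].seqid, strand, exons, exon_labels)


def load_gene_model(
    path: str | Path,
    gene_id: str,
    exon_labels: Sequence[str] = ("E3", "E4", "E5"),
) -> GeneModel:
    """Load a three-exon cassette model from GFF3, BED12 or the JSON dialect.

    The format is chosen by file extension (``.json``, ``.bed``, otherwise
    GFF3).  Coordinates are converted to 0-based half-open regardless of the
    input dialect.

    Parameters
    ----------
    path:
        Gene-model file.
    gene_id:
        Gene identifier to look up in the file.
    exon_labels:
        Labels of the upstream, cassette and downstream exons, in transcript
        order.

    Raises
    ------
    GeneModelError
        If the gene or a named exon is missing, or the exons fail validation.
    """
    path = Path(path)
    if len(exon_labels) != 3:
        raise GeneModelError("exactly three exon labels are required")
    suffix = path.suffix.lower()
    if suffix == ".json":
        return _load_json(path, gene_id, exon_labels)
    if suffix in (".bed", ".bed12"):
        return _load_bed12(path, gene_id, exon_labels)
    return _load_gff3(path, gene_id, exon_labels)
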