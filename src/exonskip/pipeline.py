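"""End-to-end orchestration: quantify -> signature -> survival report.

Each run writes its outputs plus a manifest (config echo, package version,
seed, warnings) so every reported number can be re-derived by calling the
underlying module operation on the recorded inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .gene_model import load_gene_model
from .junction_quant import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_ANCHOR,
    cohort_summary,
    quantify_sample,
)
from .signature import SUBTYPES, assignments_to_frame, build_assignments
from .survival import kruskal_wallis, pearson_corr, table1_report

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STATISTICAL = 3


@dataclass
class RunConfig:
    """Configuration shared by the pipeline stages; see the CLI for defaults."""

    out_dir: Path
    alignments: Mapping[str, str] = field(default_factory=dict)  # sample -> SAM/BAM
    gene_model_path: str | None = None
    gene_id: str | None = None
    exon_labels: tuple[str, str, str] = ("E3", "E4", "E5")
    gene_deseq: Mapping[str, float] = field(default_factory=dict)
    expression_path: str | None = None
    clinical_path: str | None = None
    cutoff: float = DEFAULT_CUTOFF
    min_anchor: int = DEFAULT_MIN_ANCHOR
    dichotomize_scope: str = "cohort"
    horizon: float | None = 120.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.out_dir = Path(self.out_dir)


def _config_digest(cfg: RunConfig) -> str:
    payload = {k: (str(v) if isinstance(v, Path) else v)
               for k, v in vars(cfg).items()}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, stage: str, extra: dict) -> Path:
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config_hash": _config_digest(cfg),
        "seed": cfg.seed,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in vars(cfg).items()},
        **extra,
    }
    path = cfg.out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


def run_quantify(cfg: RunConfig) -> pd.DataFrame:
    """Quantify every configured alignment file; write TSV + manifest.

    Samples that fail to parse are skipped, listed in the manifest, and the
    run continues.
    """
    if not cfg.alignments or cfg.gene_model_path is None or cfg.gene_id is None:
        raise ValueError("quantify stage needs alignments, a gene model and a gene id")
    gm = load_gene_model(cfg.gene_model_path, cfg.gene_id, cfg.exon_labels)
    rows, failures = [], []
    for sample_id, path in sorted(cfg.alignments.items()):
        try:
            counts, expr = quantify_sample(
                sample_id, path, gm,
                gene_deseq=float(cfg.gene_deseq.get(sample_id, 0.0)),
                min_anchor=cfg.min_anchor, cutoff=cfg.cutoff,
            )
        except (OSError, ValueError) as exc:
            logger.warning("sample %s failed to quantify: %s", sample_id, exc)
            failures.append({"sample_id": sample_id, "error": str(exc)})
            continue
        rows.append({
            "sample_id": sample_id,
            "n_e3e4": counts.n_e3e4,
            "n_e3e5": counts.n_e3e5,
            "exon3_reads": counts.exon3_reads,
            "total_reads": counts.total_reads,
            "gene_deseq": counts.gene_deseq,
            "skip_ratio": expr.skip_ratio,
            "wt_expr": expr.wt_expr,
            "de4_expr": expr.de4_expr,
            "rel_level": expr.rel_level,
            "positive": expr.positive,
        })
    table = pd.DataFrame(rows)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(cfg.out_dir / "isoform_expression.tsv", sep="\t", index=False)
    _write_manifest(cfg, "quantify", {
        "n_samples": len(rows),
        "failed_samples": failures,
        "junction_inclusion": list(gm.junction_inclusion),
        "junction_skip": list(gm.junction_skip),
    })
    return table


def run_clinical(cfg: RunConfig,
                 expression: pd.DataFrame | None = None,
                 clinical: pd.DataFrame | None = None) -> dict:
    """Signature + survival report + association statistics; write everything.

    Tables may be passed in memory or read from the configured TSV paths.
    """
    if expression is None:
        if cfg.expression_path is None:
            raise ValueError("no expression table provided")
        expression = pd.read_csv(cfg.expression_path, sep="\t")
    if clinical is None:
        if cfg.clinical_path is None:
            raise ValueError("no clinical table provided")
        clinical = pd.read_csv(cfg.clinical_path, sep="\t")
    if expression.empty or clinical.empty:
        raise ValueError("expression and clinical tables must be non-empty")
    shared = set(expression["sample_id"]) & set(clinical["sample_id"])
    if not shared:
        raise ValueError("expression and clinical tables share no sample ids")

    assignments, assign_meta = build_assignments(
        expression, clinical, scope=cfg.dichotomize_scope,
        e3_col="exon3_expr" if "exon3_expr" in expression.columns else None,
    )
    assign_df = assignments_to_frame(assignments)

    markers = {"wt": "wt_expr", "de4": "de4_expr", "signature": "signature"}
    if "exon3_expr" in expression.columns:
        markers = {"e3": "exon3_expr", **markers}
    report, report_meta = table1_report(
        expression, clinical, markers=markers, subclasses=list(SUBTYPES),
        horizon=cfg.horizon, alpha=cfg.alpha, scope=cfg.dichotomize_scope,
    )

    merged = expression.merge(assign_df[["sample_id", "subtype"]], on="sample_id")
    r, r_p = pearson_corr(merged["wt_expr"], merged["de4_expr"])
    kw: dict[str, tuple[float, int, float] | None] = {}
    for col in ("wt_expr", "de4_expr"):
        groups = [g[col].to_numpy() for _, g in merged.groupby("subtype") if len(g) > 0]
        kw[col] = kruskal_wallis(groups) if len(groups) >= 2 else None

    summary = cohort_summary(
        [row for row in _expression_records(expression, cfg.cutoff)],
    )

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    assign_df.to_csv(cfg.out_dir / "signature_assignments.tsv", sep="\t", index=False)
    report.to_csv(cfg.out_dir / "table1_report.tsv", sep="\t", index=False)
    stats = {
        "pearson_wt_de4": {"r": r, "p": r_p},
        "kruskal_wallis_by_subtype": {
            col: None if v is None else {"H": v[0], "df": v[1], "p": v[2]}
            for col, v in kw.items()
        },
        "cohort_summary": summary,
    }
    with open(cfg.out_dir / "association_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    _write_manifest(cfg, "clinical", {
        "signature_meta": assign_meta,
        "report_meta": report_meta,
    })

    _write_km_curves(cfg, expression, clinical, assign_df)
    return {"report": report, "assignments": assign_df, "stats": stats,
            "meta": {"assign": assign_meta, "report": report_meta}}


def _expression_records(expression: pd.DataFrame, cutoff: float):
    from .junction_quant import IsoformExpression

    for row in expression.itertuples():
        wt = float(row.wt_expr)
        de4 = float(row.de4_expr)
        total = wt + de4
        yield IsoformExpression(
            sample_id=str(row.sample_id),
            skip_ratio=(de4 / total) if total > 0 else None,
            wt_expr=wt,
            de4_expr=de4,
            rel_level=(de4 / wt) if wt > 0 else None,
            positive=de4 >= cutoff,
        )


def _write_km_curves(cfg: RunConfig, expression, clinical, assign_df) -> None:
    from .survival import km_curve_frame, truncate_followup

    clin = clinical.set_index("sample_id")
    merged = assign_df.merge(
        clin[["rfs_time", "event"]], left_on="sample_id", right_index=True,
    )
    frames = []
    for label, grp in merged.groupby("dual"):
        t, e = grp["rfs_time"].to_numpy(), grp["event"].to_numpy()
        if cfg.horizon is not None:
            t, e = truncate_followup(t, e, cfg.horizon)
        if e.sum() == 0:
            continue
        frame = km_curve_frame(t, e)
        frame.insert(0, "group", f"dual_{label}")
        frames.append(frame)
    if frames:
        pd.concat(frames).to_csv(cfg.out_dir / "km_curves.tsv", sep="\t", index=False)
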