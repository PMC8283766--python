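"""Synthetic data generators with known ground truth.

Three generators cover every pipeline input:

* :func:`simulate_alignments` — junction-spanning spliced reads written as a
  sorted SAM file, with a binomial split between inclusion and skip reads.
* :func:`simulate_cohort` — correlated log-normal isoform expression with
  subtype shifts, receptor statuses, and exponential relapse times whose
  hazard depends on the latent dual-signature group.
* :func:`simulate_qpcr` — Cq tables (mixtures + dilution series) from known
  efficiencies and copy numbers.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel
from .qpcr import (
    DETECTION_LIMIT_CQ,
    PRIMER_DE4,
    PRIMER_E3,
    PRIMER_REF,
    PRIMER_WT,
    MixtureDesign,
    slope_from_efficiency,
)
from .signature import SUBTYPE_HER2, SUBTYPE_LUMINAL, SUBTYPE_TN, SUBTYPES


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spliced-read simulation


@dataclass(frozen=True)
class ReadSimConfig:
    gene_model: GeneModel
    depth: int = 1000
    skip_fraction: float = 0.2
    read_length: int = 50
    anchor_min: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise SimulationError("depth must be non-negative")
        if not 0.0 <= self.skip_fraction <= 1.0:
            raise SimulationError("skip_fraction must lie in [0, 1]")
        if self.read_length < 2 * self.anchor_min + 1:
            raise SimulationError(
                "read_length must be at least 2 * anchor_min + 1 "
                f"({2 * self.anchor_min + 1}), got {self.read_length}"
            )


def simulate_alignments(cfg: ReadSimConfig, out: str | Path) -> dict:
    """Write a sorted SAM file of junction-spanning reads; return true counts.

    ``Binomial(depth, skip_fraction)`` reads span the skip junction, the
    remainder the inclusion junction.  Each read's gap operator matches its
    junction exactly and the random split position leaves at least
    ``anchor_min`` aligned bases on both sides.
    """
    gm = cfg.gene_model
    rng = np.random.default_rng(cfg.seed)
    n_skip = int(rng.binomial(cfg.depth, cfg.skip_fraction)) if cfg.depth else 0
    n_incl = cfg.depth - n_skip

    L, amin = cfg.read_length, cfg.anchor_min
    records = []
    for junction, n in ((gm.junction_inclusion, n_incl), (gm.junction_skip, n_skip)):
        gap_start, gap_end = junction
        gap = gap_end - gap_start
        # left anchor length in [anchor_min, L - anchor_min]
        lefts = rng.integers(amin, L - amin + 1, size=n)
        for i, left in enumerate(lefts):
            right = L - left
            pos = gap_start - left  # 0-based leftmost aligned base
            cigar = f"{left}M{gap}N{right}M"
            records.append((
                int(pos),
                f"read_{gap_start}_{gap_end}_{i}",
                cigar,
            ))
    records.sort(key=lambda r: r[0])

    ref_len = max(e.end for e in gm.exons) + cfg.read_length + 1
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{gm.reference_name}\tLN:{ref_len}\n")
        for pos, name, cigar in records:
            seq = "A" * L
            qual = "I" * L
            fh.write(
                f"{name}\t0\t{gm.reference_name}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )
    return {
        "n_inclusion": n_incl,
        "n_skip": n_skip,
        "depth": cfg.depth,
        "skip_fraction": cfg.skip_fraction,
        "path": str(out),
    }


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class CohortSimConfig:
    n: int = 200
    rho: float = 0.85
    mu_wt: float = 8.0
    sigma_wt: float = 0.8
    mu_de4: float = 8.0 - np.log(7.0)  # skipping isoform ~7-fold weaker by default
    sigma_de4: float = 0.8
    subtype_probs: tuple[float, float, float] = (0.7, 0.12, 0.18)
    subtype_shifts: tuple[float, float, float] = (0.0, -0.3, -0.6)
    hr_signature: float = 2.0
    baseline_hazard: float = 0.01   # events per month in the dual-low group
    censor_time: float = 120.0      # administrative censoring horizon, months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SimulationError("n must be at least 2")
        if not -1.0 < self.rho < 1.0:
            raise SimulationError("rho must lie in (-1, 1)")
        probs = np.asarray(self.subtype_probs, dtype=float)
        if probs.size != 3 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise SimulationError("subtype_probs must be a 3-simplex")
        if self.hr_signature <= 0:
            raise SimulationError("hr_signature must be positive")
        if self.sigma_wt < 0 or self.sigma_de4 < 0:
            raise SimulationError("sigmas must be non-negative")


_RECEPTORS = {
    SUBTYPE_LUMINAL: ("+", "+", "-"),
    SUBTYPE_HER2: ("-", "-", "+"),
    SUBTYPE_TN: ("-", "-", "-"),
}


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate (expression table, clinical table, ground-truth record).

    Log-expressions are bivariate normal with correlation ``rho``, shifted
    per subtype, then exponentiated.  Receptor statuses are the canonical
    pattern for the drawn subtype.  The latent dual-signature label comes
    from median splits of the generated expressions; relapse times are
    exponential with hazard ``baseline * hr_signature**is_dual_high``, then
    administratively censored at ``censor_time``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    sample_ids = [f"S{i:05d}" for i in range(n)]

    subtype_idx = rng.choice(3, size=n, p=np.asarray(cfg.subtype_probs, dtype=float))
    subtypes = [SUBTYPES[i] for i in subtype_idx]
    shifts = np.asarray(cfg.subtype_shifts, dtype=float)[subtype_idx]

    # explicit Cholesky construction; degenerates gracefully at sigma = 0
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    log_wt = cfg.mu_wt + cfg.sigma_wt * z1 + shifts
    log_de4 = (
        cfg.mu_de4
        + cfg.sigma_de4 * (cfg.rho * z1 + np.sqrt(1.0 - cfg.rho**2) * z2)
        + shifts
    )
    wt = np.exp(log_wt)
    de4 = np.exp(log_de4)
    gene_norm = wt + de4
    skip = de4 / gene_norm

    med_wt = float(np.median(wt))
    med_de4 = float(np.median(de4))
    hi_wt = wt > med_wt
    hi_de4 = de4 > med_de4
    dual_high = hi_wt | hi_de4

    hazard = cfg.baseline_hazard * np.where(dual_high, cfg.hr_signature, 1.0)
    latent_t = rng.exponential(1.0 / hazard)
    event = (latent_t <= cfg.censor_time).astype(int)
    rfs = np.minimum(latent_t, cfg.censor_time)

    age = np.clip(rng.normal(60.0, 12.0, size=n), 25.0, 95.0)
    sbr = rng.choice(["I", "II", "III"], size=n, p=[0.2, 0.45, 0.35])
    nodes = rng.choice(["negative", "positive"], size=n, p=[0.55, 0.45])
    size_mm = np.clip(rng.lognormal(np.log(20.0), 0.4, size=n), 2.0, 120.0)
    receptors = [_RECEPTORS[s] for s in subtypes]

    expression = pd.DataFrame({
        "sample_id": sample_ids,
        "wt_expr": wt,
        "de4_expr": de4,
        "gene_norm_expr": gene_norm,
        "exon3_expr": gene_norm,
        "skip_ratio": skip,
    })
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "age": np.round(age, 1),
        "sbr_grade": sbr,
        "lymph_node": nodes,
        "tumor_size": np.round(size_mm, 1),
        "er": [r[0] for r in receptors],
        "pr": [r[1] for r in receptors],
        "her2": [r[2] for r in receptors],
        "rfs_time": rfs,
        "event": event,
    })
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "median_wt": med_wt,
        "median_de4": med_de4,
        "dual_high": dict(zip(sample_ids, (bool(b) for b in dual_high))),
        "subtype": dict(zip(sample_ids, subtypes)),
        "n_dual_high": int(dual_high.sum()),
        "n_events": int(event.sum()),
    }
    return expression, clinical, truth


# ---------------------------------------------------------------------------
# qPCR simulation


DEFAULT_INTERCEPT = 35.0  # Cq of a single input copy


def simulate_qpcr(
    designs: Sequence[MixtureDesign],
    efficiencies: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    intercepts: Mapping[str, float] | None = None,
    dilution_log10: Sequence[float] = (2, 3, 4, 5, 6, 7),
    replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate mixture Cq measurements and per-primer dilution series.

    ``Cq = intercept + slope * log10(copies) + N(0, noise_sd)`` with the
    slope derived from each primer pair's efficiency.  Zero copies are
    reported at the detection limit.  Returns the long-format measurement
    table and the dilution-series table.
    """
    for primer, eff in efficiencies.items():
        if not 0.5 < eff <= 1.2:
            raise SimulationError(f"efficiency for {primer!r} outside (0.5, 1.2]: {eff}")
    rng = np.random.default_rng(seed)
    intercepts = dict(intercepts or {})
    slopes = {p: slope_from_efficiency(e) for p, e in efficiencies.items()}

    def _cq(primer: str, copies: float) -> float:
        if copies <= 0:
            return DETECTION_LIMIT_CQ
        b0 = intercepts.get(primer, DEFAULT_INTERCEPT)
        cq = b0 + slopes[primer] * np.log10(copies)
        if noise_sd > 0:
            cq += rng.normal(0.0, noise_sd)
        return min(float(cq), DETECTION_LIMIT_CQ)

    meas_rows = []
    for d in designs:
        copies = {PRIMER_WT: d.copies_wt, PRIMER_DE4: d.copies_de4,
                  PRIMER_E3: d.copies_total}
        for primer in (PRIMER_E3, PRIMER_WT, PRIMER_DE4):
            if primer not in efficiencies:
                raise SimulationError(f"no efficiency supplied for {primer!r}")
            for rep in range(replicates):
                meas_rows.append({
                    "sample_id": d.mixture_id,
                    "primer_pair": primer,
                    "replicate": rep,
                    "cq": _cq(primer, copies[primer]),
                })

    dilution_rows = []
    for primer in efficiencies:
        for log10_copies in dilution_log10:
            for rep in range(replicates):
                dilution_rows.append({
                    "primer_pair": primer,
                    "log10_copies": float(log10_copies),
                    "replicate": rep,
                    "cq": _cq(primer, 10.0 ** log10_copies),
                })
    return pd.DataFrame(meas_rows), pd.DataFrame(dilution_rows)
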