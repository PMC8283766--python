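"""Isoform-specific RT-qPCR quantification.

Standard-curve fitting (Cq vs log10 input, ordinary least squares),
efficiency-corrected relative expression against a reference gene,
copy-number back-calculation from a curve, and plasmid-mixture
primer-specificity validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# canonical primer-pair names: exon-3 internal amplicon, the two
# junction-specific amplicons, and the ribosomal reference gene
PRIMER_E3 = "E3"
PRIMER_WT = "E3-E4"
PRIMER_DE4 = "E3-E5"
PRIMER_REF = "REF28S"
PRIMER_PAIRS = (PRIMER_E3, PRIMER_WT, PRIMER_DE4, PRIMER_REF)

DETECTION_LIMIT_CQ = 40.0  # Cq at/above this is treated as non-detected


class QPCRError(ValueError):
    pass


@dataclass(frozen=True)
class QPCRMeasurement:
    sample_id: str
    primer_pair: str
    replicate: int
    cq: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cq) or self.cq <= 0:
            raise QPCRError(f"cq must be finite and positive, got {self.cq}")

    @property
    def detected(self) -> bool:
        return self.cq < DETECTION_LIMIT_CQ


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(input quantity)."""

    primer_pair: str
    slope: float
    intercept: float
    r2: float
    efficiency: float
    valid: bool


@dataclass(frozen=True)
class MixtureDesign:
    mixture_id: str
    copies_wt: int
    copies_de4: int

    def __post_init__(self) -> None:
        if self.copies_wt < 0 or self.copies_de4 < 0:
            raise QPCRError("copy numbers must be non-negative")
        if self.copies_wt + self.copies_de4 == 0:
            raise QPCRError("mixture must contain at least one copy")

    @property
    def copies_total(self) -> int:
        return self.copies_wt + self.copies_de4


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope: ``10^(-1/slope) - 1``."""
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_from_efficiency(efficiency: float) -> float:
    """Inverse of :func:`efficiency_from_slope`: ``-1 / log10(1 + efficiency)``."""
    if efficiency <= 0:
        raise QPCRError("efficiency must be positive")
    return -1.0 / np.log10(1.0 + efficiency)


def fit_standard_curve(
    dilution_log10: Sequence[float], cq: Sequence[float], primer_pair: str = ""
) -> StandardCurve:
    """Fit Cq = intercept + slope * log10(input) by ordinary least squares.

    Requires at least 3 distinct dilution points.  A non-negative slope
    yields a curve flagged invalid (efficiency is then undefined and NaN).
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size < 3:
        raise QPCRError("standard curve needs at least 3 dilution points")
    if x.size != y.size:
        raise QPCRError("dilution and cq vectors differ in length")
    if np.unique(x).size < 3:
        raise QPCRError("dilution points must be distinct")
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue ** 2)
    if slope >= 0:
        return StandardCurve(primer_pair, slope, intercept, r2, float("nan"), False)
    return StandardCurve(primer_pair, slope, intercept, r2, efficiency_from_slope(slope), True)


def relative_expression(
    cq_target: float,
    cq_ref: float,
    eff_target: float = 1.0,
    eff_ref: float = 1.0,
    efficiency_range: tuple[float, float] | None = (0.8, 1.1),
) -> float:
    """Efficiency-corrected expression of a target relative to a reference gene.

    ``(1 + eff_target)^(-cq_target) / (1 + eff_ref)^(-cq_ref)``; with both
    efficiencies at 1.0 this reduces to ``2^-(cq_target - cq_ref)``.
    Pass ``efficiency_range=None`` to skip the plausibility check.
    """
    if efficiency_range is not None:
        lo, hi = efficiency_range
        for name, eff in (("eff_target", eff_target), ("eff_ref", eff_ref)):
            if not lo <= eff <= hi:
                raise QPCRError(
                    f"{name}={eff} outside plausible range [{lo}, {hi}]; "
                    "pass efficiency_range=None to override"
                )
    return (1.0 + eff_target) ** (-cq_target) / (1.0 + eff_ref) ** (-cq_ref)


def copies_from_curve(cq: float, curve: StandardCurve) -> float:
    """Back-calculate input copies from a Cq via ``10^((cq - intercept) / slope)``."""
    if not curve.valid:
        raise QPCRError(f"standard curve for {curve.primer_pair!r} is invalid")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def aggregate_cq(measurements: Iterable[QPCRMeasurement]) -> pd.DataFrame:
    """Mean Cq per (sample, primer pair) over detected replicates.

    A (sample, primer) cell where every replicate is at/over the detection
    limit is reported with ``detected=False`` and the limit Cq.
    """
    rows = [
        {"sample_id": m.sample_id, "primer_pair": m.primer_pair, "cq": m.cq,
         "detected": m.detected}
        for m in measurements
    ]
    if not rows:
        raise QPCRError("no measurements supplied")
    df = pd.DataFrame(rows)

    def _agg(g: pd.DataFrame) -> pd.Series:
        det = g[g["detected"]]
        if det.empty:
            return pd.Series({"cq": DETECTION_LIMIT_CQ, "detected": False})
        return pd.Series({"cq": det["cq"].mean(), "detected": True})

    out = df.groupby(["sample_id", "primer_pair"]).apply(_agg, include_groups=False)
    return out.reset_index()


def validate_mixture(
    designs: Sequence[MixtureDesign],
    measurements: Iterable[QPCRMeasurement],
    curves: Mapping[str, StandardCurve],
    tolerance: float = 0.20,
) -> pd.DataFrame:
    """Check that isoform-specific primers recover the designed copy numbers.

    For each mixture the inclusion-junction primers estimate the inclusion
    plasmid copies, the skip-junction primers the skipping plasmid copies and
    the internal-exon primers the total.  Each estimate is compared to its
    expected value; ``pass`` requires the recovery ratio within
    ``1 ± tolerance`` (an expected zero passes when non-detected).
    """
    needed = (PRIMER_WT, PRIMER_DE4, PRIMER_E3)
    for p in needed:
        if p not in curves:
            raise QPCRError(f"missing standard curve for primer pair {p!r}")
    agg = aggregate_cq(measurements).set_index(["sample_id", "primer_pair"])

    gaps = [
        (d.mixture_id, p)
        for d in designs for p in needed
        if (d.mixture_id, p) not in agg.index
    ]
    if gaps:
        raise QPCRError(f"missing primer-pair coverage for: {gaps}")

    rows = []
    for d in designs:
        expected = {
            PRIMER_WT: d.copies_wt,
            PRIMER_DE4: d.copies_de4,
            PRIMER_E3: d.copies_total,
        }
        for primer in needed:
            cell = agg.loc[(d.mixture_id, primer)]
            estimate = (
                copies_from_curve(float(cell["cq"]), curves[primer])
                if bool(cell["detected"]) else 0.0
            )
            exp = expected[primer]
            if exp == 0:
                recovery = float("nan")
                ok = estimate == 0.0 or estimate < 1.0  # below single-copy detection
            else:
                recovery = estimate / exp
                ok = abs(recovery - 1.0) <= tolerance
            rows.append({
                "mixture_id": d.mixture_id,
                "primer_pair": primer,
                "expected_copies": exp,
                "estimated_copies": estimate,
                "recovery": recovery,
                "passed": ok,
            })
    return pd.DataFrame(rows)


def read_cq_table(path) -> list[QPCRMeasurement]:
    """Read a long-format CSV with columns sample,primer_pair,replicate,cq."""
    df = pd.read_csv(path)
    required = {"sample_id", "primer_pair", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise QPCRError(f"Cq table missing columns: {sorted(missing)}")
    return [
        QPCRMeasurement(str(r.sample_id), str(r.primer_pair), int(r.replicate), float(r.cq))
        for r in df.itertuples()
    ]
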