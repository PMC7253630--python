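"""Integer copy-number calling from qPCR Ct triplicates.

Copy numbers on repeated Y fragments are quantified relative to GAPDH,
an autosomal reference present in exactly two copies.  With perfectly
efficient amplification one cycle equals one template doubling, so

    cn = 2 * E_t^(-mean Ct_target) / E_r^(-mean Ct_reference)

which for both efficiencies E = 2 reduces to the familiar delta-Ct form
``cn = 2 * 2**(mean Ct_ref - mean Ct_target)``.  Triplicates whose Ct range
exceeds 0.3 cycles are flagged for retest and never enter downstream layers.
Continuous estimates are snapped to the locus's integer copy-number ladder
on a log2 scale, because Ct error is multiplicative in template copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "CopyNumberCall",
    "QcError",
    "QC_THRESHOLD",
    "triplicate_qc",
    "relative_copy_number",
    "snap_to_ladder",
    "call_copy_number",
    "calibrate_calls",
    "efficiency_from_standard_curve",
    "read_qpcr_table",
    "cn_summary",
    "cnv_polymorphism",
]

#: Maximum admissible Ct range (cycles) within a triplicate.
QC_THRESHOLD = 0.3


class QcError(ValueError):
    """Raised when a computation is attempted on a retest-flagged triplicate."""


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct triplicates for one sample at one locus, plus the reference channel."""

    sample_id: str
    locus_id: str
    ct_target: tuple[float, float, float]
    ct_reference: tuple[float, float, float]
    efficiency_target: float = 2.0
    efficiency_reference: float = 2.0

    def __post_init__(self) -> None:
        for name, cts in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if len(cts) != 3:
                raise ValueError(f"{name} needs exactly 3 replicates, got {len(cts)}")
            if not all(math.isfinite(c) and c > 0 for c in cts):
                raise ValueError(f"{name} values must be positive and finite: {cts}")
        for name, e in (
            ("efficiency_target", self.efficiency_target),
            ("efficiency_reference", self.efficiency_reference),
        ):
            if not 1.0 < e <= 2.0:
                raise ValueError(f"{name} must be in (1.0, 2.0], got {e}")


@dataclass(frozen=True)
class CopyNumberCall:
    """Continuous and ladder-snapped copy number for one sample at one locus."""

    sample_id: str
    locus_id: str
    cn_continuous: float | None
    cn_integer: int | None
    qc_flag: str  # "pass" | "retest"
    ambiguous: bool = False


def triplicate_qc(cts: Sequence[float], threshold: float = QC_THRESHOLD) -> str:
    """``"retest"`` iff the triplicate's Ct range exceeds *threshold* cycles."""
    if len(cts) != 3:
        raise ValueError(f"expected 3 replicates, got {len(cts)}")
    # small guard so a range of exactly the threshold passes despite binary
    # rounding (20.3 - 20.0 > 0.3 in floats)
    return "retest" if max(cts) - min(cts) > threshold + 1e-9 else "pass"


def relative_copy_number(m: QpcrMeasurement) -> float:
    """Efficiency-corrected relative copy number against the 2-copy reference.

    Raises :class:`QcError` if either triplicate fails QC.
    """
    if triplicate_qc(m.ct_target) != "pass" or triplicate_qc(m.ct_reference) != "pass":
        raise QcError(
            f"sample {m.sample_id} locus {m.locus_id}: triplicate failed QC, retest"
        )
    mean_t = float(np.mean(m.ct_target))
    mean_r = float(np.mean(m.ct_reference))
    return 2.0 * m.efficiency_target ** (-mean_t) / m.efficiency_reference ** (-mean_r)


def snap_to_ladder(
    cn_continuous: float, ladder: Sequence[int]
) -> tuple[int, bool]:
    """Nearest ladder value on a log2 scale; ties go to the smaller value.

    Returns ``(cn_integer, ambiguous)`` where *ambiguous* marks an exact
    log-scale tie between two ladder values.
    """
    if not ladder:
        raise ValueError("empty copy-number ladder")
    if cn_continuous <= 0:
        raise ValueError(f"cn_continuous must be positive, got {cn_continuous}")
    target = math.log2(cn_continuous)
    dists = [(abs(math.log2(v) - target), v) for v in ladder]
    best = min(d for d, _ in dists)
    winners = [v for d, v in dists if math.isclose(d, best, rel_tol=0, abs_tol=1e-12)]
    return min(winners), len(winners) > 1


def call_copy_number(
    m: QpcrMeasurement,
    ladder: Sequence[int],
    qc_threshold: float = QC_THRESHOLD,
) -> CopyNumberCall:
    """Full call: QC both channels, quantify, snap to the ladder."""
    if (
        triplicate_qc(m.ct_target, qc_threshold) != "pass"
        or triplicate_qc(m.ct_reference, qc_threshold) != "pass"
    ):
        return CopyNumberCall(m.sample_id, m.locus_id, None, None, "retest")
    cn = relative_copy_number(m)
    cn_int, ambiguous = snap_to_ladder(cn, ladder)
    return CopyNumberCall(m.sample_id, m.locus_id, cn, cn_int, "pass", ambiguous)


def calibrate_calls(
    calls: Sequence[CopyNumberCall],
    calibrator_sample: str,
    known_cn: Mapping[str, int],
    ladders: Mapping[str, Sequence[int]],
) -> list[CopyNumberCall]:
    """Rescale continuous CNs so the calibrator's known copy number is exact.

    One multiplicative factor per locus, derived from the calibrator's own
    pass-flag call; loci without a calibrator call are left untouched.
    """
    factor: dict[str, float] = {}
    for c in calls:
        if c.sample_id == calibrator_sample and c.qc_flag == "pass" and c.locus_id in known_cn:
            factor[c.locus_id] = known_cn[c.locus_id] / c.cn_continuous
    out = []
    for c in calls:
        f = factor.get(c.locus_id)
        if f is None or c.qc_flag != "pass":
            out.append(c)
            continue
        cn = c.cn_continuous * f
        cn_int, amb = snap_to_ladder(cn, ladders[c.locus_id])
        out.append(replace(c, cn_continuous=cn, cn_integer=cn_int, ambiguous=amb))
    return out


def efficiency_from_standard_curve(
    log10_input: Sequence[float], ct: Sequence[float]
) -> float:
    """Amplification efficiency from a dilution-series standard curve.

    Fits Ct against log10 template input; a slope of -1/log10(E) gives the
    per-cycle amplification factor ``E = 10**(-1/slope)`` (slope -3.32 -> 2.0).
    """
    if len(log10_input) != len(ct) or len(ct) < 2:
        raise ValueError("standard curve needs >= 2 (input, Ct) pairs")
    slope = float(np.polyfit(np.asarray(log10_input, float), np.asarray(ct, float), 1)[0])
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope)


def read_qpcr_table(
    path: str | Path,
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
) -> list[QpcrMeasurement]:
    """Read a qPCR plate TSV: sample_id, locus_id, rep (1-3), ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "locus_id": str})
    required = {"sample_id", "locus_id", "rep", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: qPCR table needs columns {sorted(required)}")
    out = []
    for (sid, lid), grp in df.groupby(["sample_id", "locus_id"], sort=True):
        grp = grp.sort_values("rep")
        if len(grp) != 3:
            raise ValueError(
                f"{path}: sample {sid} locus {lid} has {len(grp)} replicates, expected 3"
            )
        out.append(
            QpcrMeasurement(
                sample_id=sid,
                locus_id=lid,
                ct_target=tuple(grp["ct_target"].astype(float)),
                ct_reference=tuple(grp["ct_reference"].astype(float)),
                efficiency_target=efficiency_target,
                efficiency_reference=efficiency_reference,
            )
        )
    return out


def _integer_median(values: Sequence[int]) -> int:
    """Median restricted to the observed integers: lower middle for even n."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def cn_summary(
    calls: Sequence[CopyNumberCall], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group per-locus median and range of pass-flag integer calls.

    Returns a tidy frame with columns group, locus_id, n, median, min, max.
    Empty cells are simply absent (missing, never zero).
    """
    rows: dict[tuple[str, str], list[int]] = {}
    for c in calls:
        if c.qc_flag != "pass" or c.cn_integer is None:
            continue
        g = groups.get(c.sample_id)
        if g is None:
            continue
        rows.setdefault((g, c.locus_id), []).append(c.cn_integer)
    records = [
        {
            "group": g,
            "locus_id": lid,
            "n": len(v),
            "median": _integer_median(v),
            "min": min(v),
            "max": max(v),
        }
        for (g, lid), v in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(
        records, columns=["group", "locus_id", "n", "median", "min", "max"]
    )


def cnv_polymorphism(cns: Sequence[int]) -> float:
    """Unbiased gene diversity over integer copy-number states.

    ``(n/(n-1)) * (1 - sum p_k**2)``; 0 iff monomorphic, <= 1 always.
    Undefined (ValueError) for n < 2.
    """
    n = len(cns)
    if n < 2:
        raise ValueError("cnv_polymorphism needs >= 2 samples")
    _, counts = np.unique(np.asarray(cns), return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))
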