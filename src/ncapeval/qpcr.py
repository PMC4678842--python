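"""qPCR standard curves, absolute quantification and enrichment ratios.

A standard curve is the least-squares line of Ct on log10(input copies),
fitted over serial dilutions (the study protocol uses 10^6 down to 10^0
copies/ul of phage genome).  Amplification efficiency is
``10^(-1/slope) - 1`` (slope -3.3219 <=> perfect doubling).  Absolute
copies of an unknown follow by inverting the line; the enrichment
readout is the ratio of targeted to untargeted copies/ul.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["StandardCurve", "RatioResult", "fit_standard_curve", "quantify", "quantify_ratio", "ratios_from_table"]


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # Ct per log10(copies); negative for valid curves
    intercept: float
    r_squared: float
    min_ct: float  # Ct of the highest standard (extrapolation warning bound)

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies(self, ct: float) -> float:
        """Absolute copies/ul for an observed Ct."""
        if ct < self.min_ct:
            logger.warning(
                "Ct %.2f below the highest standard (%.2f); extrapolating", ct, self.min_ct
            )
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass(frozen=True)
class RatioResult:
    copies_target: float
    copies_untarget: float

    @property
    def ratio(self) -> float:
        if self.copies_untarget <= 0:
            raise ValueError("ratio undefined: untargeted copies <= 0")
        return self.copies_target / self.copies_untarget


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Fit Ct = slope * log10(copies) + intercept.

    *points* are ``(copies_per_ul, Ct)`` pairs; at least three distinct
    copy numbers are required, all positive.  A warning is logged when
    the implied efficiency leaves the usual acceptance band [0.8, 1.1].
    """
    if any(c <= 0 for c, _ in points):
        raise ValueError("copies must be positive")
    x = np.log10([c for c, _ in points])
    y = np.array([ct for _, ct in points], dtype=float)
    if len(set(x.tolist())) < 3:
        raise ValueError("need >= 3 points with distinct copy numbers")
    fit = stats.linregress(x, y)
    curve = StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        min_ct=float(y.min()),
    )
    if curve.slope >= 0:
        logger.warning("standard curve slope %.3f is non-negative", curve.slope)
    elif not 0.8 <= curve.efficiency <= 1.1:
        logger.warning("amplification efficiency %.2f outside [0.8, 1.1]", curve.efficiency)
    return curve


def quantify(ct: float, curve: StandardCurve) -> float:
    return curve.copies(ct)


def quantify_ratio(
    ct_target: float,
    ct_untarget: float,
    curve: StandardCurve,
    untarget_curve: StandardCurve | None = None,
) -> RatioResult:
    """Targeted:untargeted copy ratio from two Ct values.

    By default both assays share one curve; pass *untarget_curve* to use
    one curve per primer pair.
    """
    uc = untarget_curve or curve
    return RatioResult(curve.copies(ct_target), uc.copies(ct_untarget))


def ratios_from_table(path: str | Path, shared_curve: bool = False) -> pd.DataFrame:
    """Compute enrichment ratios from a Ct TSV.

    Expected columns: ``sample``, ``assay`` (``target``/``untarget``),
    ``ct`` and, for standards, ``copies`` (non-standards leave it
    empty).  One curve is fitted per assay unless *shared_curve* pools
    all standards.  Returns a tidy frame with one row per sample.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "assay", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "copies" not in df.columns or not df["copies"].notna().any():
        raise ValueError(f"{path}: no standard rows (copies column)")
    std = df[df["copies"].notna()]
    curves: dict[str, StandardCurve] = {}
    for assay in ("target", "untarget"):
        rows = std if shared_curve else std[std["assay"] == assay]
        curves[assay] = fit_standard_curve(list(zip(rows["copies"], rows["ct"])))
    unknowns = df[df["copies"].isna()]
    out = []
    for sample, grp in unknowns.groupby("sample"):
        cts = {a: g["ct"].mean() for a, g in grp.groupby("assay")}
        if not {"target", "untarget"}.issubset(cts):
            raise ValueError(f"sample {sample!r}: need both target and untarget Ct")
        res = quantify_ratio(cts["target"], cts["untarget"], curves["target"], curves["untarget"])
        out.append(
            {
                "sample": sample,
                "copies_target": res.copies_target,
                "copies_untarget": res.copies_untarget,
                "ratio": res.ratio,
            }
        )
    return pd.DataFrame(out)
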