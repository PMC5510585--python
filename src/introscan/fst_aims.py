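"""Per-SNP Hudson F_ST and ancestry-informative-marker (AIM) classification.

Differentiation between the two reference panels is measured per site with
Hudson's estimator in its ratio form,

    N = (p1 - p2)^2 - p1(1-p1)/(n1 - 1) - p2(1-p2)/(n2 - 1)
    D = p1(1-p2) + p2(1-p1),         F_ST = N / D,

where p are sample alternate-allele frequencies and n the numbers of called
allele copies.  This estimator is the standard per-site choice: it is nearly
unbiased at small sample sizes and makes no within-population weighting
assumptions.  Negative values are retained — clamping them would bias the
classification threshold.

AIMs are the sites whose F_ST strictly exceeds mean + 2 SD of the defined
per-site values (population SD, since the site set is fixed, not sampled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix

__all__ = ["FstResult", "AimSet", "hudson_fst_site", "fst_profile", "classify_aims"]


@dataclass
class FstResult:
    """Per-site Hudson F_ST plus the allele frequencies/counts behind it."""

    fst: np.ndarray   # (m,), NaN where undefined
    p1: np.ndarray
    n1: np.ndarray    # called allele copies, panel 1
    p2: np.ndarray
    n2: np.ndarray
    sites: pd.DataFrame | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.fst)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.fst))

    @property
    def sd(self) -> float:
        """Population (n-denominator) SD over defined sites."""
        return float(np.nanstd(self.fst))


@dataclass
class AimSet:
    """Sites classified as ancestry-informative markers."""

    indices: np.ndarray     # site indices into the source matrix
    threshold: float        # mean + 2 SD of defined per-site F_ST
    fst: np.ndarray         # per-AIM F_ST
    p1: np.ndarray          # per-AIM panel-1 (recipient) frequency
    p2: np.ndarray          # per-AIM panel-2 (donor) frequency
    positions: np.ndarray | None = None  # bp, when site metadata was available

    @property
    def n_aims(self) -> int:
        return len(self.indices)

    def spacing_bp(self) -> tuple[float, float]:
        """(mean, median) distance between consecutive AIMs in bp."""
        if self.positions is None or len(self.positions) < 2:
            return (float("nan"), float("nan"))
        gaps = np.diff(np.sort(self.positions))
        return (float(gaps.mean()), float(np.median(gaps)))


def hudson_fst_site(p1, n1, p2, n2):
    """Hudson's per-site F_ST estimator; NaN where undefined.

    Undefined when either panel has fewer than 2 called allele copies or the
    site is monomorphic across both panels (denominator zero).  Accepts
    scalars or aligned arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 \
            - p1 * (1.0 - p1) / (n1 - 1.0) \
            - p2 * (1.0 - p2) / (n2 - 1.0)
        den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
        fst = num / den
    bad = (n1 < 2) | (n2 < 2) | (den == 0)
    fst = np.where(bad, np.nan, fst)
    if fst.ndim == 0:
        return float(fst)
    return fst


def fst_profile(gm: GenotypeMatrix, group_1: str = "ref_a",
                group_2: str = "ref_b") -> FstResult:
    """Per-site Hudson F_ST between two sample groups of a dosage matrix.

    Frequencies use called genotypes only; allele counts are twice the number
    of called diploids at each site.
    """
    idx1 = gm.group_index(group_1)
    idx2 = gm.group_index(group_2)
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError("both panels must be non-empty")

    def _freq(rows):
        d = gm.dosage[rows]
        called = d != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return p, n.astype(float)

    p1, n1 = _freq(idx1)
    p2, n2 = _freq(idx2)
    fst = hudson_fst_site(p1, n1, p2, n2)
    fst = np.where(np.isnan(p1) | np.isnan(p2), np.nan, fst)
    return FstResult(fst=np.atleast_1d(fst), p1=p1, n1=n1, p2=p2, n2=n2,
                     sites=gm.sites)


def classify_aims(fst: FstResult) -> AimSet:
    """Classify AIMs with the mean + 2 SD exceedance rule (strict ``>``).

    Sites at exactly the threshold are *not* AIMs; when every defined value
    is identical (SD = 0) no site can exceed mean + 2 SD and the set is empty.
    """
    defined = fst.defined
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined F_ST values")
    mean, sd = fst.mean, fst.sd
    threshold = mean + 2.0 * sd
    if sd <= 1e-12 * max(1.0, abs(mean)):
        warnings.warn("all F_ST values identical; no AIMs classifiable",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        is_aim = np.where(defined, fst.fst > threshold, False)
    idx = np.flatnonzero(is_aim)
    positions = None
    if fst.sites is not None:
        positions = fst.sites["pos"].to_numpy()[idx]
    return AimSet(
        indices=idx,
        threshold=threshold,
        fst=fst.fst[idx],
        p1=fst.p1[idx],
        p2=fst.p2[idx],
        positions=positions,
    )
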