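"""Haplotype-homozygosity selection scan: EHH, iHH, XP-EHH and the
composite divergence x homozygosity score.

EHH at extent x is the probability that two haplotypes drawn at random from
the panel are identical over the inclusive interval [core..x]; at the core
itself it equals the core-site homozygosity.  iHH is the trapezoidal
integral of the EHH curve over genetic distance (cM), summed over both
directions, each direction truncated at the first crossing of the EHH cutoff
(default 0.05) or flagged when the chromosome edge is reached first.
XP-EHH compares target and reference panels as ln(iHH_target / iHH_ref);
positive values mean unusually extended homozygosity — a sweep — in the
target population.

For outlier calling, per-site F_ST (target vs reference) and XP-EHH are each
z-normalised over the scored sites and multiplied; sites at or above the
97.5th percentile of this composite score, jointly extreme in both
statistics, are flagged and merged into candidate regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GeneticMap, HaplotypePanel

try:  # compiled fast path for the iHH scans; numpy fallback below
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]

__all__ = [
    "EhhCurve",
    "IhhResult",
    "SelectionScanResult",
    "ehh",
    "ihh",
    "xpehh_scan",
    "znormalize",
    "composite_outliers",
    "selection_scan",
]

EHH_CUTOFF = 0.05
OUTLIER_PERCENTILE = 97.5


@dataclass
class EhhCurve:
    core: int
    site_idx: np.ndarray     # core first, then flanking sites outward
    ehh: np.ndarray          # EHH at each extent, ehh[0] = core homozygosity
    cm: np.ndarray | None    # |distance from core| when a map was supplied
    monomorphic_core: bool


@dataclass
class IhhResult:
    value: float
    edge_left: bool        # chromosome edge reached with EHH still >= cutoff
    edge_right: bool
    unscoreable: bool      # no genetic extent on either side


@dataclass
class SelectionScanResult:
    """Per-core raw and normalised scores plus merged outlier regions."""

    table: pd.DataFrame    # idx, pos, ihh_target, ihh_ref, xpehh, z_xpehh,
                           # fst, z_fst, composite, percentile, outlier, skip_reason
    regions: list[tuple[str, int, int]]
    percentile: float


def _pair_frac(counts: np.ndarray, n: int) -> float:
    """Fraction of haplotype pairs falling in the same identity group."""
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _ehh_walk(hap: np.ndarray, core: int, step: int, cutoff: float | None):
    """Yield (site_idx, ehh) from the core outward in direction ``step``.

    Identity groups are refined incrementally: extending the interval by one
    site splits each group by that site's allele, so EHH is non-increasing by
    construction.  Stops after the first value below ``cutoff`` (when given)
    or when every haplotype is in its own group (EHH has reached 0).
    """
    n, m = hap.shape
    ids = hap[:, core].astype(np.int64)
    counts = np.bincount(ids, minlength=2)
    e = _pair_frac(counts, n)
    yield core, e
    if cutoff is not None and e < cutoff:
        return
    j = core + step
    while 0 <= j < m:
        if counts.max() > 1:  # only refine while some group is non-singleton
            ids = np.unique(ids * 2 + hap[:, j], return_inverse=True)[1]
            counts = np.bincount(ids)
            e = _pair_frac(counts, n)
        yield j, e
        if cutoff is not None and e < cutoff:
            return
        j += step


def ehh(panel: HaplotypePanel, core: int, direction: str,
        gmap: GeneticMap | None = None, cutoff: float | None = None) -> EhhCurve:
    """EHH curve from a core site outward to the chromosome edge.

    ``direction`` is ``"left"`` or ``"right"``; the first point is the core
    itself (EHH = core homozygosity).  With ``cutoff`` set the curve stops
    after its first value below the cutoff.
    """
    if panel.n_haplotypes < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    step = -1 if direction == "left" else 1
    pts = list(_ehh_walk(panel.haplotypes, core, step, cutoff))
    idx = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    cm = None
    if gmap is not None:
        pos = panel.sites["pos"].to_numpy()
        cms = gmap.interpolate(pos[idx])
        cm = np.abs(cms - cms[0])
    mono = len(np.unique(panel.haplotypes[:, core])) == 1
    return EhhCurve(core=core, site_idx=idx, ehh=vals, cm=cm, monomorphic_core=mono)


@njit(cache=False)
def _ihh_direction_kernel(hap, cm, core, step, cutoff):  # pragma: no cover
    """Compiled directional trapezoidal iHH; returns (area, edge_truncated).

    Identity groups are tracked as integer labels and refined in O(n) per
    extension with a key -> new-label lookup table.
    """
    n, m = hap.shape
    ids = np.zeros(n, dtype=np.int64)
    for i in range(n):
        ids[i] = hap[i, core]
    lookup = np.full(2 * n + 2, -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    n_groups = 0
    # compact the initial (core-allele) grouping
    for i in range(n):
        key = ids[i]
        if lookup[key] < 0:
            lookup[key] = n_groups
            n_groups += 1
        ids[i] = lookup[key]
        counts[ids[i]] += 1
    lookup[0] = -1
    lookup[1] = -1
    pairs = 0.0
    for g in range(n_groups):
        pairs += counts[g] * (counts[g] - 1)
    denom = n * (n - 1)
    e = pairs / denom
    if cutoff > 0.0 and e < cutoff:
        return 0.0, False
    area = 0.0
    prev_d = 0.0
    prev_e = e
    max_count = 0
    for g in range(n_groups):
        if counts[g] > max_count:
            max_count = counts[g]
    j = core + step
    while 0 <= j < m:
        if max_count > 1:
            old_n_groups = n_groups
            n_groups = 0
            for g in range(old_n_groups):
                counts[g] = 0
            for i in range(n):
                key = 2 * ids[i] + hap[i, j]
                g = lookup[key]
                if g < 0:
                    g = n_groups
                    lookup[key] = g
                    n_groups += 1
                ids[i] = g
                counts[g] += 1
            # reset the touched lookup slots (keys < 2*old_n_groups + 2)
            for key in range(2 * old_n_groups + 2):
                lookup[key] = -1
            pairs = 0.0
            max_count = 0
            for g in range(n_groups):
                pairs += counts[g] * (counts[g] - 1)
                if counts[g] > max_count:
                    max_count = counts[g]
            e = pairs / denom
        d = abs(cm[j] - cm[core])
        area += 0.5 * (prev_e + e) * (d - prev_d)
        prev_d = d
        prev_e = e
        if e < cutoff:
            return area, False
        j += step
    return area, True  # chromosome edge reached with EHH still >= cutoff


def _ihh_direction(hap: np.ndarray, cm: np.ndarray, core: int, step: int,
                   cutoff: float) -> tuple[float, bool]:
    """Directional trapezoidal iHH; returns (area, edge_truncated)."""
    area = 0.0
    prev_cm = cm[core]
    prev_e = None
    last_e = None
    for j, e in _ehh_walk(hap, core, step, cutoff):
        d = abs(cm[j] - cm[core])
        if prev_e is not None:
            area += 0.5 * (prev_e + e) * (d - prev_cm)
        prev_cm, prev_e = d, e
        last_e = e
    edge = last_e is not None and last_e >= cutoff
    return area, edge


def _ihh_direction_fast(hap: np.ndarray, cm: np.ndarray, core: int, step: int,
                        cutoff: float) -> tuple[float, bool]:
    if HAVE_NUMBA:
        area, edge = _ihh_direction_kernel(
            np.ascontiguousarray(hap), np.ascontiguousarray(cm),
            int(core), int(step), float(cutoff),
        )
        return float(area), bool(edge)
    return _ihh_direction(hap, cm, core, step, cutoff)


def ihh(panel: HaplotypePanel, core: int, gmap: GeneticMap,
        cutoff: float = EHH_CUTOFF) -> IhhResult:
    """Integrated EHH around a core site over genetic distance (cM).

    Both directions are integrated until the EHH curve first drops below
    ``cutoff`` (that trapezoid included) and summed.  A direction that
    reaches the chromosome edge with EHH still at or above the cutoff is
    flagged edge-truncated.
    """
    pos = panel.sites["pos"].to_numpy()
    cm = gmap.interpolate(pos)
    left, edge_l = _ihh_direction_fast(panel.haplotypes, cm, core, -1, cutoff)
    right, edge_r = _ihh_direction_fast(panel.haplotypes, cm, core, 1, cutoff)
    value = left + right
    return IhhResult(
        value=value,
        edge_left=edge_l,
        edge_right=edge_r,
        unscoreable=value == 0.0,
    )


def xpehh_scan(
    panel_target: HaplotypePanel,
    panel_ref: HaplotypePanel,
    gmap: GeneticMap,
    cutoff: float = EHH_CUTOFF,
    cores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw XP-EHH = ln(iHH_target / iHH_ref) per core site.

    Cores where either iHH is zero, or where both directions are
    edge-truncated in both panels (no informative decay anywhere), are
    reported with a ``skip_reason`` and a NaN score.
    """
    if not panel_target.sites["pos"].equals(panel_ref.sites["pos"]):
        raise ValueError("target and reference panels must share the site map")
    pos = panel_target.sites["pos"].to_numpy()
    if cores is None:
        cores = np.arange(len(pos))
    cores = np.asarray(cores)
    cm = gmap.interpolate(pos)

    rows = []
    hap_t = np.ascontiguousarray(panel_target.haplotypes)
    hap_r = np.ascontiguousarray(panel_ref.haplotypes)
    for c in cores:
        t_l, t_el = _ihh_direction_fast(hap_t, cm, c, -1, cutoff)
        t_r, t_er = _ihh_direction_fast(hap_t, cm, c, 1, cutoff)
        r_l, r_el = _ihh_direction_fast(hap_r, cm, c, -1, cutoff)
        r_r, r_er = _ihh_direction_fast(hap_r, cm, c, 1, cutoff)
        ihh_t, ihh_r = t_l + t_r, r_l + r_r
        reason = ""
        score = np.nan
        if ihh_t == 0.0 or ihh_r == 0.0:
            reason = "ihh_zero"
        elif t_el and t_er and r_el and r_er:
            reason = "edge_truncated_both_panels"
        else:
            score = float(np.log(ihh_t / ihh_r))
        rows.append(
            {
                "idx": int(c),
                "pos": int(pos[c]),
                "ihh_target": ihh_t,
                "ihh_ref": ihh_r,
                "xpehh": score,
                "skip_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def znormalize(values: np.ndarray) -> np.ndarray:
    """(v - mean) / SD over finite entries (population SD); NaNs propagate."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values to z-normalise")
    mean = v[finite].mean()
    sd = v[finite].std()
    if sd == 0.0:
        raise ValueError("cannot z-normalise values with zero variance")
    out = np.full_like(v, np.nan)
    out[finite] = (v[finite] - mean) / sd
    return out


def _percentile_rank(values: np.ndarray) -> np.ndarray:
    """100 * (# strictly smaller) / n among finite entries; ties share ranks."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    n = finite.sum()
    out = np.full_like(v, np.nan)
    scored = v[finite]
    order = np.argsort(scored, kind="stable")
    sorted_vals = scored[order]
    n_less = np.searchsorted(sorted_vals, scored, side="left")
    out[finite] = 100.0 * n_less / n
    return out


def composite_outliers(
    z_fst: np.ndarray,
    z_xpehh: np.ndarray,
    sites: pd.DataFrame | None = None,
    percentile: float = OUTLIER_PERCENTILE,
) -> SelectionScanResult:
    """Composite score z_fst * z_xpehh with empirical-percentile outliers.

    The percentile rank is nearest-rank on the empirical distribution of the
    scored sites (ties at the cut share a rank and are included together);
    a site is an outlier iff its rank is at or above ``percentile``.
    Consecutive scored outlier sites merge into bp regions when site
    metadata is provided.
    """
    z_fst = np.asarray(z_fst, dtype=float)
    z_xpehh = np.asarray(z_xpehh, dtype=float)
    if z_fst.shape != z_xpehh.shape:
        raise ValueError("score vectors must be aligned")
    composite = z_fst * z_xpehh
    scored = np.isfinite(composite)
    n_scored = int(scored.sum())
    if n_scored < 40:
        warnings.warn(
            f"only {n_scored} scored sites; percentile cut is unstable",
            stacklevel=2,
        )
    if n_scored and np.unique(composite[scored]).size == 1:
        warnings.warn("all composite scores equal; no well-defined outliers",
                      stacklevel=2)
        pct = np.full_like(composite, np.nan)
        outlier = np.zeros_like(scored)
    else:
        pct = _percentile_rank(composite)
        # nearest-rank cut: the top n_scored - ceil(n_scored * p/100) values
        # are outliers, and ties at the cut value are included together
        n_top = n_scored - int(np.ceil(n_scored * percentile / 100.0))
        outlier = np.zeros_like(scored)
        if n_top > 0:
            cut = np.sort(composite[scored])[-n_top]
            with np.errstate(invalid="ignore"):
                outlier = np.where(scored, composite >= cut, False)

    regions: list[tuple[str, int, int]] = []
    if sites is not None and outlier.any():
        chrom = str(sites["chrom"].iloc[0])
        pos = sites["pos"].to_numpy()
        scored_idx = np.flatnonzero(scored)
        flags = outlier[scored_idx]
        start = None
        for k, i in enumerate(scored_idx):
            if flags[k] and start is None:
                start = i
            if start is not None and (not flags[k]):
                regions.append((chrom, int(pos[start]), int(pos[scored_idx[k - 1]])))
                start = None
        if start is not None:
            regions.append((chrom, int(pos[start]), int(pos[scored_idx[-1]])))

    table = pd.DataFrame(
        {
            "z_fst": z_fst,
            "z_xpehh": z_xpehh,
            "composite": composite,
            "percentile": pct,
            "outlier": outlier,
        }
    )
    if sites is not None:
        table.insert(0, "pos", sites["pos"].to_numpy())
        table.insert(0, "chrom", sites["chrom"].to_numpy())
    return SelectionScanResult(table=table, regions=regions, percentile=percentile)


def selection_scan(
    panel_target: HaplotypePanel,
    panel_ref: HaplotypePanel,
    fst: np.ndarray,
    gmap: GeneticMap,
    cutoff: float = EHH_CUTOFF,
    percentile: float = OUTLIER_PERCENTILE,
    cores: np.ndarray | None = None,
) -> SelectionScanResult:
    """Full composite scan: XP-EHH + F_ST -> z-scores -> product -> outliers.

    ``fst`` is the per-site F_ST between the target and reference groups
    (aligned to the panels' sites); only sites scored by both statistics
    enter the z-normalisation.
    """
    raw = xpehh_scan(panel_target, panel_ref, gmap, cutoff=cutoff, cores=cores)
    m = panel_target.n_sites
    xpehh = np.full(m, np.nan)
    xpehh[raw["idx"].to_numpy()] = raw["xpehh"].to_numpy()
    fst = np.asarray(fst, dtype=float)
    both = np.isfinite(xpehh) & np.isfinite(fst)
    z_x = np.full(m, np.nan)
    z_f = np.full(m, np.nan)
    z_x[both] = znormalize(xpehh[both])
    z_f[both] = znormalize(fst[both])
    result = composite_outliers(z_f, z_x, sites=panel_target.sites,
                                percentile=percentile)
    result.table["xpehh"] = xpehh
    result.table["fst"] = fst
    result.table["ihh_target"] = np.nan
    result.table["ihh_ref"] = np.nan
    result.table.loc[raw["idx"].to_numpy(), "ihh_target"] = raw["ihh_target"].to_numpy()
    result.table.loc[raw["idx"].to_numpy(), "ihh_ref"] = raw["ihh_ref"].to_numpy()
    return result
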