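"""Local ancestry of admixed samples from AIM genotypes.

Each admixed diploid is decoded over the ordered AIMs into a donor-dosage
path k in {0, 1, 2} (copies of donor, ``ref_b``, ancestry) by maximising

    sum_j log P(g_j | k_j, p_a_j, p_b_j)  -  s * |k_{j+1} - k_j|

with a Viterbi dynamic programme.  The emission is the genotype likelihood
with k alleles drawn Bernoulli(p_b) and 2-k alleles Bernoulli(p_a) — the
convolution of Binomial(k, p_b) and Binomial(2-k, p_a); missing genotypes
contribute log 1.  The switch penalty s (default 10, natural-log units per
haplotype switch) discourages spurious short ancestry switches; ties are
broken toward the smaller dosage, i.e. conservatively against claiming donor
ancestry.

Downstream, cohort-average donor proportions are scanned in sliding windows
of ``window_size`` AIMs (default 100, step 50) and windows more than 2 SD
above the chromosomal mean are merged into outlier regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst_aims import AimSet
from .variant_io import MISSING, GenotypeMatrix

__all__ = [
    "AncestryTrack",
    "WindowScan",
    "PcaResult",
    "emission_logprob",
    "viterbi_ancestry",
    "decode_admixed",
    "global_proportion",
    "window_scan",
    "outlier_threshold",
    "call_outlier_windows",
    "haplotype_pca",
]

FREQ_CLAMP = (0.01, 0.99)


@dataclass
class AncestryTrack:
    """Per-sample donor-dosage paths over the AIM sites."""

    samples: list[str]
    site_indices: np.ndarray   # AIM indices into the source matrix
    positions: np.ndarray      # bp of those AIMs
    chrom: str
    dosage: np.ndarray         # (n_samples, n_aims) int8 in {0,1,2}
    log_score: np.ndarray      # (n_samples,) Viterbi objective value

    @property
    def n_aims(self) -> int:
        return self.dosage.shape[1]


@dataclass
class WindowScan:
    """Sliding-window cohort donor-ancestry proportions."""

    windows: pd.DataFrame  # start_idx, end_idx (exclusive), start_bp, end_bp, mean_prop, truncated
    chrom: str
    mean: float            # chromosomal mean of window proportions
    sd: float              # population SD of window proportions
    window_size: int
    step: int


@dataclass
class PcaResult:
    loadings: np.ndarray             # (n_rows, 2) scores on PC1-2
    explained_variance: np.ndarray   # (2,) eigenvalues of the row covariance
    explained_ratio: np.ndarray      # (2,) fraction of total variance


def _clamp_freqs(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn(
            f"{what} frequencies at 0/1 clamped to {FREQ_CLAMP}", stacklevel=3
        )
    return np.clip(p, *FREQ_CLAMP)


def _emission_table(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """log P(g | k) for g in 0..2, k in 0..2; shape (m, 3 states, 3 genotypes)."""
    pa = _clamp_freqs(p_a, "recipient-panel")
    pb = _clamp_freqs(p_b, "donor-panel")
    qa, qb = 1.0 - pa, 1.0 - pb
    probs = np.empty((len(pa), 3, 3))
    probs[:, 0, 0] = qa * qa
    probs[:, 0, 1] = 2 * pa * qa
    probs[:, 0, 2] = pa * pa
    probs[:, 1, 0] = qa * qb
    probs[:, 1, 1] = pa * qb + qa * pb
    probs[:, 1, 2] = pa * pb
    probs[:, 2, 0] = qb * qb
    probs[:, 2, 1] = 2 * pb * qb
    probs[:, 2, 2] = pb * pb
    return np.log(probs)


def emission_logprob(g: int, k: int, p_a: float, p_b: float) -> float:
    """Log-likelihood of genotype ``g`` given ``k`` donor allele copies.

    ``k`` alleles are Bernoulli(p_b) and ``2 - k`` are Bernoulli(p_a);
    missing genotypes (``MISSING`` or None) return 0 (log 1).
    """
    if k not in (0, 1, 2):
        raise ValueError("state k must be 0, 1 or 2")
    if g is None or g == MISSING:
        return 0.0
    if g not in (0, 1, 2):
        raise ValueError("genotype must be 0, 1, 2 or missing")
    table = _emission_table(np.array([p_a]), np.array([p_b]))
    return float(table[0, k, g])


def viterbi_ancestry(
    genotypes: np.ndarray,
    p_a: np.ndarray,
    p_b: np.ndarray,
    switch_penalty: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Best dosage path(s) under emissions minus ``s * |dk|`` switch costs.

    Parameters
    ----------
    genotypes
        (m,) or (n, m) dosages over the AIMs, ``MISSING`` allowed.
    p_a, p_b
        (m,) recipient- and donor-panel allele frequencies at the AIMs.
    switch_penalty
        Cost per haplotype switch in natural-log units.

    Returns
    -------
    paths, scores
        ``paths`` with the input's leading shape; ``scores`` the attained
        objective per sample.  Ties are broken toward the smaller dosage.
    """
    G = np.atleast_2d(np.asarray(genotypes))
    n, m = G.shape
    if m == 0:
        raise ValueError("need at least one AIM")
    table = _emission_table(p_a, p_b)  # (m, 3, 3)
    # per-sample, per-site, per-state emission scores; missing -> 0
    em = np.zeros((n, m, 3))
    called = G != MISSING
    g_idx = np.where(called, G, 0)
    for k in range(3):
        em[:, :, k] = np.where(called, table[np.arange(m)[None, :], k, g_idx], 0.0)

    penalty = switch_penalty * np.abs(
        np.arange(3)[:, None] - np.arange(3)[None, :]
    )  # (k_prev, k_next)

    score = em[:, 0, :].copy()               # (n, 3)
    back = np.empty((n, m, 3), dtype=np.int8)
    back[:, 0, :] = np.arange(3)
    for j in range(1, m):
        cand = score[:, :, None] - penalty[None, :, :]   # (n, k_prev, k_next)
        best_prev = cand.argmax(axis=1)                  # first max -> smaller k
        score = np.take_along_axis(cand, best_prev[:, None, :], axis=1)[:, 0, :]
        score = score + em[:, j, :]
        back[:, j, :] = best_prev

    paths = np.empty((n, m), dtype=np.int8)
    paths[:, -1] = score.argmax(axis=1)                  # first max -> smaller k
    final = score.max(axis=1)
    for j in range(m - 1, 0, -1):
        paths[:, j - 1] = np.take_along_axis(
            back[:, j, :], paths[:, j][:, None], axis=1
        )[:, 0]
    if np.asarray(genotypes).ndim == 1:
        return paths[0], float(final[0])
    return paths, final


def path_logscore(
    genotypes: np.ndarray,
    path: np.ndarray,
    p_a: np.ndarray,
    p_b: np.ndarray,
    switch_penalty: float = 10.0,
) -> float:
    """Objective value of an arbitrary dosage path (for optimality checks)."""
    g = np.asarray(genotypes)
    path = np.asarray(path)
    table = _emission_table(p_a, p_b)
    called = g != MISSING
    em = np.where(
        called, table[np.arange(len(path)), path, np.where(called, g, 0)], 0.0
    )
    return float(em.sum() - switch_penalty * np.abs(np.diff(path)).sum())


def decode_admixed(
    gm: GenotypeMatrix,
    aims: AimSet,
    switch_penalty: float = 10.0,
    group: str = "admixed",
) -> AncestryTrack:
    """Viterbi-decode every sample of ``group`` over the AIM sites."""
    if aims.n_aims == 0:
        raise ValueError("empty AIM set")
    rows = gm.group_index(group)
    G = gm.dosage[np.ix_(rows, aims.indices)]
    paths, scores = viterbi_ancestry(G, aims.p1, aims.p2, switch_penalty)
    return AncestryTrack(
        samples=[gm.samples[i] for i in rows],
        site_indices=aims.indices,
        positions=gm.sites["pos"].to_numpy()[aims.indices],
        chrom=str(gm.sites["chrom"].iloc[0]),
        dosage=paths,
        log_score=scores,
    )


def global_proportion(track: AncestryTrack) -> pd.Series:
    """Genome-wide donor-ancestry proportion per sample (mean dosage / 2)."""
    if track.n_aims == 0:
        raise ValueError("empty ancestry track")
    return pd.Series(
        track.dosage.mean(axis=1) / 2.0, index=track.samples, name="donor_prop"
    )


def _window_starts(n_aims: int, window_size: int, step: int) -> list[int]:
    starts = []
    s = 0
    while True:
        starts.append(s)
        if s + window_size >= n_aims:
            break
        s += step
    return starts


def window_scan(track: AncestryTrack, window_size: int = 100,
                step: int = 50) -> WindowScan:
    """Cohort mean donor proportion in sliding AIM-index windows.

    Windows hold exactly ``window_size`` AIMs except possibly the last, which
    is kept (and flagged truncated) so chromosome ends stay covered.  The
    proportion is the mean of dosage/2 over all samples and member AIMs.
    """
    m = track.n_aims
    if m < window_size:
        warnings.warn(
            f"only {m} AIMs for window size {window_size}; single truncated window",
            stacklevel=2,
        )
    rows = []
    for s in _window_starts(m, window_size, step):
        e = min(s + window_size, m)
        rows.append(
            {
                "start_idx": s,
                "end_idx": e,
                "start_bp": int(track.positions[s]),
                "end_bp": int(track.positions[e - 1]),
                "mean_prop": float(track.dosage[:, s:e].mean() / 2.0),
                "truncated": e - s < window_size,
            }
        )
    df = pd.DataFrame(rows)
    means = df["mean_prop"].to_numpy()
    return WindowScan(
        windows=df,
        chrom=track.chrom,
        mean=float(means.mean()),
        sd=float(means.std()),   # population SD
        window_size=window_size,
        step=step,
    )


def outlier_threshold(mean: float, sd: float) -> float:
    """The 2-SD exceedance threshold on window ancestry proportions."""
    return mean + 2.0 * sd


def call_outlier_windows(ws: WindowScan) -> tuple[list[tuple[str, int, int]], float]:
    """Windows above mean + 2 SD, merged into bp regions.

    Outlier windows that overlap or touch in AIM-index space (share AIMs or
    are adjacent) merge into one region; regions are reported as 1-based
    inclusive bp intervals spanning the member AIMs.
    """
    if len(ws.windows) < 2:
        raise ValueError("need at least 2 windows to call outliers")
    thr = outlier_threshold(ws.mean, ws.sd)
    out = ws.windows[ws.windows["mean_prop"] > thr]
    regions: list[tuple[str, int, int]] = []
    prev_end_idx = None
    for _, w in out.iterrows():
        if prev_end_idx is not None and w["start_idx"] <= prev_end_idx:
            chrom, start, end = regions[-1]
            regions[-1] = (chrom, start, max(end, int(w["end_bp"])))
            prev_end_idx = max(prev_end_idx, int(w["end_idx"]))
        else:
            regions.append((ws.chrom, int(w["start_bp"]), int(w["end_bp"])))
            prev_end_idx = int(w["end_idx"])
    return regions, thr


def haplotype_pca(matrix: np.ndarray) -> PcaResult:
    """PCA of a haplotype (or genotype) matrix; loadings for PC1-2.

    Columns are centred and, where polymorphic, variance-standardised; the
    loadings are the row scores from an SVD of the standardised matrix.  The
    sign of each component is fixed so its largest-magnitude loading is
    positive, making output deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if not np.any(sd > 0):
        raise ValueError("zero-variance matrix")
    X = np.where(sd > 0, X / np.where(sd > 0, sd, 1.0), 0.0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :2] * s[:2]
    for c in range(scores.shape[1]):
        if scores[np.abs(scores[:, c]).argmax(), c] < 0:
            scores[:, c] = -scores[:, c]
    ev = (s**2) / X.shape[0]
    total = ev.sum()
    return PcaResult(
        loadings=scores,
        explained_variance=ev[:2],
        explained_ratio=ev[:2] / total if total > 0 else np.zeros(2),
    )
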