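"""Synthetic two-population panels with a known introgressed, swept tract.

The generator emulates the data features the downstream statistics consume,
not the full coalescent: per-site allele-frequency divergence between the two
reference populations follows the Balding–Nichols model (a Beta distribution
around an ancestral frequency with divergence parameter F), and haplotypes
are mosaic copies of a finite founder pool so that haplotype homozygosity
decays with distance.  Admixed samples are built on recipient-population
(``ref_a``) haplotypes, receive low genome-wide donor (``ref_b``) ancestry as
long random segments, and carry one high-frequency donor tract around a focal
interval; with ``sweep`` set, every donor tract copy descends from a single
founder haplotype, creating the shared long-range homozygosity a selective
sweep leaves behind.  Exact per-site donor dosages are recorded as truth
tracks so every downstream stage can be scored against known ancestry.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .variant_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    SITE_COLUMNS,
)

__all__ = [
    "SimConfig",
    "SiteFrequencies",
    "TruthTracks",
    "SimResult",
    "draw_site_frequencies",
    "draw_positions",
    "simulate_panels",
    "implant_introgression",
    "apply_missingness",
    "simulate",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic chromosome.

    Defaults mirror the sampling design the pipeline targets: 15 recipient
    reference diploids, 22 donor reference diploids and 21 putatively admixed
    diploids typed at ~18k SNPs on one chromosome; background divergence
    F = 0.04 with a 5% tail of strongly divergent sites (F = 0.4); admixed
    samples carry ~2% genome-wide donor ancestry plus one 600 kb donor tract
    at 80% haplotype frequency that is swept (single founder).  The candidate
    interval is typed more densely than the rest of the chromosome
    (``tract_site_fraction``), as targeted designs do around a focal gene.
    """

    seed: int = 1234
    chrom: str = "chr10"
    n_ref_a: int = 15          # recipient reference diploids (dogs)
    n_ref_b: int = 22          # donor reference diploids (wolves)
    n_admixed: int = 21        # putatively admixed diploids (highland dogs)
    n_sites: int = 18_000
    chrom_length_bp: int = 50_000_000
    fst_background: float = 0.04
    aim_fraction: float = 0.05
    f_aim: float = 0.40
    background_admixture: float = 0.02
    background_segment_bp: float = 1_000_000.0
    tract_bp: tuple[int, int] = (24_400_000, 25_000_000)
    tract_freq: float = 0.8
    sweep: bool = True
    tract_site_fraction: float = 0.12
    founder_pool: int = 1000
    copy_switch_rate: float = 2e-6
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_background < self.f_aim < 1.0:
            raise ValueError("need 0 < fst_background < f_aim < 1")
        if not 0.0 <= self.tract_freq <= 1.0:
            raise ValueError("tract_freq must be in [0, 1]")
        lo, hi = self.tract_bp
        if not (1 <= lo < hi <= self.chrom_length_bp):
            raise ValueError("tract_bp must lie within [1, chrom_length_bp]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.aim_fraction < 1.0:
            raise ValueError("aim_fraction must be in [0, 1)")
        if not 0.0 <= self.background_admixture < 1.0:
            raise ValueError("background_admixture must be in [0, 1)")
        if self.founder_pool < 1:
            raise ValueError("founder_pool must be >= 1")
        if not 0.0 <= self.copy_switch_rate < 1.0:
            raise ValueError("copy_switch_rate must be in [0, 1)")

    def to_flat_dict(self) -> dict[str, str]:
        d = asdict(self)
        d["tract_bp"] = f"{self.tract_bp[0]}-{self.tract_bp[1]}"
        return {k: str(v) for k, v in d.items()}


@dataclass
class SiteFrequencies:
    """Per-population alternate-allele frequencies plus truth labels."""

    freq_a: np.ndarray
    freq_b: np.ndarray
    p0: np.ndarray                 # ancestral frequencies
    high_divergence: np.ndarray    # bool; True where F = f_aim was used


@dataclass
class TruthTracks:
    """Exact donor-ancestry truth for the admixed samples."""

    dosage: np.ndarray           # (n_admixed, m) int8 in {0,1,2}
    hap_is_donor: np.ndarray     # (2*n_admixed, m) bool
    tract_bp: tuple[int, int]
    tract_site_idx: np.ndarray   # site indices inside the tract

    def to_table(self, samples, sites: pd.DataFrame) -> pd.DataFrame:
        n, m = self.dosage.shape
        return pd.DataFrame(
            {
                "sample": np.repeat(samples, m),
                "chrom": np.tile(sites["chrom"].to_numpy(), n),
                "pos": np.tile(sites["pos"].to_numpy(), n),
                "dosage": self.dosage.ravel(),
            }
        )


@dataclass
class SimResult:
    """Everything one simulated study produces."""

    config: SimConfig
    sites: pd.DataFrame
    freqs: SiteFrequencies
    panel: HaplotypePanel            # all samples, phased, complete
    genotypes: GenotypeMatrix        # with missingness applied
    truth: TruthTracks
    missing_mask: np.ndarray         # (n_samples, m) bool

    def group_panel(self, group: str) -> HaplotypePanel:
        return self.panel.group_panel(group)


def _validate_F(F: float) -> None:
    if not 0.0 < F < 1.0:
        raise ValueError(f"Balding–Nichols F must be in (0, 1), got {F}")


def _aim_p0_bounds(f_aim: float, clamp: float = 0.01) -> tuple[float, float]:
    """Ancestral-frequency range where the AIM divergence is realisable.

    The symmetric frequency split below keeps both population frequencies in
    ``[clamp, 1 - clamp]`` only when ``p0 - delta/2 >= clamp``; solving that
    boundary (a quadratic in p0) gives the feasible range.
    """
    c = f_aim / (2.0 - f_aim)
    disc = (2 * clamp + c) ** 2 - 4.0 * (1.0 + c) * clamp**2
    lo = ((2 * clamp + c) + np.sqrt(disc)) / (2.0 * (1.0 + c))
    return float(lo), float(1.0 - lo)


def draw_site_frequencies(config: SimConfig, rng: np.random.Generator) -> SiteFrequencies:
    """Per-population allele frequencies: Balding–Nichols background plus a
    fixed-divergence AIM tail.

    Background sites: an ancestral frequency ``p0 ~ U(0.05, 0.95)`` and
    independent population frequencies from a Beta with mean ``p0`` and
    variance ``p0 (1 - p0) F`` (shape parameters ``p0 (1-F)/F`` and
    ``(1-p0)(1-F)/F``), ``F = fst_background``.

    AIM tail (a random ``aim_fraction`` of sites): frequencies are split
    symmetrically around ``p0`` as ``p0 +- delta/2``, with random
    orientation, where ``delta^2 = 2 f_aim p0 (1-p0) / (1 - f_aim/2)`` makes
    the true-frequency Hudson F_ST equal ``f_aim`` at every designated site;
    ``p0`` is drawn from the range where that split stays inside the clamp
    bounds.  Independent Beta draws at ``F = f_aim`` would put the *average*
    per-site F_ST near ``f_aim`` but leave many designated sites essentially
    undiverged, which is not what an ancestry-informative-marker tail looks
    like: AIMs are by definition the consistently divergent sites.

    All frequencies are clamped to [0.01, 0.99] so no reference panel is
    monomorphic in expectation.
    """
    _validate_F(config.fst_background)
    _validate_F(config.f_aim)
    m = config.n_sites
    p0 = rng.uniform(0.05, 0.95, size=m)
    n_aim = int(round(config.aim_fraction * m))
    high = np.zeros(m, dtype=bool)
    if n_aim:
        high[rng.choice(m, size=n_aim, replace=False)] = True

    F = config.fst_background
    shape_scale = (1.0 - F) / F
    a = p0 * shape_scale
    b = (1.0 - p0) * shape_scale
    freq_a = np.clip(rng.beta(a, b), 0.01, 0.99)
    freq_b = np.clip(rng.beta(a, b), 0.01, 0.99)

    if n_aim:
        lo, hi = _aim_p0_bounds(config.f_aim)
        lo, hi = max(lo, 0.05), min(hi, 0.95)
        p0_aim = rng.uniform(lo, hi, size=n_aim)
        p0[high] = p0_aim
        delta = np.sqrt(2.0 * config.f_aim * p0_aim * (1.0 - p0_aim)
                        / (1.0 - config.f_aim / 2.0))
        q_hi = np.clip(p0_aim + delta / 2.0, 0.01, 0.99)
        q_lo = np.clip(p0_aim - delta / 2.0, 0.01, 0.99)
        flip = rng.random(n_aim) < 0.5
        freq_a[high] = np.where(flip, q_lo, q_hi)
        freq_b[high] = np.where(flip, q_hi, q_lo)

    return SiteFrequencies(freq_a=freq_a, freq_b=freq_b, p0=p0, high_divergence=high)


def draw_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sorted unique physical positions, densified inside the focal tract."""
    lo, hi = config.tract_bp
    n_tract = int(round(config.tract_site_fraction * config.n_sites))
    n_out = config.n_sites - n_tract
    taken: set[int] = set()

    def _draw(n, a, b):
        out = []
        while len(out) < n:
            cand = rng.integers(a, b + 1, size=2 * (n - len(out)))
            for c in cand:
                c = int(c)
                if c not in taken:
                    taken.add(c)
                    out.append(c)
                    if len(out) == n:
                        break
        return out

    pos = _draw(n_tract, lo, hi)
    # outside the tract: uniform over the two flanks, weighted by length
    left_len = lo - 1
    right_len = config.chrom_length_bp - hi
    n_left = int(round(n_out * left_len / (left_len + right_len)))
    pos += _draw(n_left, 1, lo - 1)
    pos += _draw(n_out - n_left, hi + 1, config.chrom_length_bp)
    return np.sort(np.array(pos, dtype=np.int64))


def _site_table(config: SimConfig, pos: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "id": [f"snp{i}" for i in range(len(pos))],
            "ref": "A",
            "alt": "G",
        },
        columns=SITE_COLUMNS,
    )


def _mosaic_haplotypes(freqs: np.ndarray, pos: np.ndarray, n_hap: int,
                       config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Mosaic copies of a founder pool with geometric segment lengths.

    Founders are independent Bernoulli draws per site from ``freqs``.  Each
    emitted haplotype copies one founder and switches to a random founder
    between adjacent sites with probability ``1 - (1-r)^gap`` (per-bp switch
    rate ``r``), which yields approximately exponential copy-segment lengths
    and hence haplotype homozygosity that decays with distance.
    """
    m = len(freqs)
    founders = (rng.random((config.founder_pool, m)) < freqs).astype(np.uint8)
    if config.founder_pool == 1:
        return np.tile(founders, (n_hap, 1))
    gaps = np.diff(pos).astype(np.float64)
    p_switch = -np.expm1(gaps * np.log1p(-config.copy_switch_rate))
    switch = np.zeros((n_hap, m), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_hap, m - 1)) < p_switch
    # founder index drawn fresh at every switch point, carried forward otherwise
    draws = rng.integers(0, config.founder_pool, size=(n_hap, m))
    seg_start = np.maximum.accumulate(
        np.where(switch, np.arange(m)[None, :], 0), axis=1
    )
    founder_idx = np.take_along_axis(draws, seg_start, axis=1)
    return founders[founder_idx, np.arange(m)[None, :]]


def simulate_panels(freqs: SiteFrequencies, sites: pd.DataFrame, config: SimConfig,
                    rng: np.random.Generator) -> dict[str, HaplotypePanel]:
    """Build the three phased panels (``ref_a``, ``ref_b``, ``admixed``).

    Each panel has its own founder pool drawn from its population's
    frequencies; admixed samples start as pure recipient-population
    (``ref_a``-frequency) haplotypes and acquire donor ancestry in
    :func:`implant_introgression`.
    """
    if len(freqs.freq_a) != len(freqs.freq_b):
        raise ValueError("frequency vectors must have equal length")
    pos = sites["pos"].to_numpy()
    spec = {
        "ref_a": (config.n_ref_a, freqs.freq_a, "dog"),
        "ref_b": (config.n_ref_b, freqs.freq_b, "wolf"),
        "admixed": (config.n_admixed, freqs.freq_a, "hdog"),
    }
    panels = {}
    for group, (n, f, prefix) in spec.items():
        hap = _mosaic_haplotypes(f, pos, 2 * n, config, rng)
        panels[group] = HaplotypePanel(
            samples=[f"{prefix}{i:02d}" for i in range(n)],
            groups=[group] * n,
            sites=sites,
            haplotypes=hap,
        )
    return panels


def implant_introgression(
    admixed_panel: HaplotypePanel,
    donor_panel: HaplotypePanel,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[HaplotypePanel, TruthTracks]:
    """Place background donor segments and the focal donor tract.

    Background: each admixed haplotype receives a Poisson number of donor
    segments with exponential lengths (mean ``background_segment_bp``) at
    uniform starts, totalling ``background_admixture`` of the chromosome in
    expectation; each segment is copied from a random donor haplotype.

    Tract: a fraction ``tract_freq`` of admixed haplotypes (exact count,
    sampled without replacement) has the tract interval replaced by donor
    sequence — the same single donor haplotype for every carrier when
    ``sweep`` is set, otherwise an independent random donor haplotype each.
    """
    if not admixed_panel.sites["pos"].equals(donor_panel.sites["pos"]):
        raise ValueError("admixed and donor panels must share the site map")
    pos = admixed_panel.sites["pos"].to_numpy()
    lo, hi = config.tract_bp
    tract_idx = np.flatnonzero((pos >= lo) & (pos <= hi))
    if tract_idx.size == 0:
        raise ValueError("tract interval contains no sites")

    hap = admixed_panel.haplotypes.copy()
    donors = donor_panel.haplotypes
    n_hap, m = hap.shape
    is_donor = np.zeros((n_hap, m), dtype=bool)

    # --- background segments -------------------------------------------------
    if config.background_admixture > 0:
        lam = config.background_admixture * config.chrom_length_bp / config.background_segment_bp
        for h in range(n_hap):
            for _ in range(rng.poisson(lam)):
                length = rng.exponential(config.background_segment_bp)
                start = rng.uniform(1, config.chrom_length_bp)
                seg = (pos >= start) & (pos <= start + length)
                if not seg.any():
                    continue
                src = donors[rng.integers(donors.shape[0])]
                hap[h, seg] = src[seg]
                is_donor[h, seg] = True

    # --- focal tract ---------------------------------------------------------
    n_carrier = int(round(config.tract_freq * n_hap))
    carriers = rng.choice(n_hap, size=n_carrier, replace=False)
    if config.sweep:
        founder = donors[rng.integers(donors.shape[0])]
        for h in carriers:
            hap[h, tract_idx] = founder[tract_idx]
            is_donor[h, tract_idx] = True
    else:
        for h in carriers:
            src = donors[rng.integers(donors.shape[0])]
            hap[h, tract_idx] = src[tract_idx]
            is_donor[h, tract_idx] = True

    dosage = (is_donor[0::2].astype(np.int8) + is_donor[1::2].astype(np.int8))
    truth = TruthTracks(
        dosage=dosage,
        hap_is_donor=is_donor,
        tract_bp=(lo, hi),
        tract_site_idx=tract_idx,
    )
    # consistency by construction: dosage must match the haplotype origin mask
    assert (dosage == is_donor[0::2].astype(np.int8)
            + is_donor[1::2].astype(np.int8)).all()
    out = HaplotypePanel(
        samples=list(admixed_panel.samples),
        groups=list(admixed_panel.groups),
        sites=admixed_panel.sites,
        haplotypes=hap,
    )
    return out, truth


def apply_missingness(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Independently set each genotype missing with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.dosage.shape) < rate
    dos = gm.dosage.copy()
    dos[mask] = MISSING
    return GenotypeMatrix(
        samples=list(gm.samples), groups=list(gm.groups), sites=gm.sites, dosage=dos
    )


def _combine_panels(panels: dict[str, HaplotypePanel]) -> HaplotypePanel:
    order = ["ref_a", "ref_b", "admixed"]
    return HaplotypePanel(
        samples=sum((panels[g].samples for g in order), []),
        groups=sum((panels[g].groups for g in order), []),
        sites=panels["ref_a"].sites,
        haplotypes=np.vstack([panels[g].haplotypes for g in order]),
    )


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: frequencies, panels, introgression, missingness."""
    rng = np.random.default_rng(config.seed)
    freqs = draw_site_frequencies(config, rng)
    pos = draw_positions(config, rng)
    sites = _site_table(config, pos)
    panels = simulate_panels(freqs, sites, config, rng)
    panels["admixed"], truth = implant_introgression(
        panels["admixed"], panels["ref_b"], config, rng
    )
    panel = _combine_panels(panels)
    rng_missing = int(rng.integers(2**31))
    gm = panel.to_genotypes()
    if config.missing_rate > 0:
        gm = apply_missingness(gm, config.missing_rate, rng_missing)
    missing_mask = gm.dosage == MISSING
    return SimResult(
        config=config,
        sites=sites,
        freqs=freqs,
        panel=panel,
        genotypes=gm,
        truth=truth,
        missing_mask=missing_mask,
    )
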