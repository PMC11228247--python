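"""Synthetic islet cohorts and synthetic two-channel images.

The generator emulates the architecture the analysis assumes for NOD-mouse
islets during insulitis:

* a β-cell-rich core with an α-cell-enriched mantle (``mantle_bias``),
* immune cells concentrated in a peri-islet band outside the rim (rim
  distances truncated-normal within the band, positions uniform by arc
  length along the offset curve at the drawn distance), with a minority
  fraction inside the islet placed the same way by depth,
* islet-to-islet heterogeneity of the T/β ratio spanning the early /
  intermediate / late staging ranges, sampled log-uniformly within each
  stage (the ranked spectrum of such ratios is approximately exponential),
* an optional ground-truth attraction of immune cells toward α-cell-rich
  regions, controlled by a single knob λ (``alpha_attraction``): immune
  positions are accepted with probability proportional to ``1 + λ·ρ_α``
  where ρ_α is a Gaussian-kernel α-cell density (kernel sd 25 μm,
  comparable to the 20 μm link threshold).  λ = 0 gives unbiased
  placement; increasing λ produces the polarized peri-insulitis pattern
  the network statistics are designed to detect.

Everything is reproducible from integer seeds via
``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point

from .geometry import (
    CellRecord,
    IsletMap,
    OffsetCurveCache,
    RimPolygon,
    signed_distance_to_rim,
)

__all__ = [
    "GenerationError",
    "IsletSimParams",
    "CohortSpec",
    "ColocSimParams",
    "generate_islet",
    "generate_cohort",
    "generate_coloc_images",
]

#: Gaussian kernel sd (μm) of the α-cell density field used for the
#: immune attraction bias.
ALPHA_KERNEL_SD = 25.0

#: Default per-stage target T/β ratio ranges.  Cutoffs are the staging
#: cutoffs (0.51, 1.25); the lower and upper ends bracket the ratios
#: reported for real NOD cohorts at desk scale.
STAGE_RATIO_RANGES = {
    "early": (0.03, 0.51),
    "intermediate": (0.51, 1.25),
    "late": (1.25, 5.0),
}


class GenerationError(RuntimeError):
    """Raised when dart-throwing cannot satisfy the packing constraints."""


@dataclass(frozen=True)
class IsletSimParams:
    """Parameters of one synthetic islet.

    Defaults describe a medium-sized islet (~11,000 μm² cross-section):
    40 β-cells, 30% of endocrine cells α, nucleus spacing 10 μm (a typical
    islet-cell diameter, so the 15/20/25 μm link thresholds span one to
    two cell diameters), immune cells mostly in a 40 μm peri-islet band
    with 20% inside the islet, and no α attraction (λ = 0).
    """

    n_beta: int = 40
    alpha_fraction: float = 0.3
    mantle_bias: float = 0.8
    islet_radius: float = 60.0
    min_spacing: float = 10.0
    target_t_beta_ratio: float = 0.3
    n_macrophage: int = 8
    n_myeloid: int = 8
    peri_band: float = 40.0
    inside_fraction: float = 0.2
    alpha_polarity: float = 0.8
    alpha_attraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_beta, self.n_macrophage, self.n_myeloid) < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0.0 <= self.alpha_fraction <= 1.0:
            raise ValueError("alpha_fraction must be in [0, 1]")
        if not 0.0 <= self.mantle_bias <= 1.0:
            raise ValueError("mantle_bias must be in [0, 1]")
        if not 0.0 <= self.alpha_polarity <= 1.0:
            raise ValueError("alpha_polarity must be in [0, 1]")
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be > 0")
        if self.alpha_attraction < 0:
            raise ValueError("alpha_attraction (λ) must be >= 0")
        if self.target_t_beta_ratio < 0:
            raise ValueError("target_t_beta_ratio must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A staged cohort: islets per stage, per-stage T/β ratio ranges, seed.

    The default 44/46/44 split yields a 134-islet cohort spread over 11
    mice, matching the scale of a typical NOD staging experiment.
    """

    n_islets: dict = field(
        default_factory=lambda: {"early": 44, "intermediate": 46, "late": 44}
    )
    ratio_ranges: dict = field(default_factory=lambda: dict(STAGE_RATIO_RANGES))
    base_params: IsletSimParams = field(default_factory=IsletSimParams)
    n_mice: int = 11
    master_seed: int = 0

    def __post_init__(self) -> None:
        for stage, (lo, hi) in self.ratio_ranges.items():
            if not 0 <= lo < hi:
                raise ValueError(f"bad ratio range for stage {stage!r}")


def _jittered_rim(rng: np.random.Generator, radius: float, n_vertices: int = 24) -> RimPolygon:
    """Convex-ish star-shaped polygon of roughly the given radius.

    Radial jitter is smoothed with a circular moving average so the
    polygon stays simple (star-shaped about the origin by construction).
    """
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    jitter = rng.uniform(-0.25, 0.25, n_vertices)
    kernel = np.ones(3) / 3.0
    jitter = np.convolve(np.r_[jitter[-1], jitter, jitter[0]], kernel, mode="valid")
    radii = radius * (1.0 + jitter)
    verts = np.c_[radii * np.cos(angles), radii * np.sin(angles)]
    return RimPolygon(verts)


def _dart_throw_in_polygon(
    rng: np.random.Generator,
    rim: RimPolygon,
    n: int,
    min_spacing: float,
    max_attempts_per_cell: int = 400,
) -> np.ndarray:
    """Uniform positions inside the rim with pairwise min_spacing rejection."""
    poly = rim.polygon
    minx, miny, maxx, maxy = poly.bounds
    placed = np.empty((0, 2))
    attempts = 0
    budget = max_attempts_per_cell * max(n, 1)
    while len(placed) < n:
        if attempts >= budget:
            raise GenerationError(
                f"could not pack {n} cells at spacing {min_spacing} μm "
                f"inside a {poly.area:.0f} μm² rim"
            )
        attempts += 1
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if not poly.covers(Point(p)):
            continue
        if len(placed) and np.min(np.hypot(*(placed - p).T)) < min_spacing:
            continue
        placed = np.vstack([placed, p])
    return placed


def _assign_alpha_labels(
    rng: np.random.Generator,
    positions: np.ndarray,
    depths: np.ndarray,
    n_alpha: int,
    mantle_bias: float,
    alpha_polarity: float,
) -> np.ndarray:
    """Pick which endocrine cells are α: rim-weighted, angularly polarized.

    ``depths`` are |signed distance| to the rim (all cells inside).  With
    mantle_bias 0 the radial choice is uniform; with 1 the weight falls
    linearly to zero at the deepest cell, concentrating α in the outer
    shell.  ``alpha_polarity`` adds a cosine modulation about a random
    pole direction, producing the α-rich / α-poor sectors seen in real
    islets (0 = angularly homogeneous mantle).  Returns a boolean α mask.
    """
    n = len(depths)
    if n_alpha >= n:
        return np.ones(n, dtype=bool)
    dmax = depths.max()
    shell = 1.0 - depths / dmax if dmax > 0 else np.ones(n)
    w = (1.0 - mantle_bias) + mantle_bias * shell
    pole = rng.uniform(0.0, 2.0 * np.pi)
    if alpha_polarity > 0:
        theta = np.arctan2(positions[:, 1], positions[:, 0])
        w = w * (1.0 + alpha_polarity * np.cos(theta - pole))
    w = np.clip(w, 1e-12, None)
    idx = rng.choice(n, size=n_alpha, replace=False, p=w / w.sum())
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask


def _alpha_density(points: np.ndarray, alpha_pos: np.ndarray, sd: float = ALPHA_KERNEL_SD) -> np.ndarray:
    """Gaussian-kernel α-cell density at each query point.

    Count-weighted (sum over α cells, unnormalized), so a sector with
    twice the α cells reads as twice the density and the attraction knob
    λ spans no-bias to near-deterministic preference over its working
    range.
    """
    if len(alpha_pos) == 0:
        return np.zeros(len(points))
    d2 = ((points[:, None, :] - alpha_pos[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sd * sd)).sum(axis=1)


def _place_immune(
    rng: np.random.Generator,
    rim: RimPolygon,
    cache: OffsetCurveCache,
    n: int,
    inside_fraction: float,
    peri_band: float,
    islet_radius: float,
    lam: float,
    alpha_pos: np.ndarray,
    max_attempts_per_cell: int = 2000,
) -> np.ndarray:
    """Place immune cells at normal rim distances inside or outside the islet.

    Each cell is first assigned inside/outside (Bernoulli
    ``inside_fraction``).  Its signed rim distance is then drawn from a
    truncated normal — outside: N(peri_band/2, peri_band/6) on
    (0, peri_band]; inside depth: N(islet_radius/3, islet_radius/6)
    truncated to feasible depths — and the cell is placed uniformly by
    arc length on the level set of that distance.  Placements are
    accepted with probability ∝ (1 + λ·ρ_α(x)), which skews both the
    radial and the angular law toward α-rich regions when λ > 0.
    """
    if n == 0:
        return np.empty((0, 2))
    if lam > 0 and len(alpha_pos):
        rho_max = _alpha_density(alpha_pos, alpha_pos).max()
    else:
        rho_max = 0.0
    mu_out, sd_out = peri_band / 2.0, peri_band / 6.0
    mu_in, sd_in = islet_radius / 3.0, islet_radius / 6.0
    inside_flags = rng.random(n) < inside_fraction
    placed = np.empty((n, 2))
    for i in range(n):
        want_inside = bool(inside_flags[i])
        for _ in range(max_attempts_per_cell):
            if want_inside:
                depth = rng.normal(mu_in, sd_in)
                if depth <= 0:
                    continue
                d = -depth
                if not cache.feasible(d):
                    continue
            else:
                d = rng.normal(mu_out, sd_out)
                if d <= 0 or d > peri_band:
                    continue
            p = np.asarray(cache.sample_point(d, rng.random()))
            if lam > 0:
                rho = _alpha_density(p[None, :], alpha_pos)[0]
                if rng.random() >= (1.0 + lam * rho) / (1.0 + lam * rho_max):
                    continue
            placed[i] = p
            break
        else:
            raise GenerationError("immune placement rejection sampling exhausted")
    return placed


def generate_islet(
    params: IsletSimParams,
    islet_id: str = "islet_0",
    mouse_id: str = "m1",
    tissue_edge_flag: bool = False,
) -> IsletMap:
    """Generate one synthetic islet, fully reproducible from ``rng_seed``.

    The rim is a jittered convex-ish polygon of roughly ``islet_radius``;
    endocrine cells are dart-thrown inside it with ``min_spacing``
    rejection and α labels biased toward the rim; T-cell count is
    ``round(target_t_beta_ratio · n_beta)``; immune cells are placed
    inside the rim or in the peri-islet band with acceptance probability
    ∝ (1 + λ·ρ_α).
    """
    rng = np.random.default_rng(params.rng_seed)
    rim = _jittered_rim(rng, params.islet_radius)

    if params.alpha_fraction >= 1.0:
        raise ValueError("alpha_fraction must be < 1 when n_beta > 0")
    n_endocrine = int(round(params.n_beta / (1.0 - params.alpha_fraction)))
    n_alpha = n_endocrine - params.n_beta
    disc_area = np.pi * (params.min_spacing / 2.0) ** 2
    if n_endocrine * disc_area >= rim.polygon.area:
        raise GenerationError("infeasible endocrine packing for this rim")

    endo_pos = _dart_throw_in_polygon(rng, rim, n_endocrine, params.min_spacing)
    depths = np.abs(signed_distance_to_rim(endo_pos, rim))
    alpha_mask = _assign_alpha_labels(
        rng, endo_pos, depths, n_alpha, params.mantle_bias, params.alpha_polarity
    )
    alpha_pos = endo_pos[alpha_mask]

    n_t = int(round(params.target_t_beta_ratio * params.n_beta))
    counts = {"T": n_t, "macrophage": params.n_macrophage, "myeloid": params.n_myeloid}

    cells: list[CellRecord] = []
    for i, (p, is_a) in enumerate(zip(endo_pos, alpha_mask)):
        ctype = "alpha" if is_a else "beta"
        cells.append(CellRecord(f"{ctype[0]}{i:04d}", ctype, float(p[0]), float(p[1])))
    prefix = {"T": "t", "macrophage": "f", "myeloid": "y"}
    cache = OffsetCurveCache(rim)
    for ctype, n in counts.items():
        pos = _place_immune(
            rng, rim, cache, n, params.inside_fraction, params.peri_band,
            params.islet_radius, params.alpha_attraction, alpha_pos,
        )
        for i, p in enumerate(pos):
            cells.append(
                CellRecord(f"{prefix[ctype]}{i:04d}", ctype, float(p[0]), float(p[1]))
            )

    return IsletMap(
        islet_id=islet_id,
        mouse_id=mouse_id,
        rim=rim,
        cells=cells,
        tissue_edge_flag=tissue_edge_flag,
    )


def _sample_stage_ratio(
    rng: np.random.Generator, stage: str, lo: float, hi: float, n_beta: int
) -> float:
    """Log-uniform ratio in (lo, hi) whose count-quantized value stays in-stage.

    The realized insulitis degree is ``round(r·n_beta)/n_beta``; ratios
    whose quantized value would land in a neighbouring stage bin (the
    early bin is half-open at the top, the late bin open at the bottom)
    are redrawn, so a cohort always round-trips its intended stages.
    """
    def in_bin(v: float) -> bool:
        if stage == "early":
            return lo <= v < hi
        if stage == "late":
            return lo < v <= hi
        return lo <= v <= hi

    for _ in range(1000):
        r = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if in_bin(round(r * n_beta) / n_beta):
            return r
    raise GenerationError("could not sample a stage-consistent ratio")


def generate_cohort(spec: CohortSpec) -> list[IsletMap]:
    """Generate a staged cohort; per-islet seeds derive from the master seed.

    Islets are emitted stage by stage (early, intermediate, late) and
    assigned to mice round-robin.  Target T/β ratios are drawn
    log-uniformly within each stage's range, redrawn if count
    quantization would push the realized degree into a different stage.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    ratio_rng = np.random.default_rng(ss.spawn(1)[0])
    cohort: list[IsletMap] = []
    k = 0
    for stage in ("early", "intermediate", "late"):
        n = spec.n_islets.get(stage, 0)
        lo, hi = spec.ratio_ranges[stage]
        for _ in range(n):
            ratio = _sample_stage_ratio(ratio_rng, stage, lo, hi, spec.base_params.n_beta)
            seed = int(np.random.SeedSequence([spec.master_seed, 7919, k]).generate_state(1)[0] % (2**31))
            params = replace(spec.base_params, target_t_beta_ratio=ratio, rng_seed=seed)
            cohort.append(
                generate_islet(
                    params,
                    islet_id=f"islet_{k:04d}",
                    mouse_id=f"m{k % spec.n_mice + 1}",
                )
            )
            k += 1
    return cohort


# ---------------------------------------------------------------------------
# Synthetic two-channel images for the colocalization stage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColocSimParams:
    """Parameters of a synthetic two-channel spot-image pair.

    ``overlap_fraction`` of the channel-2 spots share centres with
    channel-1 spots; ``bleed_coefficient`` adds that fraction of the
    channel-1 signal into channel 2 (spectral bleed-through);
    ``noise_sd`` is the Gaussian background sd in intensity units.
    """

    shape: tuple = (128, 128)
    pixel_size: float = 0.5
    n_spots: int = 25
    spot_sigma_px: float = 2.0
    amplitude: float = 3000.0
    overlap_fraction: float = 0.5
    bleed_coefficient: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not 0.0 <= self.bleed_coefficient <= 1.0:
            raise ValueError("bleed_coefficient must be in [0, 1]")


@dataclass(frozen=True)
class ColocGroundTruth:
    """Spot centres, boolean signal masks per channel, and the bleed factor."""

    centers1: np.ndarray
    centers2: np.ndarray
    mask1: np.ndarray
    mask2: np.ndarray
    bleed_coefficient: float


def _render_spots(shape, centers, sigma, amplitude) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, dtype=float)
    for cy, cx in centers:
        img += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    return img


def generate_coloc_images(params: ColocSimParams):
    """Two Gaussian-spot channel images with known overlap and bleed-through.

    Returns ``(ch1, ch2, truth)`` where the channels are float pixel
    arrays (quantized to integer intensity levels) and ``truth`` records
    the spot centres, per-channel signal masks and the bleed coefficient.
    """
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.shape
    n = params.n_spots
    # Centers are uniform over the whole frame (edge spots render
    # partially); restricting them to an interior margin would give both
    # channels a shared border-vs-interior structure that reads as
    # spurious colocalization.
    centers1 = np.c_[rng.uniform(0, h, n), rng.uniform(0, w, n)]
    n_shared = int(round(params.overlap_fraction * n))
    shared = centers1[rng.choice(n, n_shared, replace=False)] if n_shared else np.empty((0, 2))
    # Non-shared channel-2 spots are kept clear of every channel-1 spot,
    # so overlap_fraction is the true colocalized fraction rather than a
    # lower bound corrupted by chance coincidences.
    min_sep = 6.0 * params.spot_sigma_px
    own = []
    while len(own) < n - n_shared:
        c = rng.uniform((0, 0), (h, w))
        if np.min(np.hypot(*(centers1 - c).T)) >= min_sep:
            own.append(c)
    own = np.asarray(own, dtype=float).reshape(-1, 2)
    centers2 = np.vstack([shared, own])

    sig1 = _render_spots(params.shape, centers1, params.spot_sigma_px, params.amplitude)
    sig2 = _render_spots(params.shape, centers2, params.spot_sigma_px, params.amplitude)
    ch1 = sig1.copy()
    ch2 = sig2 + params.bleed_coefficient * sig1
    if params.noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, params.noise_sd, params.shape)
        ch2 = ch2 + rng.normal(0.0, params.noise_sd, params.shape)
    # Quantize like a 16-bit camera: integer levels, clipped at zero.
    ch1 = np.clip(np.round(ch1), 0, 65535)
    ch2 = np.clip(np.round(ch2), 0, 65535)

    level = 0.02 * params.amplitude
    truth = ColocGroundTruth(
        centers1=centers1,
        centers2=centers2,
        mask1=sig1 > level,
        mask2=sig2 > level,
        bleed_coefficient=params.bleed_coefficient,
    )
    return ch1, ch2, truth
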