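"""Rim-distance-preserving randomization null model for immune positions.

To judge whether observed endocrine–immune proximities could arise by
chance, immune cells are randomly repositioned around the islet while the
endocrine cells stay fixed and the immune cells' *distance-to-rim
statistics* are preserved:

1. immune cells are split into an inside group (signed rim distance
   <= 0; cells exactly on the rim count as inside) and an outside group
   (> 0);
2. for each non-empty group a pool of 1,000 normal draws is generated
   from the group's empirical mean and (sample) standard deviation of
   signed distances — the pool is materialized literally so the
   procedure is auditable;
3. each immune cell's distance is replaced by a uniform draw from its
   group's pool (rejecting draws on the wrong side of the rim, or deeper
   than the rim allows, with bounded redraws), and the cell is placed
   uniformly by arc length on the level set of that signed distance (the
   offset curve of the rim) — unbiased for non-circular rims;
4. the repositioned network is rebuilt with *identical* membership and
   link rules and K_avg recorded; the whole procedure is repeated over
   (by default) 100 seeds.

Group membership (inside/outside) and group counts are preserved exactly
in every seed, and the seed-averaged distance to the rim stays close to
the empirical group mean.  A supplementary variant fixes the immune cells
instead and shuffles α/β labels over the endocrine positions.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import CellRecord, IsletMap, OffsetCurveCache
from .networks import DEFAULT_IMMUNE_MARGIN, DEFAULT_THRESHOLD, build_network, k_avg

__all__ = [
    "DistanceStats",
    "RandomizationEnsemble",
    "OffsetCurveCache",
    "empirical_distance_stats",
    "randomize_immune_positions",
    "random_kavg_ensemble",
    "shuffle_alpha_labels",
    "compare_experimental_vs_random",
]

logger = logging.getLogger(__name__)

POOL_SIZE = 1000
MAX_REDRAWS = 100
DEFAULT_N_SEEDS = 100


@dataclass(frozen=True)
class DistanceStats:
    """Signed rim-distance statistics of one immune group, with its pool."""

    group: str  # "inside" or "outside"
    mean: float
    sd: float
    n_cells: int
    pool: np.ndarray

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if len(self.pool) != POOL_SIZE:
            raise ValueError(f"pool must hold {POOL_SIZE} draws")


@dataclass
class RandomizationEnsemble:
    """Per-seed K_avg of randomized networks against the empirical value."""

    islet_id: str
    pair: tuple
    n_seeds: int
    kavg_random: np.ndarray
    kavg_experimental: float
    positions: list | None = None


def empirical_distance_stats(
    islet: IsletMap, immune_type: str, pool_seed: int = 0
):
    """Inside/outside signed-distance statistics with seeded 1,000-draw pools.

    Returns ``(inside_stats, outside_stats)``; a group with no cells is
    returned as ``None`` and skipped by the randomization.  Sample sd
    (ddof=1) is used; a single-cell group gets sd 0.
    """
    d = islet.signed_distances(immune_type)
    if len(d) == 0:
        return None, None
    rng = np.random.default_rng(pool_seed)
    out = []
    for group, mask in (("inside", d <= 0), ("outside", d > 0)):
        vals = d[mask]
        if len(vals) == 0:
            out.append(None)
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        pool = rng.normal(mean, sd, POOL_SIZE)
        out.append(DistanceStats(group, mean, sd, int(len(vals)), pool))
    return tuple(out)


def _randomize(
    islet: IsletMap,
    immune_type: str,
    stats_inside,
    stats_outside,
    rng: np.random.Generator,
    cache: OffsetCurveCache,
):
    """Reposition all immune cells of one type; returns (records, distances)."""
    cells = islet.cells_of_type(immune_type)
    d_emp = islet.signed_distances(immune_type)
    records: list[CellRecord] = []
    dists = np.empty(len(cells))
    for i, (cell, d0) in enumerate(zip(cells, d_emp)):
        inside = d0 <= 0
        stats = stats_inside if inside else stats_outside
        d_new = None
        for _ in range(MAX_REDRAWS):
            cand = float(stats.pool[rng.integers(POOL_SIZE)])
            if inside:
                if cand > 0 or not cache.feasible(cand):
                    continue
            else:
                if cand <= 0:
                    continue
            d_new = cand
            break
        if d_new is None:
            # Fall back to the cell's own empirical distance (always
            # feasible: the cell exists at that depth) with a random
            # position along its level set.
            logger.debug(
                "islet %s cell %s: no feasible draw after %d redraws; "
                "using empirical distance",
                islet.islet_id, cell.cell_id, MAX_REDRAWS,
            )
            d_new = float(d0)
        x, y = cache.sample_point(d_new, rng.random())
        records.append(CellRecord(cell.cell_id, cell.cell_type, x, y))
        dists[i] = d_new
    return records, dists


def _seed_for(master_seed: int, islet_id: str, index: int) -> np.random.SeedSequence:
    """Stable per-(islet, index) seed: master seed hashed with the islet id."""
    tag = zlib.crc32(islet_id.encode()) % (2**31)
    return np.random.SeedSequence([int(master_seed) % (2**31), tag, index])


def randomize_immune_positions(
    islet: IsletMap, immune_type: str, seed: int
) -> list[CellRecord]:
    """One randomized repositioning of all immune cells of one type.

    Endocrine cells are untouched; each immune cell keeps its
    inside/outside group; deterministic given ``seed`` (the pool and the
    draws derive from it).  Returns the repositioned cell records.
    """
    ss = np.random.SeedSequence(seed)
    pool_ss, draw_ss = ss.spawn(2)
    stats_in, stats_out = empirical_distance_stats(
        islet, immune_type, pool_seed=pool_ss
    )
    cache = OffsetCurveCache(islet.rim)
    rng = np.random.default_rng(draw_ss)
    records, _ = _randomize(islet, immune_type, stats_in, stats_out, rng, cache)
    return records


def random_kavg_ensemble(
    islet: IsletMap,
    pair: tuple,
    threshold: float = DEFAULT_THRESHOLD,
    n_seeds: int = DEFAULT_N_SEEDS,
    master_seed: int = 0,
    immune_margin: float = DEFAULT_IMMUNE_MARGIN,
    keep_positions: bool = False,
) -> RandomizationEnsemble:
    """Empirical vs randomized K_avg for one (endocrine, immune) pair.

    Per seed: reposition the immune cells, rebuild the pair network with
    identical membership and link rules, and record K_avg of the
    endocrine type.  The distance pool is generated once per islet; the
    per-seed draws derive from ``master_seed`` hashed with the islet id
    and the seed index, so the ensemble is stable under cohort
    reordering.
    """
    endo_type, immune_type = pair
    exp_net = build_network(islet, set(pair), threshold, immune_margin)
    kavg_exp = k_avg(exp_net, endo_type)

    stats_in, stats_out = empirical_distance_stats(
        islet, immune_type, pool_seed=_seed_for(master_seed, islet.islet_id, 0)
    )
    cache = OffsetCurveCache(islet.rim)

    # Endocrine member positions are fixed across seeds.
    endo_cells = islet.cells_of_type(endo_type)
    endo_d = islet.signed_distances(endo_type)
    endo_pos = np.array(
        [(c.x, c.y) for c, d in zip(endo_cells, endo_d) if d <= 0], dtype=float
    ).reshape(-1, 2)
    n_endo = len(endo_pos)

    kavg_rand = np.empty(n_seeds)
    kept = [] if keep_positions else None
    for s in range(n_seeds):
        rng = np.random.default_rng(_seed_for(master_seed, islet.islet_id, s + 1))
        records, dists = _randomize(
            islet, immune_type, stats_in, stats_out, rng, cache
        )
        if kept is not None:
            kept.append(records)
        if n_endo == 0:
            kavg_rand[s] = float("nan")
            continue
        member = dists <= immune_margin
        if not member.any():
            kavg_rand[s] = 0.0
            continue
        ipos = np.array([(r.x, r.y) for r, m in zip(records, member) if m])
        dmat = np.hypot(
            endo_pos[:, 0:1] - ipos[None, :, 0], endo_pos[:, 1:2] - ipos[None, :, 1]
        )
        kavg_rand[s] = float((dmat <= threshold).sum() / n_endo)

    return RandomizationEnsemble(
        islet_id=islet.islet_id,
        pair=(endo_type, immune_type),
        n_seeds=n_seeds,
        kavg_random=kavg_rand,
        kavg_experimental=kavg_exp,
        positions=kept,
    )


def shuffle_alpha_labels(islet: IsletMap, seed: int) -> IsletMap:
    """Supplementary null: permute α/β labels over the endocrine positions.

    Immune cells and all positions stay fixed; only which endocrine cells
    carry the α label changes, preserving the α and β counts.
    """
    rng = np.random.default_rng(seed)
    endo_idx = [i for i, c in enumerate(islet.cells) if c.cell_type in ("alpha", "beta")]
    labels = [islet.cells[i].cell_type for i in endo_idx]
    perm = rng.permutation(len(labels))
    new_cells = list(islet.cells)
    for slot, p in zip(endo_idx, perm):
        c = islet.cells[slot]
        new_cells[slot] = CellRecord(c.cell_id, labels[p], c.x, c.y)
    return IsletMap(
        islet_id=islet.islet_id,
        mouse_id=islet.mouse_id,
        rim=islet.rim,
        cells=new_cells,
        tissue_edge_flag=islet.tissue_edge_flag,
    )


def compare_experimental_vs_random(ensembles: list[RandomizationEnsemble]) -> dict:
    """Paired t-test of experimental K_avg vs per-islet seed-mean K_avg.

    One pair per islet (islets with undefined values dropped listwise);
    fewer than 3 pairs marks the report underpowered, with no p-value.
    """
    pairs = [
        (e.kavg_experimental, float(np.nanmean(e.kavg_random)))
        for e in ensembles
        if not math.isnan(e.kavg_experimental) and not np.all(np.isnan(e.kavg_random))
    ]
    n = len(pairs)
    if n < 3:
        return {"n": n, "underpowered": True, "t": None, "df": None, "p": None,
                "mean_diff": None, "ci95": None}
    exp = np.array([p[0] for p in pairs])
    rnd = np.array([p[1] for p in pairs])
    diff = exp - rnd
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        t = 0.0 if mean_diff == 0.0 else math.copysign(math.inf, mean_diff)
        p = 1.0 if mean_diff == 0.0 else 0.0
        ci = (mean_diff, mean_diff)
    else:
        res = sps.ttest_rel(exp, rnd)
        t, p = float(res.statistic), float(res.pvalue)
        half = float(sps.t.ppf(0.975, df)) * sd / math.sqrt(n)
        ci = (mean_diff - half, mean_diff + half)
    return {"n": n, "underpowered": False, "t": t, "df": df, "p": p,
            "mean_diff": mean_diff, "ci95": ci}
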