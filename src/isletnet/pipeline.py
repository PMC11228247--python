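"""End-to-end orchestration: cohort → staging → networks → nulls → report.

``run_pipeline`` executes, in order: load or simulate a cohort, exclude
tissue-edge islets, stage every islet by insulitis degree, build
heterotypic networks at each link threshold, run the randomization null
model for the α–immune pairs, the outer-ring α-linked analysis and the
half-islet polarity analysis, compare immune–immune network strengths,
and write fixed-schema CSV tables plus a ``report.json`` that carries
the serialized configuration and master seed, so any number in the
report can be regenerated from the inputs.  The run is deterministic for
a fixed configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from .geometry import IMMUNE_TYPES, IsletMap
from .networks import (
    build_network,
    degree_correlation,
    degree_summary,
    half_islet_proportions,
    half_polarity_points,
    k_avg,
    outer_ring_immune_networks,
)
from .nullmodels import compare_experimental_vs_random, random_kavg_ensemble
from .simulate import CohortSpec, IsletSimParams, generate_cohort
from .staging import filter_edge_islets, stage_cohort
from .stats import (
    stat_linear_regression,
    stat_rm_anova_gg,
    stat_wilcoxon_signed_rank,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("early", "intermediate", "late")
ALPHA_PAIRS = (("alpha", "T"), ("alpha", "macrophage"), ("alpha", "myeloid"))
IMMUNE_PAIRS = (("T", "myeloid"), ("T", "macrophage"), ("myeloid", "macrophage"))
NETWORK_PAIRS = (
    ("alpha", "beta"), ("alpha", "T"), ("alpha", "macrophage"), ("alpha", "myeloid"),
    ("beta", "T"), ("beta", "macrophage"), ("beta", "myeloid"),
    ("T", "myeloid"), ("T", "macrophage"), ("myeloid", "macrophage"),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either point ``cells_path``/``rims_path`` at an existing cohort or
    leave them unset to simulate one from ``cohort``.  The two margins
    are deliberately distinct: ``degree_margin`` (60 μm) is the staging
    count region, ``immune_margin`` (20 μm) the network membership band.
    """

    cells_path: str | None = None
    rims_path: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    thresholds: tuple = (15.0, 20.0, 25.0)
    primary_threshold: float = 20.0
    immune_margin: float = 20.0
    degree_margin: float = 60.0
    outer_band: float = 20.0
    n_seeds: int = 100
    stage_cutoffs: tuple = (0.51, 1.25)
    size_cutoffs: tuple = (7000.0, 20000.0)
    master_seed: int = 0
    outdir: str = "isletnet_out"

    def __post_init__(self) -> None:
        if min(self.immune_margin, self.degree_margin, self.outer_band) <= 0:
            raise ValueError("all margins must be > 0")
        if not (self.stage_cutoffs[0] < self.stage_cutoffs[1]
                and self.size_cutoffs[0] < self.size_cutoffs[1]):
            raise ValueError("cutoffs must be ascending")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            c = raw["cohort"]
            base = IsletSimParams(**c.pop("base_params", {}))
            raw["cohort"] = CohortSpec(base_params=base, **c)
        for key in ("thresholds", "stage_cutoffs", "size_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _stage_of(records) -> dict:
    return {r.islet_id: r.stage for r in records}


def _load_or_simulate(config: PipelineConfig) -> list[IsletMap]:
    if config.cells_path is not None:
        if config.rims_path is None:
            raise PipelineError("load: cells_path given without rims_path")
        return iio.read_cohort(config.cells_path, config.rims_path)
    spec = replace(config.cohort, master_seed=config.master_seed)
    return generate_cohort(spec)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all outputs under ``config.outdir``.

    Returns the report dictionary (also written as ``report.json``).
    Any stage failure aborts with a stage-named :class:`PipelineError`
    and removes partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    try:
        return _run(config, outdir, _write_csv, written)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed: {exc}") from exc


def _run(config: PipelineConfig, outdir: Path, _write_csv, written) -> dict:
    # -- load / simulate -------------------------------------------------
    try:
        cohort = _load_or_simulate(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"load/simulate: {exc}") from exc
    simulated = config.cells_path is None
    if simulated:
        iio.write_cohort(cohort, outdir / "cells.csv", outdir / "rims.csv")
        written += [outdir / "cells.csv", outdir / "rims.csv"]

    # -- edge filtering and staging --------------------------------------
    cohort = filter_edge_islets(cohort)
    records = stage_cohort(
        cohort, config.degree_margin, config.stage_cutoffs, config.size_cutoffs
    )
    staged_ids = {r.islet_id for r in records}
    cohort = [i for i in cohort if i.islet_id in staged_ids]
    stage_by_id = _stage_of(records)
    _write_csv(
        pd.DataFrame(
            [
                (r.islet_id, r.degree, r.rank, r.stage, r.area, r.size_class)
                for r in records
            ],
            columns=["islet_id", "degree", "rank", "stage", "area_um2", "size_class"],
        ),
        "stages.csv",
    )

    # -- per-threshold networks and K_avg --------------------------------
    rows = []
    kavg_store: dict = {}
    for thr in config.thresholds:
        for pair in NETWORK_PAIRS:
            for islet in cohort:
                net = build_network(islet, set(pair), thr, config.immune_margin)
                summ = degree_summary(net)
                ka = summ.k_avg.get(pair[0], float("nan"))
                kb = summ.k_avg.get(pair[1], float("nan"))
                kavg_store[(thr, pair, islet.islet_id)] = (ka, kb, len(net.edges))
                rows.append(
                    (islet.islet_id, thr, f"{pair[0]}-{pair[1]}", ka, kb, len(net.edges))
                )
    _write_csv(
        pd.DataFrame(
            rows,
            columns=["islet_id", "threshold_um", "pair", "k_avg_a", "k_avg_b", "n_edges"],
        ),
        "degrees.csv",
    )

    # -- null-model ensembles for the α–immune pairs ---------------------
    thr = config.primary_threshold
    ens_rows = []
    null_tests: dict = {}
    for pair in ALPHA_PAIRS:
        ensembles = []
        for islet in cohort:
            e = random_kavg_ensemble(
                islet, pair, thr, config.n_seeds, config.master_seed,
                config.immune_margin,
            )
            ensembles.append(e)
            for s, kr in enumerate(e.kavg_random):
                ens_rows.append(
                    (islet.islet_id, f"{pair[0]}-{pair[1]}", s, kr, e.kavg_experimental)
                )
        for stage in STAGES:
            sub = [e for e in ensembles if stage_by_id[e.islet_id] == stage]
            null_tests[f"{pair[0]}-{pair[1]}:{stage}"] = (
                compare_experimental_vs_random(sub)
            )
    _write_csv(
        pd.DataFrame(
            ens_rows,
            columns=["islet_id", "pair", "seed", "k_avg_random", "k_avg_experimental"],
        ),
        "ensembles.csv",
    )

    # -- outer-ring α-linked analysis ------------------------------------
    ring_rows = []
    ring_tests: dict = {}
    per_type: dict = {t: {"linked": {}, "non": {}} for t in sorted(IMMUNE_TYPES)}
    for immune_type in sorted(IMMUNE_TYPES):
        for islet in cohort:
            _, _, k_l, k_n = outer_ring_immune_networks(
                islet, immune_type, thr, config.outer_band, config.immune_margin
            )
            per_type[immune_type]["linked"][islet.islet_id] = k_l
            per_type[immune_type]["non"][islet.islet_id] = k_n
            ring_rows.append((islet.islet_id, immune_type, k_l, k_n))
        for stage in STAGES:
            ids = [i.islet_id for i in cohort if stage_by_id[i.islet_id] == stage]
            x = [per_type[immune_type]["linked"][i] for i in ids]
            y = [per_type[immune_type]["non"][i] for i in ids]
            ring_tests[f"{immune_type}:{stage}"] = stat_wilcoxon_signed_rank(x, y)
    _write_csv(
        pd.DataFrame(
            ring_rows,
            columns=["islet_id", "immune_type", "k_avg_alpha_linked", "k_avg_non_alpha_linked"],
        ),
        "outer_ring.csv",
    )

    # -- half-islet polarity ---------------------------------------------
    half_rows = []
    half_tests: dict = {}
    for axis in ("vertical", "horizontal"):
        for islet in cohort:
            res = half_islet_proportions(islet, axis, config.outer_band)
            for t, prop in sorted(res.proportions.items()):
                if prop is None:
                    continue
                half_rows.append((islet.islet_id, axis, t, prop[0], prop[1]))
        for t in sorted(IMMUNE_TYPES):
            xs, ys = half_polarity_points(cohort, t, axis, config.outer_band)
            half_tests[f"alpha-vs-{t}:{axis}"] = stat_linear_regression(xs, ys)
    _write_csv(
        pd.DataFrame(
            half_rows,
            columns=["islet_id", "axis", "cell_type", "prop_first_half", "prop_second_half"],
        ),
        "half_islet.csv",
    )

    # -- cross-network comparisons ---------------------------------------
    # K_avg(α) across the four α networks, and K_avg of the first type
    # across the immune–immune pairs, as repeated measures per islet.
    def _rm_matrix(pairs, ref_index):
        cols = []
        for pair in pairs:
            col = [
                kavg_store[(thr, pair, i.islet_id)][ref_index] for i in cohort
            ]
            cols.append(col)
        return np.array(cols, dtype=float).T

    alpha_pairs_all = (("alpha", "beta"),) + ALPHA_PAIRS
    rm_alpha = stat_rm_anova_gg(
        _rm_matrix(alpha_pairs_all, 0),
        [f"{a}-{b}" for a, b in alpha_pairs_all],
    )
    rm_immune = stat_rm_anova_gg(
        _rm_matrix(IMMUNE_PAIRS, 0),
        [f"{a}-{b}" for a, b in IMMUNE_PAIRS],
    )
    corr_tests = {
        "beta-macrophage_vs_beta-T": degree_correlation(
            cohort, ("beta", "macrophage"), ("beta", "T"), thr, config.immune_margin
        ),
        "beta-myeloid_vs_beta-T": degree_correlation(
            cohort, ("beta", "myeloid"), ("beta", "T"), thr, config.immune_margin
        ),
    }

    # -- report -----------------------------------------------------------
    report = {
        "provenance": {
            "config": config.to_dict(),
            "master_seed": config.master_seed,
            "n_islets": len(cohort),
            "simulated": simulated,
        },
        "stage_counts": {
            s: sum(1 for r in records if r.stage == s) for s in STAGES
        },
        "null_model_paired_t": null_tests,
        "outer_ring_wilcoxon": ring_tests,
        "half_islet_regressions": half_tests,
        "rm_anova_alpha_networks": rm_alpha,
        "rm_anova_immune_networks": rm_immune,
        "degree_correlations": corr_tests,
    }
    path = Path(config.outdir) / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    written.append(path)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
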