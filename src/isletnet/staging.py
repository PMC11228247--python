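"""Insulitis staging: degree, pseudotime ranking, stage and size classes.

Disease progression is tracked per islet by the *insulitis degree* — the
ratio of T-cells to β-cells counted inside the islet plus a 60 μm margin
around the rim.  Ranking islets by this degree in ascending order places
them on a pseudotime spectrum; fixed cutoffs then classify each islet as
early- ([0, 0.51)), intermediate- ([0.51, 1.25]) or late-stage (> 1.25)
insulitis.  Both boundary values go to the intermediate bin: "late" is
strictly greater than 1.25, and 0.51 is assigned upward so the three bins
strictly partition [0, ∞).  Islets are independently stratified by
cross-sectional area into small ([0, 7,000) μm²), medium
([7,000, 20,000] μm²) and large (> 20,000 μm²).

Note the two distinct margins: the degree counts cells within 60 μm of
the rim (``degree_margin``), while network membership of immune cells
uses a 20 μm margin (``immune_margin`` in the network builder).  They are
deliberately separate configuration values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .geometry import IsletMap, islet_area

__all__ = [
    "DEFAULT_STAGE_CUTOFFS",
    "DEFAULT_SIZE_CUTOFFS",
    "DEFAULT_DEGREE_MARGIN",
    "UndefinedDegreeError",
    "StageRecord",
    "insulitis_degree",
    "rank_islets",
    "classify_stage",
    "classify_size",
    "filter_edge_islets",
    "stage_cohort",
]

logger = logging.getLogger(__name__)

DEFAULT_STAGE_CUTOFFS = (0.51, 1.25)
DEFAULT_SIZE_CUTOFFS = (7000.0, 20000.0)  # μm²
DEFAULT_DEGREE_MARGIN = 60.0  # μm


class UndefinedDegreeError(ValueError):
    """No β-cells in the counting region; the T/β ratio is undefined."""


@dataclass(frozen=True)
class StageRecord:
    """Per-islet staging result."""

    islet_id: str
    degree: float
    n_t: int
    n_beta: int
    area: float
    stage: str
    size_class: str
    rank: int | None = None


def insulitis_degree(
    islet: IsletMap,
    margin: float = DEFAULT_DEGREE_MARGIN,
    stage_cutoffs: tuple[float, float] = DEFAULT_STAGE_CUTOFFS,
    size_cutoffs: tuple[float, float] = DEFAULT_SIZE_CUTOFFS,
) -> StageRecord:
    """T/β ratio over cells inside the islet plus ``margin`` μm of the rim.

    Raises :class:`UndefinedDegreeError` when no β-cell lies in the
    counting region (such islets are excluded from the spectrum).
    The returned record has no rank yet; :func:`rank_islets` assigns it.
    """
    d_t = islet.signed_distances("T")
    d_b = islet.signed_distances("beta")
    n_t = int((d_t <= margin).sum())
    n_b = int((d_b <= margin).sum())
    if n_b == 0:
        raise UndefinedDegreeError(
            f"islet {islet.islet_id!r}: no β-cells within {margin} μm of the rim"
        )
    degree = n_t / n_b
    area = islet_area(islet.rim)
    return StageRecord(
        islet_id=islet.islet_id,
        degree=degree,
        n_t=n_t,
        n_beta=n_b,
        area=area,
        stage=classify_stage(degree, stage_cutoffs),
        size_class=classify_size(area, size_cutoffs),
    )


def classify_stage(
    degree: float, cutoffs: tuple[float, float] = DEFAULT_STAGE_CUTOFFS
) -> str:
    """Early [0, c1), intermediate [c1, c2], late (c2, ∞)."""
    if degree < 0:
        raise ValueError("insulitis degree must be >= 0")
    c1, c2 = cutoffs
    if degree < c1:
        return "early"
    if degree <= c2:
        return "intermediate"
    return "late"


def classify_size(
    area: float, cutoffs: tuple[float, float] = DEFAULT_SIZE_CUTOFFS
) -> str:
    """Small [0, c1), medium [c1, c2], large (c2, ∞), in μm²."""
    if area <= 0:
        raise ValueError("area must be > 0")
    c1, c2 = cutoffs
    if area < c1:
        return "small"
    if area <= c2:
        return "medium"
    return "large"


def rank_islets(records: list[StageRecord]) -> list[StageRecord]:
    """Stable ascending sort by degree; ties keep input order; ranks 0-based."""
    ordered = sorted(records, key=lambda r: r.degree)
    return [replace(r, rank=i) for i, r in enumerate(ordered)]


def filter_edge_islets(cohort: list[IsletMap]) -> list[IsletMap]:
    """Drop islets at the tissue edge (their surroundings are incomplete)."""
    kept = [i for i in cohort if not i.tissue_edge_flag]
    n_removed = len(cohort) - len(kept)
    if n_removed:
        logger.info("excluded %d tissue-edge islet(s)", n_removed)
    return kept


def stage_cohort(
    cohort: list[IsletMap],
    margin: float = DEFAULT_DEGREE_MARGIN,
    stage_cutoffs: tuple[float, float] = DEFAULT_STAGE_CUTOFFS,
    size_cutoffs: tuple[float, float] = DEFAULT_SIZE_CUTOFFS,
) -> list[StageRecord]:
    """Stage every islet with a defined degree and rank them ascending.

    Islets without β-cells in the counting region are logged and skipped.
    """
    records = []
    for islet in cohort:
        try:
            records.append(insulitis_degree(islet, margin, stage_cutoffs, size_cutoffs))
        except UndefinedDegreeError as exc:
            logger.warning("%s; excluded from spectrum", exc)
    return rank_islets(records)
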