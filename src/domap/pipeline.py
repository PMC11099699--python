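"""End-to-end orchestration: mine -> null -> thresholds -> filter -> predict -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .annotation_io import AnnotationCorpus
from .mapping_core import (
    DEFAULT_ALPHA,
    DEFAULT_N_GRID,
    DEFAULT_S_GRID,
    MappingTable,
    ThresholdSelection,
    build_initial_mappings,
    filter_mappings,
    randomize_mappings,
    select_thresholds,
)

# fallback when the KS scan cannot separate original from null: the
# conservative thresholds n >= 2, S > 0.2
SAFE_THRESHOLDS = (0.2, 2)


@dataclass
class MiningResult:
    mapping_table: MappingTable
    randomized_table: MappingTable
    selection: ThresholdSelection
    s_min: float
    n_min: int
    filtered_table: MappingTable
    safety_applied: bool = False


def mine_mappings(
    corpus: AnnotationCorpus,
    seed: int = 0,
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    alpha: float = DEFAULT_ALPHA,
    safety_margin: bool = True,
    shuffle_unit: str = "triplet",
) -> MiningResult:
    """Mine reliable domain-GO mappings with data-driven thresholds.

    Builds the initial mapping table, a column-shuffled null, scans the
    (S, n) grid by KS test, then applies the final reliability filter.  With
    ``safety_margin`` (the default), any selected threshold that sits at the
    bottom of its candidate grid is moved one grid step up before filtering:
    the scan can only say the boundary cell already separates, so the
    conservative choice takes the first clearly-separated band rather than
    the boundary itself.  If no grid cell separates the distributions, the
    conservative fallback thresholds are used and flagged.
    """
    table = build_initial_mappings(corpus)
    randomized = randomize_mappings(table, seed=seed, unit=shuffle_unit)
    selection = select_thresholds(table, randomized, s_grid=s_grid,
                                  n_grid=n_grid, alpha=alpha)
    if selection.selected is None:
        s_min, n_min = SAFE_THRESHOLDS
        safety = True
    else:
        s_min, n_min = selection.selected
        safety = False
        if safety_margin:
            if s_min == min(s_grid):
                higher = sorted(s for s in s_grid if s > s_min)
                if higher:
                    s_min = higher[0]
            if n_min == min(n_grid):
                higher_n = sorted(n for n in n_grid if n > n_min)
                if higher_n:
                    n_min = higher_n[0]
    filtered = filter_mappings(table, s_min=s_min, n_min=n_min)
    return MiningResult(
        mapping_table=table,
        randomized_table=randomized,
        selection=selection,
        s_min=s_min,
        n_min=n_min,
        filtered_table=filtered,
        safety_applied=safety,
    )
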