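"""Link-persistence robustness analysis over a hyperparameter grid.

Discovery is rerun once per cell of a ``tau_max`` x ``alpha`` grid (default
5..14 x {0.05, 0.01, 0.001} = 30 cells).  A link "appears" in a cell when a
link with the same (source, sink, exact lag) identity — orientation
ignored, since contemporaneous orientations can flip across
hyperparameters — survives the MCI stage at that cell's alpha.  Persistence
is the appearance count divided by the *full* grid size, including cells
whose ``tau_max`` is below the link's lag and therefore can never contain
it; ``attainable`` reports the reachable maximum for transparency.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import link_key
from .panel import TimeSeriesPanel
from .pcmci import run_pcmciplus

__all__ = [
    "DEFAULT_TAU_GRID",
    "DEFAULT_ALPHA_GRID",
    "PersistenceRecord",
    "link_persistence",
    "persistence_to_frame",
]

DEFAULT_TAU_GRID = tuple(range(5, 15))
DEFAULT_ALPHA_GRID = (0.05, 0.01, 0.001)


@dataclass
class PersistenceRecord:
    source: int
    sink: int
    lag: int
    orientation: str
    count: int
    denominator: int
    persistence: float
    attainable: float
    cells: list[tuple[int, float, bool]] = field(default_factory=list)
    source_name: str | None = None
    sink_name: str | None = None


def link_persistence(
    panel: TimeSeriesPanel | np.ndarray,
    tau_grid=DEFAULT_TAU_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
) -> list[PersistenceRecord]:
    """Score every link ever discovered across the grid by its persistence."""
    tau_grid = tuple(tau_grid)
    alpha_grid = tuple(alpha_grid)
    if not tau_grid or not alpha_grid:
        raise ValueError("tau_grid and alpha_grid must be nonempty")
    m = len(tau_grid) * len(alpha_grid)

    cell_keys: dict[tuple[int, float], set] = {}
    first_seen: dict[tuple, object] = {}
    for tau_max in tau_grid:
        for alpha in alpha_grid:
            graph = run_pcmciplus(panel, tau_max=tau_max, alpha=alpha)
            keys = {link_key(l) for l in graph.cross_links()}
            cell_keys[(tau_max, alpha)] = keys
            for link in graph.cross_links():
                first_seen.setdefault(link_key(link), link)

    names = panel.names if isinstance(panel, TimeSeriesPanel) else None
    records = []
    for key, link in first_seen.items():
        cells = []
        count = 0
        for tau_max in tau_grid:
            for alpha in alpha_grid:
                found = key in cell_keys[(tau_max, alpha)]
                count += found
                cells.append((tau_max, alpha, found))
        reachable = sum(t >= key[2] for t in tau_grid) * len(alpha_grid)
        records.append(
            PersistenceRecord(
                source=link.source,
                sink=link.sink,
                lag=link.lag,
                orientation=link.orientation,
                count=count,
                denominator=m,
                persistence=count / m,
                attainable=reachable / m,
                cells=cells,
                source_name=names[link.source] if names else None,
                sink_name=names[link.sink] if names else None,
            )
        )
    records.sort(key=lambda r: (-r.persistence, r.source, r.sink, r.lag))
    return records


def persistence_to_frame(records: list[PersistenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "source": r.source_name if r.source_name is not None else r.source,
                "sink": r.sink_name if r.sink_name is not None else r.sink,
                "lag": r.lag,
                "orientation": r.orientation,
                "count": r.count,
                "denominator": r.denominator,
                "persistence": r.persistence,
                "attainable": r.attainable,
            }
        )
    return pd.DataFrame(rows)
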