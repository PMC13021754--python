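import numpy as np
import pytest

from amystage import EventGrid


@pytest.fixture
def tiny_grid():
    """2 biomarkers x 3 thresholds -> N = 6 events (enumeration-friendly)."""
    return EventGrid(("roi_1", "roi_2"), (1.0, 2.0, 3.0), z_max=5.0)


@pytest.fixture
def study_grid():
    """The full-size configuration: 10 ROIs x thresholds {1,2,3} -> N = 30."""
    return EventGrid(tuple(f"roi_{i}" for i in range(1, 11)),
                     (1.0, 2.0, 3.0), z_max=5.0)


def reference_trajectory(grid, ordering, biomarker, stages):
    """Independent piecewise-linear oracle built on np.interp: 0 at stage 0,
    threshold z_j at the 1-based position of event (biomarker, z_j), z_max
    at stage N."""
    ordering = np.asarray(ordering)
    position = np.empty(grid.n_events)
    position[ordering] = np.arange(1, grid.n_events + 1)
    sel = grid.event_biomarker == biomarker
    xs, ys = position[sel], grid.event_threshold[sel]
    srt = np.argsort(xs)
    xp = np.concatenate(([0.0], xs[srt], [float(grid.n_events)]))
    fp = np.concatenate(([0.0], ys[srt], [grid.z_max]))
    return np.interp(np.asarray(stages, dtype=float), xp, fp)
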