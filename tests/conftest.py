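import numpy as np
import pytest

from mycomap import GridSpec, PointSampleSet, Raster, infer_grid_index
from mycomap.synthetic import island_points


@pytest.fixture(scope="session")
def island():
    """One island-design realization: 90 lattice samples, 5 failed."""
    pts, truth = island_points(seed=7)
    return pts, truth


@pytest.fixture
def lattice3x3():
    """3x3 lattice at 100-m spacing with a simple gradient attribute."""
    xs, ys, vals, ids = [], [], [], []
    for r in range(3):
        for c in range(3):
            ids.append(f"p{r}{c}")
            xs.append(100.0 * c)
            ys.append(200.0 - 100.0 * r)
            vals.append(float(r + c))
    pts = PointSampleSet(ids, xs, ys, {"v": vals})
    return infer_grid_index(pts, 100.0)


@pytest.fixture
def small_raster():
    spec = GridSpec(x_min=0.0, y_max=40.0, cell_size=10.0, n_cols=5, n_rows=4)
    values = np.arange(20, dtype=float).reshape(4, 5)
    return Raster(spec, values)


def naive_morans_i(values, w):
    """Independent oracle: double loop over all ordered pairs."""
    x = np.asarray(values, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    denom = ((x - xbar) ** 2).sum()
    return n * num / (s0 * denom)


def best_threshold_partition(values, k):
    """Brute-force 1-D clustering oracle: exhaustive threshold search.

    Returns labels minimizing within-class sum of squares over all
    (k-1)-threshold partitions of the sorted values.
    """
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def wss(seg):
        return ((seg - seg.mean()) ** 2).sum() if len(seg) else 0.0

    best = (np.inf, None)
    if k == 2:
        for c in range(1, n):
            cost = wss(v[:c]) + wss(v[c:])
            if cost < best[0] - 1e-12:
                best = (cost, (v[c - 1] + v[c]) / 2.0)
        thr = best[1]
        return (np.asarray(values, float) > thr).astype(int), best[0]
    assert k == 3
    cuts = None
    for c1 in range(1, n - 1):
        for c2 in range(c1 + 1, n):
            cost = wss(v[:c1]) + wss(v[c1:c2]) + wss(v[c2:])
            if cost < best[0] - 1e-12:
                best = (cost, None)
                cuts = ((v[c1 - 1] + v[c1]) / 2.0, (v[c2 - 1] + v[c2]) / 2.0)
    vals = np.asarray(values, float)
    labels = np.zeros(len(vals), dtype=int)
    labels[vals > cuts[0]] = 1
    labels[vals > cuts[1]] = 2
    return labels, best[0]
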