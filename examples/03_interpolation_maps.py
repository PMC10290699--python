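"""Interpolate abundance maps with IDW, ordinary kriging and B-spline.

Kriging fits a variogram automatically (weighted least squares, best
determination coefficient among spherical / exponential / gaussian) and
smooths through the nugget; IDW and the multilevel B-spline honor the
data at the sample points.
"""

import numpy as np

from mycomap import InterpolationConfig, interpolate, island_points, write_raster

pts, _ = island_points(seed=7)

for method in ("idw", "bspline", "kriging"):
    cfg = InterpolationConfig(method=method, cell_size=20.0)
    out = interpolate(pts, "abundance", cfg)
    if isinstance(out, tuple):
        raster, model = out
        print(f"{method:8s}: fitted variogram {model.kind}, "
              f"nugget={model.nugget:.3f}, partial sill={model.partial_sill:.3f}, "
              f"range={model.range:.0f} m, r2={model.r2:.3f}")
    else:
        raster = out
        print(f"{method:8s}: raster {raster.spec.n_rows} x {raster.spec.n_cols}, "
              f"values {np.nanmin(raster.values):.2f} .. "
              f"{np.nanmax(raster.values):.2f}")
    write_raster(raster, f"map_{method}.asc", format="esri_ascii")

print("wrote map_idw.asc, map_bspline.asc, map_kriging.asc")
# All three rasters share the same grid (bounding box of the usable
# samples padded by one cell), so they can be differenced cell by cell.
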