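"""Gridded spatial layers and the operations that turn them into predictors.

Continuous layers (utilisation distribution, leopard resource-selection
surface, encounter risk, familiarity) live on a regular grid and are rescaled
to [0, 1] by a linear stretch before entering any model.  The habitat layer
holds integer codes into :data:`HABITAT_TYPES`.  No-data cells are carried as
NaN in memory and as the ``nodata`` sentinel in ESRI ASCII files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

HABITAT_TYPES = (
    "forest",
    "woodland",
    "bush",
    "grassland",
    "rock",
    "camps",
    "farms",
    "roads",
)

CONTINUOUS_KINDS = ("ud", "familiarity", "leopard_rsf", "encounter_risk", "encounter_ud")
LAYER_KINDS = CONTINUOUS_KINDS + ("habitat",)

FAMILIARITY_CLASSES = ("core", "frequent", "boundary")


@dataclasses.dataclass
class SpatialLayer:
    """A single gridded surface.

    Parameters
    ----------
    values
        2-D array.  Continuous kinds hold floats (NaN = no data); the
        ``habitat`` kind holds integer indices into :data:`HABITAT_TYPES`.
    kind
        One of :data:`LAYER_KINDS`.
    origin
        (x, y) of the lower-left corner of the grid.
    cell_size
        Side length of one (square) cell.
    """

    values: np.ndarray
    kind: str
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("layer values must be a 2-D array")
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "SpatialLayer") -> bool:
        return (
            self.shape == other.shape
            and self.origin == other.origin
            and self.cell_size == other.cell_size
        )

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "SpatialLayer":
        return SpatialLayer(
            values=values,
            kind=self.kind if kind is None else kind,
            origin=self.origin,
            cell_size=self.cell_size,
        )

    def value_at(self, cell: tuple[int, int]) -> float:
        return self.values[cell]


def _check_finite(layer: SpatialLayer) -> np.ndarray:
    vals = np.asarray(layer.values, dtype=float)
    if np.isinf(vals).any():
        raise ValueError("layer contains non-finite (infinite) cells")
    return vals


def linear_stretch(layer: SpatialLayer) -> SpatialLayer:
    """Rescale a layer linearly so its minimum maps to 0 and maximum to 1.

    A constant layer stretches to all zeros (the 0/0 case is defined away);
    NaN cells are preserved as NaN.
    """
    vals = _check_finite(layer)
    lo = np.nanmin(vals)
    hi = np.nanmax(vals)
    if hi == lo:
        out = np.where(np.isnan(vals), np.nan, 0.0)
    else:
        out = (vals - lo) / (hi - lo)
    return layer.with_values(out)


def invert_layer(layer: SpatialLayer) -> SpatialLayer:
    """Flip a stretched layer: v -> 1 - v (high use becomes low familiarity risk)."""
    vals = _check_finite(layer)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("invert_layer expects a layer already stretched to [0, 1]")
    return layer.with_values(1.0 - vals)


def encounter_risk_layer(encounter_ud: SpatialLayer, range_ud: SpatialLayer) -> SpatialLayer:
    """Spatial probability of encountering another group, offset by range use.

    The (stretched) encounter distribution is divided cellwise by the
    (stretched) range utilisation distribution; cells never used by the group
    (range UD = 0) are masked as no-data, and the ratio is stretched a further
    time so all values lie in [0, 1].
    """
    if not encounter_ud.same_geometry(range_ud):
        raise ValueError("encounter and range layers have different grid geometry")
    enc = _check_finite(encounter_ud)
    rng = _check_finite(range_ud)
    for name, vals in (("encounter", enc), ("range", rng)):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError(f"{name} layer must be stretched to [0, 1] first")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rng > 0, enc / rng, np.nan)
    return linear_stretch(encounter_ud.with_values(ratio, kind="encounter_risk"))


def integrate_rsf(
    rsf2: SpatialLayer, rsf3: SpatialLayer, method: str = "product"
) -> SpatialLayer:
    """Combine 2nd- and 3rd-order resource-selection surfaces into one layer.

    The combiner is pluggable: ``product`` (default) multiplies the stretched
    surfaces cellwise, ``mean`` averages them; either way the result is
    re-stretched to [0, 1].
    """
    if not rsf2.same_geometry(rsf3):
        raise ValueError("RSF layers have different grid geometry")
    a = _check_finite(rsf2)
    b = _check_finite(rsf3)
    if method == "product":
        combined = a * b
    elif method == "mean":
        combined = 0.5 * (a + b)
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return linear_stretch(rsf2.with_values(combined, kind="leopard_rsf"))


def familiarity_thresholds(layer: SpatialLayer) -> tuple[float, float]:
    """Cell-value cut points delimiting thirds of cumulative utilisation mass.

    Cells are ranked by utilisation; the isopleth containing the top third of
    total use defines the core, the next third the frequently used area, the
    remainder the boundary.  Returns ``(t_core, t_frequent)`` such that
    ``v >= t_core`` is core and ``t_frequent <= v < t_core`` is frequent.
    """
    vals = _check_finite(layer)
    flat = vals[~np.isnan(vals)].ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("utilisation layer has no positive mass")
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) / total
    core_idx = np.searchsorted(cum, 1.0 / 3.0)
    freq_idx = np.searchsorted(cum, 2.0 / 3.0)
    t_core = flat[order[min(core_idx, len(flat) - 1)]]
    t_frequent = flat[order[min(freq_idx, len(flat) - 1)]]
    return float(t_core), float(t_frequent)


def familiarity_class(ud_value: float, layer: SpatialLayer) -> str:
    """Classify a stretched-UD value as core / frequent / boundary.

    Classes are terciles of cumulative utilisation mass (isopleth logic), not
    terciles of raw cell value.
    """
    if not 0.0 <= ud_value <= 1.0:
        raise ValueError("ud_value must come from the stretched UD, in [0, 1]")
    t_core, t_frequent = familiarity_thresholds(layer)
    if ud_value >= t_core:
        return "core"
    if ud_value >= t_frequent:
        return "frequent"
    return "boundary"


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_ascii_grid(layer: SpatialLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (.asc) with full float precision."""
    path = Path(path)
    nrows, ncols = layer.shape
    vals = np.asarray(layer.values, dtype=float)
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {layer.origin[0]!r}",
        f"yllcorner {layer.origin[1]!r}",
        f"cellsize {layer.cell_size!r}",
        f"NODATA_value {_NODATA!r}",
    ]
    # ASCII grids store row 0 as the northernmost row
    for row in vals[::-1]:
        out = np.where(np.isnan(row), _NODATA, row)
        lines.append(" ".join(repr(float(v)) for v in out))
    path.write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path, kind: str) -> SpatialLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    nodata = header.get("nodata_value", _NODATA)
    rows = [
        np.array([float(v) for v in line.split()], dtype=float)
        for line in lines[body_start : body_start + nrows]
    ]
    vals = np.vstack(rows)[::-1]
    if vals.shape != (nrows, ncols):
        raise ValueError(f"grid body shape {vals.shape} does not match header")
    vals = np.where(vals == nodata, np.nan, vals)
    return SpatialLayer(
        values=vals,
        kind=kind,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
    )
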