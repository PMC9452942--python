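"""Ground-truth probability maps for nucleus-center regression.

The detector is trained to regress a per-pixel nucleus-likelihood surface
rather than a binary mask: the target value at pixel ``z_j`` is

    y_j = 1 / (1 + ||z_j - z_m*||^2 / 2)   if ||z_j - z_m*|| <= d, else 0,

where ``z_m*`` is the nearest annotated center and ``d`` (default 4 px) is
the support radius.  The map peaks at exactly 1 on each center and decays to
0 outside a disc of radius ``d``, giving the network a smooth, localized
regression target whose maxima mark nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidAnnotationError, InvalidParameterError

__all__ = [
    "NucleusRecord",
    "distance_weight",
    "build_probability_map",
    "read_centers_csv",
    "write_centers_csv",
]

DEFAULT_RADIUS = 4.0


@dataclass(frozen=True)
class NucleusRecord:
    """One annotated or predicted nucleus.

    Coordinates are 0-based continuous ``(row, col)`` with pixel centers at
    integer positions.  ``height`` is the peak amplitude in [0, 1]: 1 for
    ground truth, the local map value for detections.
    """

    row: float
    col: float
    label: str | int | None = None
    height: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.height <= 1.0:
            raise InvalidParameterError(f"height must lie in [0, 1], got {self.height}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.row, self.col)


def distance_weight(pixel, center) -> float:
    """Halved squared Euclidean distance ``||z_j - z_m||^2 / 2``."""
    pr, pc = pixel
    cr, cc = center
    return 0.5 * ((pr - cr) ** 2 + (pc - cc) ** 2)


def build_probability_map(
    centers, shape: tuple[int, int], d: float = DEFAULT_RADIUS
) -> np.ndarray:
    """Render the nucleus-probability target for a list of centers.

    Each pixel takes the kernel value of its *nearest* center (equidistant
    ties go to the lower-index center) and 0 beyond the closed disc of
    radius ``d``.

    Parameters
    ----------
    centers
        Iterable of `NucleusRecord` or ``(row, col)`` pairs, all inside
        ``[0, H) x [0, W)``.
    shape
        ``(H, W)`` of the output map.
    d
        Support radius in pixels, >= 1.

    Returns
    -------
    ``(H, W)`` float64 array with values in [0, 1].
    """
    if d < 1:
        raise InvalidParameterError(f"support radius d must be >= 1, got {d}")
    h, w = shape
    out = np.zeros((h, w), dtype=np.float64)
    pts = np.array(
        [(c.row, c.col) if isinstance(c, NucleusRecord) else tuple(c) for c in centers],
        dtype=np.float64,
    ).reshape(-1, 2)
    if pts.size == 0:
        return out
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] >= h) or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] >= w):
        raise InvalidAnnotationError("nucleus center outside the map bounds")
    rows = np.arange(h, dtype=np.float64)[:, None, None]
    cols = np.arange(w, dtype=np.float64)[None, :, None]
    dist2 = (rows - pts[:, 0]) ** 2 + (cols - pts[:, 1]) ** 2  # (H, W, M)
    nearest = np.argmin(dist2, axis=2)  # first minimum -> lowest index on ties
    d2 = np.take_along_axis(dist2, nearest[:, :, None], axis=2)[:, :, 0]
    support = np.sqrt(d2) <= d
    out[support] = 1.0 / (1.0 + d2[support] / 2.0)
    return out


def read_centers_csv(path) -> list[NucleusRecord]:
    """Read nucleus annotations from CSV with columns ``row,col,class``."""
    df = pd.read_csv(path)
    required = {"row", "col"}
    if not required.issubset(df.columns):
        raise InvalidAnnotationError(f"annotation CSV needs columns {sorted(required)}")
    labels = df["class"] if "class" in df.columns else [None] * len(df)
    return [
        NucleusRecord(row=float(r), col=float(c), label=lab)
        for r, c, lab in zip(df["row"], df["col"], labels)
    ]


def write_centers_csv(records, path) -> None:
    pd.DataFrame(
        {
            "row": [r.row for r in records],
            "col": [r.col for r in records],
            "class": [r.label for r in records],
        }
    ).to_csv(path, index=False)
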