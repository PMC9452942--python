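"""Beer-Lambert stain model and colour deconvolution for brightfield histology.

Under the Beer-Lambert law the light transmitted through stained tissue decays
exponentially with the amount of absorbing dye, so the per-channel optical
density ``OD_c = -log10(I_c / I0_c)`` is *linear* in the stain concentrations.
Writing the unit absorbance vectors of the stains as the rows of a matrix
``A`` (stains x RGB), a pixel's OD vector is ``od = A^T c`` for concentration
vector ``c``.  Colour deconvolution recovers ``c`` by applying the inverse
(or, for fewer than three stains, the Moore-Penrose pseudo-inverse) of
``A^T`` — this separates e.g. the hematoxylin (nuclei) and eosin
(cytoplasm/stroma) contributions of an H&E slide into independent density
maps usable for morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import DegenerateStainError, InvalidParameterError, SingularStainMatrixError

__all__ = [
    "StainMatrix",
    "HE_DEFAULT",
    "rgb_to_od",
    "od_to_rgb",
    "normalize_stain_matrix",
    "deconvolution_matrix",
    "separate_stains",
]

#: OD clamp corresponding to intensities below I0 * 10**-OD_MAX; bounds the
#: optical density of saturated dark pixels at 6.
OD_MAX = 6.0


@dataclass(frozen=True)
class StainMatrix:
    """Per-stain RGB absorbance rows.

    Parameters
    ----------
    rows
        ``(S, 3)`` array, one absorbance triple per stain, ``1 <= S <= 3``.
    names
        One label per stain, e.g. ``("hematoxylin", "eosin")``.
    normalized
        True once every row has unit Euclidean norm.
    """

    rows: np.ndarray
    names: tuple[str, ...] = ()
    normalized: bool = False

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.ndim != 2 or rows.shape[1] != 3 or not 1 <= rows.shape[0] <= 3:
            raise InvalidParameterError(
                f"stain matrix must be (S, 3) with 1 <= S <= 3, got {rows.shape}"
            )
        object.__setattr__(self, "rows", rows)
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"stain_{i}" for i in range(rows.shape[0]))
            )
        if len(self.names) != rows.shape[0]:
            raise InvalidParameterError("one name per stain row required")
        norms = np.linalg.norm(rows, axis=1)
        if np.any(norms == 0):
            raise DegenerateStainError("stain matrix contains an all-zero row")
        if self.normalized and not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidParameterError("normalized flag set but rows are not unit norm")

    @property
    def n_stains(self) -> int:
        return self.rows.shape[0]

    @classmethod
    def from_yaml(cls, path) -> "StainMatrix":
        """Load a named stain profile: mapping of stain name -> [r, g, b]."""
        with open(path) as fh:
            profile = yaml.safe_load(fh)
        if not isinstance(profile, dict) or not profile:
            raise InvalidParameterError(f"stain profile {path!r} must map names to triples")
        names = tuple(profile)
        rows = np.array([profile[n] for n in names], dtype=np.float64)
        return cls(rows=rows, names=names)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {n: [float(v) for v in row] for n, row in zip(self.names, self.rows)},
                fh,
                sort_keys=False,
            )


#: Default H&E profile: hematoxylin absorbs roughly equally in R/G/B
#: (dark blue-purple), eosin absorbs mostly green (pink).
HE_DEFAULT = StainMatrix(
    rows=np.array([[0.18, 0.20, 0.18], [0.01, 0.13, 0.01]]),
    names=("hematoxylin", "eosin"),
)


def rgb_to_od(pixels: np.ndarray, incident: float | np.ndarray = 255.0) -> np.ndarray:
    """Transmitted intensities -> optical densities, ``OD = -log10(I / I0)``.

    Intensities are clamped from below at ``I0 * 10**-6`` so fully dark
    pixels map to a finite OD of 6 instead of infinity.
    """
    incident = np.asarray(incident, dtype=np.float64)
    if np.any(incident <= 0):
        raise InvalidParameterError("incident intensity must be positive")
    pixels = np.asarray(pixels, dtype=np.float64)
    clamped = np.maximum(pixels, incident * 10.0 ** (-OD_MAX))
    return -np.log10(clamped / incident)


def od_to_rgb(od: np.ndarray, incident: float | np.ndarray = 255.0) -> np.ndarray:
    """Optical densities -> transmitted intensities, the inverse of `rgb_to_od`."""
    incident = np.asarray(incident, dtype=np.float64)
    if np.any(incident <= 0):
        raise InvalidParameterError("incident intensity must be positive")
    od = np.asarray(od, dtype=np.float64)
    if np.any(od < 0) or not np.all(np.isfinite(od)):
        raise InvalidParameterError("optical densities must be finite and >= 0")
    return incident * 10.0 ** (-od)


def normalize_stain_matrix(m: StainMatrix) -> StainMatrix:
    """Scale each absorbance row to unit Euclidean norm (idempotent)."""
    norms = np.linalg.norm(m.rows, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateStainError("cannot normalize an all-zero stain row")
    return replace(m, rows=m.rows / norms, normalized=True)


def deconvolution_matrix(m: StainMatrix) -> np.ndarray:
    """The ``(S, 3)`` unmixing matrix ``D`` with ``c = D @ od``.

    For three stains this is the ordinary matrix inverse of ``A^T``; for one
    or two stains it is the Moore-Penrose pseudo-inverse, i.e. the
    least-squares projection onto the stain plane.  Either way
    ``D @ A^T = I_S`` holds on the stain subspace.
    """
    if not m.normalized:
        m = normalize_stain_matrix(m)
    a_t = m.rows.T  # (3, S)
    if np.linalg.matrix_rank(a_t, tol=1e-9) < m.n_stains:
        raise SingularStainMatrixError("stain rows are linearly dependent")
    return np.linalg.pinv(a_t)


def separate_stains(
    pixels: np.ndarray,
    m: StainMatrix,
    incident: float | np.ndarray = 255.0,
    clip_negative: bool = False,
) -> np.ndarray:
    """Unmix an RGB image into per-stain concentration maps.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` transmitted intensities.
    m
        Stain matrix; normalized internally if needed.
    clip_negative
        Clip small negative concentrations (deconvolution of noisy pixels)
        at zero.  Off by default so linear-algebra identities hold exactly.

    Returns
    -------
    ``(H, W, S)`` concentration array, one channel per stain row of ``m``.
    """
    od = rgb_to_od(pixels, incident)
    d = deconvolution_matrix(m)
    conc = od @ d.T
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc
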