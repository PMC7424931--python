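"""Cone coordinate files and ROI manifests.

Cone selections are stored as delimited text with two numeric columns
(x, y), one row per cone, comma- or tab-separated with an optional single
header line.  Units (pixels or micrometers) are declared per ROI in the
manifest, never inside the coordinate file itself.  The manifest is a
delimited table with one row per ROI carrying the geometry and optics
metadata needed to convert and validate coordinates.

Coordinate convention: origin at the ROI top-left corner, x increasing
rightward and y downward, continuous 0-based micrometers.  Pixel inputs
are converted by multiplying by the ROI scale (pixel centers sit at
integer pixel coordinates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MERIDIANS = ("superior", "inferior", "nasal", "temporal", "unspecified")

#: Reference axial length (mm) for proportional image scaling.  An emmetropic
#: model eye; both the reference and the base scale are parameters, never
#: baked into stored coordinates.
REFERENCE_AXIAL_LENGTH_MM = 24.0

MANIFEST_COLUMNS = [
    "subject_id",
    "roi_id",
    "width_um",
    "height_um",
    "scale_um_per_px",
    "axial_length_mm",
    "eccentricity_um",
    "meridian",
]


class CoordinateParseError(ValueError):
    """A coordinate file row could not be parsed."""


class ManifestError(ValueError):
    """The ROI manifest is missing columns or violates an invariant."""


@dataclass(frozen=True)
class ROIMeta:
    """Geometry and optics metadata for one square-ish retinal ROI.

    Parameters
    ----------
    subject_id, roi_id
        Free-text identifiers; (subject_id, roi_id) is unique per study.
    width_um, height_um
        ROI extent in micrometers.
    scale_um_per_px
        Lateral image scale after axial-length correction.
    axial_length_mm
        Ocular axial length; drives the retinal magnification of the raw
        image and therefore the micrometer scale.
    eccentricity_um
        Retinal distance of the ROI center from fixation.
    meridian
        Retinal meridian the ROI was sampled from.
    """

    subject_id: str
    roi_id: str
    width_um: float
    height_um: float
    scale_um_per_px: float
    axial_length_mm: float
    eccentricity_um: float
    meridian: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.width_um > 0 or not self.height_um > 0:
            raise ManifestError(
                f"ROI {self.roi_id}: width/height must be positive, got "
                f"({self.width_um}, {self.height_um})"
            )
        if not self.scale_um_per_px > 0:
            raise ManifestError(f"ROI {self.roi_id}: scale must be positive")
        if not 15.0 <= self.axial_length_mm <= 35.0:
            raise ManifestError(
                f"ROI {self.roi_id}: axial length {self.axial_length_mm} mm "
                "outside the plausible human range [15, 35]"
            )
        if self.eccentricity_um < 0:
            raise ManifestError(f"ROI {self.roi_id}: negative eccentricity")
        if self.meridian not in MERIDIANS:
            raise ManifestError(
                f"ROI {self.roi_id}: unknown meridian {self.meridian!r}"
            )


@dataclass
class ConePoints:
    """An ordered set of 2-D cone coordinates (µm) for one ROI and annotator.

    ``coords`` is an (n, 2) float array.  Invariants enforced at
    construction: coordinates finite and inside the ROI rectangle;
    bit-identical duplicates collapsed (a double-click artifact) with the
    collapse count recorded in ``n_duplicates_collapsed``.
    """

    roi: ROIMeta
    annotator: str
    coords: np.ndarray
    n_duplicates_collapsed: int = 0
    n_out_of_bounds_dropped: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.annotator}: non-finite coordinates")
        self.coords = coords

    def __len__(self) -> int:
        return len(self.coords)


def scale_factor(
    axial_length_mm: float,
    reference_axial_length_mm: float = REFERENCE_AXIAL_LENGTH_MM,
    base_um_per_px: float = 1.0,
) -> float:
    """Micrometers-per-pixel scale adjusted proportionally to axial length.

    The retinal magnification of a fundus image grows with the eye's axial
    length; scaling the base (reference-eye) pixel size by the ratio
    ``axial_length / reference`` converts pixel coordinates to micrometers
    on that subject's retina.

    >>> scale_factor(24.0, 24.0, 0.45)
    0.45
    """
    for name, v in (
        ("axial_length_mm", axial_length_mm),
        ("reference_axial_length_mm", reference_axial_length_mm),
        ("base_um_per_px", base_um_per_px),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return base_um_per_px * axial_length_mm / reference_axial_length_mm


def _detect_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def _is_numeric_row(fields: Sequence[str]) -> bool:
    try:
        [float(f) for f in fields]
        return True
    except ValueError:
        return False


def read_cone_coordinates(
    path: str | Path,
    roi: ROIMeta,
    units: str = "microns",
    annotator: str | None = None,
) -> ConePoints:
    """Read one annotator's cone selections for one ROI.

    Parameters
    ----------
    path
        Delimited text, two numeric columns (x, y), comma- or tab-separated
        (auto-detected), at most one header line (auto-detected).
    roi
        ROI the selections belong to; provides the pixel scale and bounds.
    units
        ``"pixels"`` (converted to µm via ``roi.scale_um_per_px``) or
        ``"microns"``.
    annotator
        Label for the selection set; defaults to the file stem.

    Rows outside the ROI rectangle are dropped (count logged and recorded);
    bit-identical duplicates are collapsed to one.  An empty file yields an
    empty, valid ConePoints.
    """
    if units not in ("pixels", "microns"):
        raise ValueError(f"units must be 'pixels' or 'microns', got {units!r}")
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    annotator = annotator if annotator is not None else path.stem
    if not lines:
        return ConePoints(roi=roi, annotator=annotator, coords=np.empty((0, 2)))

    delim = _detect_delimiter(lines[0])
    start = 0
    first = [f.strip() for f in lines[0].split(delim)]
    if not _is_numeric_row(first):
        start = 1  # single header line permitted
    rows = []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in ln.split(delim)]
        if len(fields) < 2 or not _is_numeric_row(fields[:2]):
            raise CoordinateParseError(
                f"{path}: malformed row at line {lineno}: {ln!r}"
            )
        rows.append((float(fields[0]), float(fields[1])))

    coords = np.asarray(rows, dtype=float).reshape(-1, 2)
    if units == "pixels":
        coords = coords * roi.scale_um_per_px

    # Tolerate float-representation slack at the border (points clicked or
    # clipped exactly onto the ROI edge), then clamp them onto it.
    tol = 1e-9
    inside = (
        (coords[:, 0] >= -tol)
        & (coords[:, 0] <= roi.width_um + tol)
        & (coords[:, 1] >= -tol)
        & (coords[:, 1] <= roi.height_um + tol)
    )
    n_oob = int((~inside).sum())
    if n_oob:
        logger.warning(
            "%s: dropped %d out-of-bounds coordinate(s) for ROI %s",
            path,
            n_oob,
            roi.roi_id,
        )
    coords = coords[inside]
    coords[:, 0] = np.clip(coords[:, 0], 0.0, roi.width_um)
    coords[:, 1] = np.clip(coords[:, 1], 0.0, roi.height_um)

    uniq, idx = np.unique(coords, axis=0, return_index=True)
    n_dup = len(coords) - len(uniq)
    if n_dup:
        warnings.warn(
            f"{path}: collapsed {n_dup} duplicate coordinate(s)", stacklevel=2
        )
        coords = coords[np.sort(idx)]  # preserve original row order

    return ConePoints(
        roi=roi,
        annotator=annotator,
        coords=coords,
        n_duplicates_collapsed=n_dup,
        n_out_of_bounds_dropped=n_oob,
    )


def write_cone_coordinates(points: ConePoints, path: str | Path) -> None:
    """Write cone selections as ``x,y`` CSV (µm) with a header line.

    Round-trips through :func:`read_cone_coordinates` to ≤1e-9 µm.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("x_um,y_um\n")
        for x, y in points.coords:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_roi_manifest(path: str | Path) -> list[ROIMeta]:
    """Read the study manifest: one validated :class:`ROIMeta` per row."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in MANIFEST_COLUMNS if c != "meridian" and c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: manifest missing column(s) {missing}")
    out: list[ROIMeta] = []
    for i, row in df.iterrows():
        try:
            out.append(
                ROIMeta(
                    subject_id=str(row["subject_id"]),
                    roi_id=str(row["roi_id"]),
                    width_um=float(row["width_um"]),
                    height_um=float(row["height_um"]),
                    scale_um_per_px=float(row["scale_um_per_px"]),
                    axial_length_mm=float(row["axial_length_mm"]),
                    eccentricity_um=float(row["eccentricity_um"]),
                    meridian=str(row.get("meridian", "unspecified")),
                )
            )
        except ManifestError as e:
            raise ManifestError(f"{path}: row {i}: {e}") from e
    return out


def write_roi_manifest(rois: Sequence[ROIMeta], path: str | Path) -> None:
    """Write a manifest readable by :func:`read_roi_manifest`."""
    df = pd.DataFrame([vars(r) for r in rois], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
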