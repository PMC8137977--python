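"""The nine OCTA morphologic biomarkers of an mCNV lesion.

From the binary vessel map and its skeleton the panel collects: lesion (mCNV)
area, vessel area, vessel density (vessel/lesion area fraction), total vessel
length, mean vessel diameter (vessel area / skeleton length), box-counting
fractal dimension of the skeleton, junction count, junction density
(junctions per mm of vessel) and mean branch tortuosity (arc/chord).  Central
retinal thickness (CRT), the traditional structural response marker, is an
externally supplied number in micrometres and is carried through unchanged.

Lesions in which no vessel survives binarization report the undefined markers
(diameter, fractal dimension, tortuosity) as NaN rather than 0, so that
cohort statistics can exclude them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .binarize import BinarizeParams, BinaryVesselMap, binarize_lesion
from .imaging import EnFaceImage, LesionMask
from .skeleton import (
    SkeletonGraph,
    SkeletonMap,
    build_graph,
    junction_count,
    skeletonize,
    total_length_mm,
)

#: CSV column names of a panel row, matching the cohort report layout
PANEL_COLUMNS = (
    "mCNV_area", "VA", "VLD", "FD", "VD", "VL", "VT", "VJ", "JD", "CRT",
)


@dataclass
class BiomarkerPanel:
    """The nine OCTA biomarkers (+CRT) for one eye at one timepoint."""

    mcnv_area_mm2: float
    vessel_area_mm2: float
    vessel_density: float
    vessel_length_mm: float
    vessel_diameter_um: float
    fractal_dimension: float
    vessel_junctions: int
    junction_density_per_mm: float
    vessel_tortuosity: float
    crt_um: Optional[float] = None

    def to_row(self) -> dict:
        """One CSV row with the conventional short column names."""
        return {
            "mCNV_area": self.mcnv_area_mm2,
            "VA": self.vessel_area_mm2,
            "VLD": self.vessel_density,
            "FD": self.fractal_dimension,
            "VD": self.vessel_diameter_um,
            "VL": self.vessel_length_mm,
            "VT": self.vessel_tortuosity,
            "VJ": self.vessel_junctions,
            "JD": self.junction_density_per_mm,
            "CRT": self.crt_um if self.crt_um is not None else float("nan"),
        }

    @classmethod
    def from_row(cls, row: dict) -> "BiomarkerPanel":
        crt = row.get("CRT")
        return cls(
            mcnv_area_mm2=float(row["mCNV_area"]),
            vessel_area_mm2=float(row["VA"]),
            vessel_density=float(row["VLD"]),
            vessel_length_mm=float(row["VL"]),
            vessel_diameter_um=float(row["VD"]),
            fractal_dimension=float(row["FD"]),
            vessel_junctions=int(round(float(row["VJ"]))),
            junction_density_per_mm=float(row["JD"]),
            vessel_tortuosity=float(row["VT"]),
            crt_um=None if crt is None or (isinstance(crt, float) and math.isnan(crt))
            else float(crt),
        )


def area_mm2(mask: np.ndarray, pixel_scale_mm: float) -> float:
    """Foreground pixel count times the pixel area."""
    return float(np.asarray(mask, dtype=bool).sum()) * pixel_scale_mm**2


def vessel_density(binary: BinaryVesselMap) -> float:
    """Fraction of the lesion area occupied by vessels."""
    n_lesion = binary.lesion.n_pixels
    if n_lesion == 0:
        raise ValueError("lesion mask is empty")
    return float(binary.mask.sum()) / n_lesion


def vessel_diameter_um(vessel_area_mm2: float, vessel_length_mm: float) -> float:
    """Mean caliber: non-skeletonized vessel area over skeleton length, in um."""
    if vessel_area_mm2 == 0:
        return 0.0
    if vessel_length_mm <= 0:
        raise ValueError("vessel diameter undefined for zero vessel length")
    return 1000.0 * vessel_area_mm2 / vessel_length_mm


def box_counts(mask: np.ndarray, sizes: list[int]) -> list[int]:
    """Occupied-box counts over a dyadic grid anchored at the set's bounding box."""
    rows, cols = np.nonzero(mask)
    r0, c0 = rows.min(), cols.min()
    cropped = mask[r0 : rows.max() + 1, c0 : cols.max() + 1]
    counts = []
    for s in sizes:
        h = -(-cropped.shape[0] // s) * s
        w = -(-cropped.shape[1] // s) * s
        padded = np.zeros((h, w), dtype=bool)
        padded[: cropped.shape[0], : cropped.shape[1]] = cropped
        blocks = padded.reshape(h // s, s, w // s, s).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    return counts


def fractal_dimension(skel: SkeletonMap | np.ndarray) -> float:
    """Box-counting dimension of the skeleton point set.

    Least-squares slope of ``log N(s)`` against ``log(1/s)`` over dyadic box
    sizes ``s = 2, 4, 8, ... <= min(h, w)/4`` of the grid, with boxes anchored
    at the skeleton's bounding-box origin.  Higher values indicate a more
    complex branching pattern (1 = smooth curve, 2 = space-filling).
    """
    mask = skel.mask if isinstance(skel, SkeletonMap) else np.asarray(skel, bool)
    if not mask.any():
        raise ValueError("fractal dimension undefined for an empty skeleton")
    limit = min(mask.shape) / 4
    sizes = []
    s = 2
    while s <= limit:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        raise ValueError("grid too small: need at least 3 dyadic box sizes")
    counts = box_counts(mask, sizes)
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                       np.log(np.asarray(counts, float)), 1)[0]
    return float(slope)


def vessel_tortuosity(
    graph: SkeletonGraph,
    length_weighted: bool = False,
    include_cycles: bool = True,
    smoothed: bool = True,
) -> float:
    """Mean over branches of arc length / chord length (1 = straight).

    The branch arc length is measured on the lightly smoothed pixel path by
    default, which removes the staircase bias of raw 8-connected step sums
    (``smoothed=False`` uses the raw steps).  Cycles use the loop diameter as
    chord; ``include_cycles=False`` drops them.  Degenerate branches (zero
    chord) are excluded.
    """
    ratios, weights = [], []
    for b in graph.branches:
        if b.is_cycle and not include_cycles:
            continue
        chord = b.chord_length_px
        if chord <= 0:
            continue
        arc = b.smoothed_length_px() if smoothed else b.path_length_px
        ratios.append(max(arc / chord, 1.0))
        weights.append(b.path_length_px)
    if not ratios:
        raise ValueError("tortuosity undefined: no branch with a positive chord")
    if length_weighted:
        return float(np.average(ratios, weights=weights))
    return float(np.mean(ratios))


@dataclass
class PanelIntermediates:
    """Optional intermediate artifacts of a panel computation."""

    denoised: Optional[np.ndarray] = None
    vesselness: Optional[np.ndarray] = None
    binary: Optional[BinaryVesselMap] = None
    skeleton: Optional[SkeletonMap] = None
    graph: Optional[SkeletonGraph] = None


def compute_panel(
    img: EnFaceImage,
    lesion: LesionMask,
    params: BinarizeParams = BinarizeParams(),
    crt_um: Optional[float] = None,
    prune_px: int = 3,
    intermediates: Optional[PanelIntermediates] = None,
) -> BiomarkerPanel:
    """Run the full chain binarize -> skeletonize -> graph -> nine biomarkers.

    A lesion in which no vessel is detected yields zeroed size metrics and NaN
    for the markers that are undefined without vessels (diameter, fractal
    dimension, tortuosity).
    """
    binary = binarize_lesion(img, lesion, params)
    skel = skeletonize(binary)
    graph = build_graph(skel, prune_px=prune_px)
    # metrics are computed on the pruned skeleton the graph saw
    pruned = np.zeros(skel.mask.shape, dtype=bool)
    for b in graph.branches:
        pruned[b.path[:, 0], b.path[:, 1]] = True
    for j in graph.junctions:
        pruned[j.pixels[:, 0], j.pixels[:, 1]] = True
    for r, c in graph.isolated:
        pruned[r, c] = True
    pruned_skel = SkeletonMap(pruned)

    scale = img.pixel_scale_mm
    lesion_area = area_mm2(lesion.mask, scale)
    va = area_mm2(binary.mask, scale)
    vld = vessel_density(binary)
    vl = total_length_mm(pruned_skel, scale)
    vj = junction_count(graph)

    nan = float("nan")
    if va == 0 or vl == 0:
        panel = BiomarkerPanel(
            mcnv_area_mm2=lesion_area, vessel_area_mm2=va, vessel_density=vld,
            vessel_length_mm=vl, vessel_diameter_um=nan, fractal_dimension=nan,
            vessel_junctions=vj, junction_density_per_mm=nan,
            vessel_tortuosity=nan, crt_um=crt_um,
        )
    else:
        try:
            vt = vessel_tortuosity(graph)
        except ValueError:
            vt = nan
        try:
            fd = fractal_dimension(pruned_skel)
        except ValueError:
            fd = nan
        panel = BiomarkerPanel(
            mcnv_area_mm2=lesion_area,
            vessel_area_mm2=va,
            vessel_density=vld,
            vessel_length_mm=vl,
            vessel_diameter_um=vessel_diameter_um(va, vl),
            fractal_dimension=fd,
            vessel_junctions=vj,
            junction_density_per_mm=vj / vl,
            vessel_tortuosity=vt,
            crt_um=crt_um,
        )
    if intermediates is not None:
        from .binarize import frangi_vesselness, gaussian_denoise

        den = gaussian_denoise(img, params.sigma_px)
        intermediates.denoised = den.pixels
        if params.threshold_on == "vesselness":
            intermediates.vesselness = frangi_vesselness(
                den, params.scales_px, params.beta, params.c
            ).response
        intermediates.binary = binary
        intermediates.skeleton = pruned_skel
        intermediates.graph = graph
    return panel
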