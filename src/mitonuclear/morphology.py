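"""Nuclear morphometry from H&E-stained RGB tiles.

Pipeline per tile: brightness QC -> colour deconvolution to the
hematoxylin channel -> foreground threshold at half the channel mean ->
small-object removal and watershed splitting -> per-object features.

Feature definitions:

* number of nuclei — segmented foreground objects;
* Size Area — total pixel count of the objects;
* Intensity — mean hematoxylin-channel value over object pixels;
* Circularity — mean over objects of 4*pi*area / perimeter^2, with the
  perimeter measured along the contour through the centres of border
  pixels (border pixels are object pixels 4-connected to background).

Per subject, mean Size Area and mean Intensity are divided by the mean
number of nuclei and log2-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "RUIFROK_HE_MATRIX", "MorphologyFeatures", "SubjectPhenotypes",
    "qc_tile", "deconvolve_hematoxylin", "foreground_mask", "segment_nuclei",
    "extract_features", "aggregate_subject", "process_tile",
    "percent_increase", "contour_perimeter",
]

logger = logging.getLogger(__name__)

# Ruifrok & Johnston H&E stain vectors (unit optical-density directions):
# rows = hematoxylin, eosin, residual (cross product), columns = R,G,B.
_H = np.array([0.650, 0.704, 0.286])
_E = np.array([0.072, 0.990, 0.105])
_R = np.cross(_H, _E)
RUIFROK_HE_MATRIX = np.stack(
    [_H / np.linalg.norm(_H), _E / np.linalg.norm(_E), _R / np.linalg.norm(_R)]
)

BLACK_PERCENTILE, BLACK_CUTOFF = 85, 15
WHITE_PERCENTILE, WHITE_CUTOFF = 15, 240


@dataclass
class MorphologyFeatures:
    tile_id: str
    n_nuclei: int
    size_area: float  # NaN when no nuclei
    intensity: float
    circularity: float


@dataclass
class SubjectPhenotypes:
    subject_id: str
    log2_size_per_nucleus: float
    log2_intensity_per_nucleus: float
    mean_n_nuclei: float
    mean_circularity: float


def qc_tile(tile: np.ndarray) -> bool:
    """Keep/exclude decision: ``False`` for overly black or white tiles.

    Percentiles are pooled over all three channels. A tile is excluded
    when its 85th percentile is below 15 (black) or its 15th percentile
    is above 240 (white).
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("empty tile")
    vals = tile.reshape(-1).astype(float)
    if np.percentile(vals, BLACK_PERCENTILE) < BLACK_CUTOFF:
        return False
    if np.percentile(vals, WHITE_PERCENTILE) > WHITE_CUTOFF:
        return False
    return True


def deconvolve_hematoxylin(
    tile: np.ndarray, return_all: bool = False
) -> np.ndarray:
    """Unmix an RGB tile into stain concentrations; return hematoxylin.

    Optical density per channel is -log10((v + 1) / 256) (the +1 avoids
    log 0 at v = 0), unmixed against the Ruifrok-Johnston H&E matrix.
    The hematoxylin concentration is rescaled to [0, 255] with 255
    corresponding to unit concentration; larger = more stain.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("expected an RGB tile of shape (h, w, 3)")
    od = -np.log10((tile.astype(float) + 1.0) / 256.0)
    conc = od @ np.linalg.inv(RUIFROK_HE_MATRIX)  # solves conc @ M = od
    conc = np.clip(conc, 0.0, None)
    out = np.clip(conc * 255.0, 0.0, 255.0)
    if return_all:
        return out
    return out[..., 0]


def foreground_mask(channel: np.ndarray) -> np.ndarray:
    """Binary mask: 1 where value >= half the channel mean."""
    channel = np.asarray(channel, dtype=float)
    if not np.isfinite(channel).all():
        raise ValueError("channel contains non-finite values")
    thr = 0.5 * channel.mean()
    if thr == 0.0:
        logger.warning("all-zero channel: threshold 0 marks every pixel foreground")
    return (channel >= thr).astype(np.uint8)


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by raster order of object centroids."""
    props = regionprops(labels)
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros_like(labels)
    for new, p in enumerate(order, start=1):
        out[labels == p.label] = new
    return out


def segment_nuclei(
    mask: np.ndarray,
    channel: np.ndarray | None = None,
    min_radius: float = 10,
    max_radius: float = 15,
    search_radius: float = 10,
) -> np.ndarray:
    """Label nuclei in a foreground mask.

    Holes are filled, objects with equivalent radius sqrt(area/pi) below
    ``min_radius`` are removed, and the remaining foreground is split by
    watershed seeded at distance-transform local maxima separated by at
    least ``search_radius`` pixels (resolving touching nuclei). Labels
    are assigned in raster order of object centroids so the output is
    deterministic. ``max_radius`` bounds the expected nucleus scale; it
    caps the distance transform used for seeding.
    """
    mask = np.asarray(mask).astype(bool)
    if channel is not None and np.shape(channel) != mask.shape:
        raise ValueError("mask and channel shapes differ")
    filled = ndimage.binary_fill_holes(mask)
    lab = sk_label(filled, connectivity=1)
    min_area = np.pi * min_radius**2
    areas = np.bincount(lab.ravel())
    small = np.nonzero(areas < min_area)[0]
    filled &= ~np.isin(lab, small[small > 0])
    if not filled.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(filled)
    np.minimum(dist, max_radius, out=dist)
    peaks = peak_local_max(
        dist, min_distance=int(round(search_radius)), labels=filled,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        lab = sk_label(filled, connectivity=1)
    else:
        lab = watershed(-dist, markers=markers, mask=filled)
    # watershed splitting can leave fragments below the size filter
    areas = np.bincount(lab.ravel())
    small = np.nonzero(areas < min_area)[0]
    lab[np.isin(lab, small[small > 0])] = 0
    return _relabel_raster_order(lab)


_STEPS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def contour_perimeter(obj_mask: np.ndarray) -> float:
    """Perimeter of the contour through the centres of border pixels.

    Border pixels are object pixels with a 4-connected background
    neighbour. The closed boundary is traced with Moore-neighbour
    tracing and the perimeter is the summed Euclidean distance between
    consecutive border-pixel centres (1 for axis steps, sqrt(2) for
    diagonal steps). A filled axis-aligned square of side s therefore
    has perimeter exactly 4(s - 1).
    """
    m = np.asarray(obj_mask).astype(bool)
    if m.sum() == 0:
        return 0.0
    if m.sum() == 1:
        return 1.0  # degenerate: a single pixel, nominal unit contour
    pad = np.pad(m, 1)
    # start: first object pixel in raster order, entered from its west
    # (background) neighbour; trace clockwise with Moore-neighbour
    # tracing, keeping the background "backtrack" pixel as state
    rr, cc = np.nonzero(pad)
    start = (int(rr[0]), int(cc[0]))
    start_back = (start[0], start[1] - 1)
    dir_of = {step: i for i, step in enumerate(_STEPS)}
    cur, back = start, start_back
    perimeter = 0.0
    while True:
        d_back = dir_of[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            d = (d_back + k) % 8
            cand = (cur[0] + _STEPS[d][0], cur[1] + _STEPS[d][1])
            if pad[cand]:
                nxt = cand
                break
            back_cand = cand  # last background pixel examined
        if nxt is None:  # isolated pixel (m.sum() == 1 handled above)
            return 1.0
        perimeter += np.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
        cur, back = nxt, back_cand
        if cur == start and back == start_back:  # Jacob's criterion
            break
        if perimeter > 4.0 * pad.size:  # safety bound
            break
    return perimeter


def extract_features(
    labels: np.ndarray, channel: np.ndarray, tile_id: str = ""
) -> MorphologyFeatures:
    """Per-tile features from labelled nuclei and the stain channel."""
    labels = np.asarray(labels)
    channel = np.asarray(channel, dtype=float)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    n = len(ids)
    if n == 0:
        return MorphologyFeatures(tile_id, 0, np.nan, np.nan, np.nan)
    fg = labels > 0
    size_area = float(fg.sum())
    intensity = float(channel[fg].mean())
    circ = []
    for i in ids:
        obj = labels == i
        area = float(obj.sum())
        per = contour_perimeter(obj)
        circ.append(4.0 * np.pi * area / per**2 if per > 0 else np.nan)
    return MorphologyFeatures(tile_id, int(n), size_area, intensity,
                              float(np.nanmean(circ)))


def process_tile(
    tile: np.ndarray,
    tile_id: str = "",
    min_radius: float = 10,
    max_radius: float = 15,
    search_radius: float = 10,
) -> MorphologyFeatures | None:
    """QC -> deconvolve -> threshold -> segment -> features for one tile.

    Returns ``None`` for tiles excluded by QC.
    """
    if not qc_tile(tile):
        return None
    chan = deconvolve_hematoxylin(tile)
    mask = foreground_mask(chan)
    labels = segment_nuclei(mask, chan, min_radius, max_radius, search_radius)
    return extract_features(labels, chan, tile_id)


def aggregate_subject(
    features: list[MorphologyFeatures], subject_id: str = ""
) -> SubjectPhenotypes:
    """Aggregate retained tiles to subject phenotypes.

    Tiles with zero nuclei contribute zero to the Size Area and
    Intensity means and to the mean nuclei count (rather than being
    dropped), keeping the per-tile averages unbiased. If the mean
    nuclei count is zero the log-ratio phenotypes are undefined (NaN).
    """
    if not features:
        raise ValueError("need at least one retained tile")
    area = np.array([f.size_area if f.n_nuclei > 0 else 0.0 for f in features])
    inten = np.array([f.intensity if f.n_nuclei > 0 else 0.0 for f in features])
    nnuc = np.array([float(f.n_nuclei) for f in features])
    circ = np.array([f.circularity for f in features])
    mean_n = nnuc.mean()
    if mean_n == 0:
        logger.warning("subject %s: no nuclei in any tile; phenotype missing",
                       subject_id)
        return SubjectPhenotypes(subject_id, np.nan, np.nan, 0.0, np.nan)
    return SubjectPhenotypes(
        subject_id,
        float(np.log2(area.mean() / mean_n)),
        float(np.log2(inten.mean() / mean_n)),
        float(mean_n),
        float(np.nanmean(circ)) if np.isfinite(circ).any() else np.nan,
    )


def percent_increase(larger: float, smaller: float) -> float:
    """Percent by which ``larger`` exceeds ``smaller`` relative to itself:
    100 * (larger - smaller) / larger."""
    return 100.0 * (larger - smaller) / larger
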