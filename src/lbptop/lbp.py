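"""LBP-TOP texture encoding for 3D volumes.

The local binary pattern (LBP) of a voxel thresholds P neighbors sampled on
a circle of radius R against the center value and sums the resulting bits
with weights 2^p:

    code(c) = sum_p [v_p >= v_c] * 2^p,   p = 0..P-1

with neighbor p at angle 2*pi*p/P from the +first-axis direction,
counter-clockwise, bilinearly interpolated when it falls between grid
points.  Ties count as 1 (v_p >= v_c), so a constant image encodes to the
all-ones code 2^P - 1 everywhere.

LBP-TOP extends this to volumes by encoding every voxel on the three
orthogonal planes (xy, xz, yz) through it with the same radius, and
concatenating the per-plane code histograms.  Uniform-pattern mapping
collapses the 2^P raw codes to P*(P-1)+3 bins: each code with at most two
circular bitwise transitions keeps its own bin, all others share one.
Histograms are accumulated per atlas region; the feature vector concatenates
regions (ascending label), planes (xy, xz, yz), bins (ascending).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .volume_io import LabelVolume, Volume, check_aligned

logger = logging.getLogger(__name__)

PLANES = ("xy", "xz", "yz")
PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}

# square-window neighbor offsets in angular order (0, 45, ..., 315 degrees
# counter-clockwise from +first-axis), matching the circular convention
_SQUARE_OFFSETS = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]


@dataclass
class NeighborhoodSpec:
    """Sampling geometry for one LBP plane.

    P is the neighbor count (>= 4), R_mm the radius in mm (converted to
    voxels by dividing by the in-plane spacing), ``sampling`` either
    ``circular_interpolated`` (standard LBP_{P,R}) or ``square`` (the 8
    surrounding grid offsets scaled by R; P = 8 only).
    """

    P: int = 8
    R_mm: float = 1.0
    sampling: str = "circular_interpolated"
    plane: str = "xy"

    def __post_init__(self):
        if self.P < 4:
            raise ValueError(f"P must be >= 4, got {self.P}")
        if self.R_mm <= 0:
            raise ValueError(f"R_mm must be positive, got {self.R_mm}")
        if self.sampling not in ("circular_interpolated", "square"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.sampling == "square" and self.P != 8:
            raise ValueError("square sampling is defined only for P = 8")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")


@dataclass
class LBPCodePlanes:
    """Per-voxel LBP codes on the three orthogonal planes.

    ``valid`` marks voxels whose full neighborhood on all three planes lies
    inside the volume; codes are only meaningful there.
    """

    codes_xy: np.ndarray
    codes_xz: np.ndarray
    codes_yz: np.ndarray
    valid: np.ndarray
    P: int = 8

    def plane_codes(self, plane: str) -> np.ndarray:
        return {"xy": self.codes_xy, "xz": self.codes_xz, "yz": self.codes_yz}[plane]


@dataclass
class UniformMap:
    """Lookup table from raw LBP codes to uniform-pattern bins."""

    P: int
    table: np.ndarray
    n_bins: int


@dataclass
class FeatureVector:
    values: np.ndarray
    index: list = field(default_factory=list)  # (region_label, plane, bin) triples

    def __len__(self):
        return len(self.values)


def neighbor_offsets(P: int, R_vox: float, sampling: str) -> np.ndarray:
    """In-plane neighbor offsets (first-axis, second-axis), shape (P, 2)."""
    if sampling == "square":
        if P != 8:
            raise ValueError("square sampling requires P = 8")
        R = int(round(R_vox))
        if abs(R_vox - R) > 1e-9 or R < 1:
            raise ValueError(f"square sampling needs an integer voxel radius >= 1, got {R_vox}")
        return np.array(_SQUARE_OFFSETS, dtype=np.float64) * R
    angles = 2.0 * np.pi * np.arange(P) / P
    offs = np.stack([R_vox * np.cos(angles), R_vox * np.sin(angles)], axis=1)
    # snap nearly-integer offsets so grid-exact samples compare exactly
    snapped = np.rint(offs)
    near = np.abs(offs - snapped) < 1e-9
    offs[near] = snapped[near]
    return offs


def _shift2d(data: np.ndarray, axes, sa: int, sb: int) -> np.ndarray:
    """data sampled at index + (sa, sb) along ``axes`` (wrap; masked later)."""
    return np.roll(data, (-sa, -sb), axis=axes)


def lbp_codes_plane(volume: Volume, spec: NeighborhoodSpec):
    """Compute raw LBP codes for one plane.

    Returns (codes, valid): integer codes in [0, 2^P - 1] and the boolean
    mask of voxels whose neighborhood stays inside the volume.  Boundary
    voxels are never padded; they are simply invalid.
    """
    ax_a, ax_b = PLANE_AXES[spec.plane]
    sp = volume.spacing
    if not np.isclose(sp[ax_a], sp[ax_b], rtol=1e-6):
        raise ValueError(
            f"plane {spec.plane} needs isotropic in-plane spacing, got {sp[ax_a]} vs {sp[ax_b]} mm"
        )
    R_vox = spec.R_mm / sp[ax_a]
    if R_vox < 1 - 1e-9:
        raise ValueError(f"radius {spec.R_mm} mm is {R_vox:.3f} voxels (< 1) on plane {spec.plane}")

    offs = neighbor_offsets(spec.P, R_vox, spec.sampling)
    data = volume.data
    codes = np.zeros(data.shape, dtype=np.int64)
    for p, (da, db) in enumerate(offs):
        ia, ib = int(np.floor(da)), int(np.floor(db))
        fa, fb = da - ia, db - ib
        if fa == 0.0 and fb == 0.0:
            vp = _shift2d(data, (ax_a, ax_b), ia, ib)
        else:
            # nested lerp: exact when the four corners are equal, so flat
            # in-plane regions always compare as ties
            s00 = _shift2d(data, (ax_a, ax_b), ia, ib)
            s01 = _shift2d(data, (ax_a, ax_b), ia, ib + 1)
            s10 = _shift2d(data, (ax_a, ax_b), ia + 1, ib)
            s11 = _shift2d(data, (ax_a, ax_b), ia + 1, ib + 1)
            top = s00 + fb * (s01 - s00)
            bot = s10 + fb * (s11 - s10)
            vp = top + fa * (bot - top)
        codes |= (vp >= data).astype(np.int64) << p

    margin = int(np.ceil(np.max(np.abs(offs)) - 1e-9))
    valid = np.zeros(data.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[ax_a] = slice(margin, data.shape[ax_a] - margin)
    sl[ax_b] = slice(margin, data.shape[ax_b] - margin)
    if data.shape[ax_a] > 2 * margin and data.shape[ax_b] > 2 * margin:
        valid[tuple(sl)] = True
    return codes, valid


def lbp_top(
    volume: Volume,
    P: int = 8,
    R_mm: float = 1.0,
    sampling: str = "circular_interpolated",
    allow_anisotropic: bool = False,
) -> LBPCodePlanes:
    """Encode a volume on the three orthogonal planes with one shared radius.

    Requires isotropic voxels unless ``allow_anisotropic`` permits a
    per-plane mm-to-voxel conversion.  The joint validity mask is the
    conjunction of the three per-plane masks.
    """
    if not volume.is_isotropic() and not allow_anisotropic:
        raise ValueError(
            f"volume spacing {volume.spacing} is anisotropic; "
            "pass allow_anisotropic=True for per-plane radius conversion"
        )
    out = {}
    valid = np.ones(volume.shape, dtype=bool)
    for plane in PLANES:
        codes, v = lbp_codes_plane(volume, NeighborhoodSpec(P=P, R_mm=R_mm, sampling=sampling, plane=plane))
        out[plane] = codes
        valid &= v
    return LBPCodePlanes(out["xy"], out["xz"], out["yz"], valid, P=P)


def uniformity(code: int, P: int) -> int:
    """Number of circular bitwise transitions (0->1 or 1->0) in a code."""
    code = int(code)
    if not 0 <= code < (1 << P):
        raise ValueError(f"code {code} out of range for P={P}")
    bits = [(code >> i) & 1 for i in range(P)]
    return sum(bits[i] != bits[(i + 1) % P] for i in range(P))


def build_uniform_map(P: int = 8) -> UniformMap:
    """Uniform-pattern lookup table.

    Codes with U <= 2 get distinct bins in ascending code order; all other
    codes share the final bin.  Bin count is P*(P-1) + 3 (59 for P = 8).
    """
    if not 4 <= P <= 16:
        raise ValueError(f"P must be in [4, 16], got {P}")
    n_codes = 1 << P
    n_bins = P * (P - 1) + 3
    table = np.full(n_codes, n_bins - 1, dtype=np.int64)
    nxt = 0
    for code in range(n_codes):
        if uniformity(code, P) <= 2:
            table[code] = nxt
            nxt += 1
    assert nxt == n_bins - 1, f"uniform census {nxt} != {n_bins - 1}"
    return UniformMap(P=P, table=table, n_bins=n_bins)


def region_histograms(
    codes: LBPCodePlanes,
    atlas: LabelVolume,
    umap: UniformMap | None = None,
    normalize: bool = True,
) -> FeatureVector:
    """Per-region, per-plane histograms of uniform-mapped codes.

    The center voxel's atlas label decides region membership; neighbors may
    lie outside the region.  Order: regions ascending, then planes
    (xy, xz, yz), then bins ascending.  With ``normalize`` each
    (region, plane) block is L1-normalized; blocks of empty regions stay
    all-zero (with a logged warning), never NaN.
    """
    if umap is None:
        umap = build_uniform_map(codes.P)
    if umap.P != codes.P:
        raise ValueError(f"uniform map P={umap.P} does not match codes P={codes.P}")
    if atlas.shape != codes.valid.shape:
        raise ValueError(f"atlas shape {atlas.shape} does not match code arrays {codes.valid.shape}")
    regions = atlas.region_labels
    n_bins = umap.n_bins
    values = np.zeros(len(regions) * 3 * n_bins, dtype=np.float64)
    index = []
    pos = 0
    for lab in regions:
        mask = (atlas.labels == lab) & codes.valid
        n_valid = int(mask.sum())
        if n_valid == 0:
            logger.warning("region %d has zero valid voxels; emitting a zero block", lab)
        for plane in PLANES:
            if n_valid:
                mapped = umap.table[codes.plane_codes(plane)[mask]]
                hist = np.bincount(mapped, minlength=n_bins).astype(np.float64)
                if normalize:
                    hist /= n_valid
            else:
                hist = np.zeros(n_bins)
            values[pos : pos + n_bins] = hist
            index.extend((int(lab), plane, b) for b in range(n_bins))
            pos += n_bins
    return FeatureVector(values=values, index=index)


@dataclass
class FeatureGroup:
    """A named block of feature columns (e.g. one LBP radius)."""

    name: str
    matrix: np.ndarray  # subjects x columns
    index: list  # per-column (region_label, plane, bin)
    whole_brain: bool = False  # flagged groups skip the drop step in selection


def extract_features(
    volumes,
    atlas: LabelVolume,
    P: int = 8,
    radii_mm=(1.0, 2.0, 3.0),
    sampling: str = "circular_interpolated",
    normalize: bool = True,
) -> list:
    """LBP-TOP feature matrices for a cohort, one :class:`FeatureGroup` per radius.

    Per-radius groups are kept separate because the iterative selector
    consumes them as distinct groups.  Deterministic; logs per-subject valid
    voxel counts.
    """
    volumes = list(volumes)
    umap = build_uniform_map(P)
    groups = []
    for R in radii_mm:
        rows, idx = [], None
        for si, vol in enumerate(volumes):
            try:
                check_aligned(vol, atlas)
            except ValueError as err:
                raise ValueError(f"subject {si}: {err}") from err
            codes = lbp_top(vol, P=P, R_mm=R, sampling=sampling)
            logger.info("subject %d R=%g mm: %d valid voxels", si, R, int(codes.valid.sum()))
            fv = region_histograms(codes, atlas, umap, normalize=normalize)
            rows.append(fv.values)
            idx = fv.index
        groups.append(
            FeatureGroup(name=f"R{R:g}mm", matrix=np.array(rows), index=idx,
                         whole_brain=len(atlas.region_labels) == 1)
        )
    return groups


def feature_dimension(n_regions: int, P: int = 8) -> int:
    """Feature-vector length: n_regions x 3 planes x (P(P-1)+3) bins."""
    return n_regions * 3 * (P * (P - 1) + 3)


class LBPTOPExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer from volumes to LBP-TOP feature rows.

    Modelled on the nilearn masker pattern: ``transform`` consumes a list of
    :class:`~lbptop.volume_io.Volume` (not an array) and emits a subjects x
    features matrix — per-radius groups concatenated in radius order, each
    group laid out regions-ascending, planes (xy, xz, yz), bins ascending.

    Parameters
    ----------
    atlas : LabelVolume
        Parcellation shared by all subjects (single-label mask = whole brain).
    P, radii_mm, sampling, normalize
        Passed through to the encoder; see :func:`extract_features`.

    Attributes
    ----------
    group_slices_ : per-radius column slices into the output matrix.
    feature_index_ : per-column (region_label, plane, bin) triples.
    whole_brain_flags_ : per-group drop-exemption flags for the selector.
    """

    def __init__(self, atlas=None, P=8, radii_mm=(1.0, 2.0, 3.0),
                 sampling="circular_interpolated", normalize=True):
        self.atlas = atlas
        self.P = P
        self.radii_mm = radii_mm
        self.sampling = sampling
        self.normalize = normalize

    def fit(self, X=None, y=None):
        if self.atlas is None:
            raise ValueError("LBPTOPExtractor requires an atlas")
        n_regions = len(self.atlas.region_labels)
        per_group = feature_dimension(n_regions, self.P)
        self.group_slices_ = [
            slice(k * per_group, (k + 1) * per_group) for k in range(len(self.radii_mm))
        ]
        self.n_features_out_ = per_group * len(self.radii_mm)
        return self

    def transform(self, X):
        """X: list of Volume aligned with the atlas -> feature matrix."""
        if not hasattr(self, "group_slices_"):
            self.fit()
        groups = extract_features(
            X, self.atlas, P=self.P, radii_mm=self.radii_mm,
            sampling=self.sampling, normalize=self.normalize,
        )
        self.feature_index_ = [t for g in groups for t in g.index]
        self.whole_brain_flags_ = [g.whole_brain for g in groups]
        return np.hstack([g.matrix for g in groups])
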