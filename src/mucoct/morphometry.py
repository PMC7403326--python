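"""Digital sections and villous-height / crypt-depth (VH:CrD) morphometry.

A 3-D volume is resliced along an arbitrarily orientated plane — the digital
counterpart of recutting a paraffin block until the crypts run
longitudinally.  On the resulting section, villous height (VH) and crypt
depth (CrD) are measured per crypt-villous pair, averaged over at least
three pairs, and the mean ratio is classified against the diagnostic
cutoff: VH:CrD < 2.0 indicates a celiac-type lesion.

Landmarks can come from an expert (delimited text file: sample, section_id,
pair_id, role ∈ {tip, junction, base}, x_um, y_um) or, on synthetic
phantoms, from the automatic height-profile heuristic
:func:`auto_landmarks`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import ConfigurationError, InsufficientPairsError, MissingCryptError, MucoctError
from .volume_io import BinaryVolume, VoxelVolume

__all__ = [
    "SectionPlane",
    "SectionImage",
    "VillusCryptPair",
    "MorphometryResult",
    "extract_section",
    "measure_pair",
    "compute_vhcd",
    "auto_landmarks",
    "read_landmark_file",
    "write_landmark_file",
    "pairs_from_landmarks",
]

DIAGNOSTIC_CUTOFF = 2.0


@dataclass
class SectionPlane:
    """Orientated section plane: centre point, in-plane frame, extent.

    ``u``/``v`` are in-plane unit axes, ``normal`` completes the frame; all
    vectors use (z, y, x) components, lengths in µm.  ``v`` is the section's
    row axis (axis 0 of the image) and should point lumen-ward (+z) when the
    section is meant for height-profile morphometry.
    """

    point: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray
    extent_u_um: float
    extent_v_um: float
    pixel_spacing_um: float

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        for name in ("u", "v", "normal"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(np.linalg.norm(vec), 1.0, atol=1e-6):
                raise ConfigurationError(f"plane vector {name} must be unit length")
            setattr(self, name, vec)
        for a, b in (("u", "v"), ("u", "normal"), ("v", "normal")):
            if abs(float(getattr(self, a) @ getattr(self, b))) > 1e-6:
                raise ConfigurationError(f"plane vectors {a}, {b} must be orthogonal")
        if self.extent_u_um <= 0 or self.extent_v_um <= 0 or self.pixel_spacing_um <= 0:
            raise ConfigurationError("extent and pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        nv = max(2, int(round(self.extent_v_um / self.pixel_spacing_um)))
        nu = max(2, int(round(self.extent_u_um / self.pixel_spacing_um)))
        return nv, nu


@dataclass
class SectionImage:
    """2-D resampled section; axis 0 along the plane's v axis."""

    values: np.ndarray
    pixel_spacing_um: float
    provenance: SectionPlane | None = None
    binary: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class VillusCryptPair:
    """One crypt-villous pair; landmark coordinates are section-local (x, y) µm.

    ``crypt_base`` / ``crd_um`` are None when no crypt is detectable (crypt
    depth "absent"), which blocks ratio computation downstream.
    """

    villus_tip: tuple[float, float]
    villus_crypt_junction: tuple[float, float]
    crypt_base: tuple[float, float] | None
    vh_um: float
    crd_um: float | None


@dataclass
class MorphometryResult:
    pairs: list
    mean_vh_um: float
    mean_crd_um: float
    ratio: float
    n_pairs: int
    label: str


def extract_section(
    vol: VoxelVolume | BinaryVolume, plane: SectionPlane, interp: str | None = None
) -> SectionImage:
    """Resample the volume on the section plane.

    Binary volumes use nearest-neighbour; grayscale defaults to trilinear.
    The plane footprint must lie inside the volume.
    """
    is_binary = isinstance(vol, BinaryVolume)
    values = vol.occupancy if is_binary else vol.values
    if interp is None:
        interp = "nearest" if is_binary else "linear"
    if interp not in ("nearest", "linear"):
        raise ConfigurationError(f"interp must be 'nearest' or 'linear', got {interp!r}")
    if is_binary and interp == "linear":
        interp = "nearest"
    nv, nu = plane.shape
    ps = plane.pixel_spacing_um
    iv = (np.arange(nv) - (nv - 1) / 2.0) * ps
    iu = (np.arange(nu) - (nu - 1) / 2.0) * ps
    world = (
        plane.point[None, None, :]
        + iv[:, None, None] * plane.v[None, None, :]
        + iu[None, :, None] * plane.u[None, None, :]
    )  # (nv, nu, 3) in (z, y, x)
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    idx = (world - origin) / spacing
    dims = np.asarray(values.shape)
    lo = idx.reshape(-1, 3).min(axis=0)
    hi = idx.reshape(-1, 3).max(axis=0)
    if (lo < -0.5).any() or (hi > dims - 0.5).any():
        raise MucoctError(
            f"section plane footprint leaves the volume (index range {lo}..{hi}, dims {dims})"
        )
    order = 0 if interp == "nearest" else 1
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(
        values.astype(np.float32) if not is_binary else values.astype(np.uint8),
        coords, order=order, mode="nearest",
    )
    if is_binary:
        out = out.astype(bool)
    return SectionImage(out, ps, provenance=plane, binary=is_binary)


def measure_pair(section: SectionImage, landmarks) -> VillusCryptPair:
    """Build one pair from (tip, junction, base) section-local landmarks (µm).

    ``base`` may be None (crypt absent).  Distances are Euclidean in µm.
    """
    if len(landmarks) != 3:
        raise ConfigurationError("landmarks must be (tip, junction, base)")
    tip, junction, base = landmarks
    nv, nu = section.shape
    ps = section.pixel_spacing_um
    bounds = (nu * ps, nv * ps)
    for name, pt in (("tip", tip), ("junction", junction), ("base", base)):
        if pt is None:
            continue
        x, y = pt
        if not (-ps / 2 <= x <= bounds[0] + ps / 2 and -ps / 2 <= y <= bounds[1] + ps / 2):
            raise MucoctError(f"landmark {name} at ({x}, {y}) µm lies outside the section")
    tip = (float(tip[0]), float(tip[1]))
    junction = (float(junction[0]), float(junction[1]))
    vh = float(np.hypot(tip[0] - junction[0], tip[1] - junction[1]))
    if vh == 0.0:
        warnings.warn("villus tip coincides with the crypt-villous junction (VH = 0)",
                      stacklevel=2)
    if base is None:
        return VillusCryptPair(tip, junction, None, vh, None)
    base = (float(base[0]), float(base[1]))
    crd = float(np.hypot(junction[0] - base[0], junction[1] - base[1]))
    return VillusCryptPair(tip, junction, base, vh, crd)


def compute_vhcd(pairs, method: str = "ratio_of_means") -> MorphometryResult:
    """Average at least three crypt-villous pairs and classify.

    The default ratio is mean(VH)/mean(CrD) — robust to one short crypt; the
    mean of per-pair ratios is available as ``method="mean_of_ratios"``.
    The lesion cutoff is strict: VH:CrD < 2.0 is diagnostic, exactly 2.0 is
    normal morphometry.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise InsufficientPairsError(
            f"VH:CrD needs at least three crypt-villous pairs, got {len(pairs)}"
        )
    if any(p.crd_um is None for p in pairs):
        raise MissingCryptError(
            "ratio undefined: one or more pairs have no detectable crypt"
        )
    vh = np.array([p.vh_um for p in pairs], dtype=float)
    crd = np.array([p.crd_um for p in pairs], dtype=float)
    if method == "ratio_of_means":
        ratio = float(vh.mean() / crd.mean())
    elif method == "mean_of_ratios":
        ratio = float((vh / crd).mean())
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    label = "diagnostic_lesion" if ratio < DIAGNOSTIC_CUTOFF else "normal_morphometry"
    return MorphometryResult(pairs, float(vh.mean()), float(crd.mean()), ratio,
                             len(pairs), label)


# ---------------------------------------------------------------------------
# automatic landmarks on binary phantom sections
# ---------------------------------------------------------------------------

def _height_profile(section: SectionImage) -> np.ndarray:
    """Top-of-tissue interface height (µm) per column; axis 0 points up."""
    occ = section.values
    nv = occ.shape[0]
    has = occ.any(axis=0)
    top = nv - 1 - np.argmax(occ[::-1, :], axis=0)
    height = (top + 0.5) * section.pixel_spacing_um
    height = np.where(has, height, 0.0)
    return height


def _analyze_gap(seg: np.ndarray, tips: float, wall_jump_um: float,
                 min_prominence_um: float, crypt_min_depth_um: float):
    """Saddle level and crypt floor of one inter-villus profile segment.

    A crypt well has near-vertical walls, so its floor forms a height
    cluster separated from the saddle plateau by a jump larger than any
    step a smooth relief can produce.  The sorted segment heights are split
    at jumps > ``wall_jump_um``; the lowest cluster is the crypt floor only
    when the next cluster up (the saddle) sits clearly below the flanking
    villus tips — otherwise the lowest cluster *is* the saddle.

    Returns (junction_level, crypt_floor_or_None).
    """
    vals = np.sort(seg)
    splits = np.nonzero(np.diff(vals) > wall_jump_um)[0]
    if len(splits) == 0:
        return float(np.median(vals)), None
    lowest = vals[: splits[0] + 1]
    second = vals[splits[0] + 1: (splits[1] + 1 if len(splits) > 1 else len(vals))]
    saddle = float(np.median(second))
    if saddle > tips - min_prominence_um:
        # the jump is a villus wall, not a crypt: the lowest cluster is the saddle
        return float(np.median(lowest)), None
    floor = float(np.median(lowest))
    if saddle - floor < crypt_min_depth_um:
        return saddle, None
    return saddle, floor


def auto_landmarks(
    section: SectionImage,
    min_prominence_um: float = 50.0,
    crypt_min_depth_um: float = 10.0,
    wall_jump_um: float = 25.0,
) -> list[VillusCryptPair]:
    """Detect crypt-villous pairs from the tissue height profile of a section.

    Heuristic intended for synthetic phantoms (on real scans manual
    landmarks govern): local maxima of the column-wise tissue height are
    villus tips; for each villus, the junction level is the saddle/plateau
    level of the adjacent inter-villus segments; crypt floors are height
    clusters separated from the saddle by a near-vertical wall (a jump
    > ``wall_jump_um`` in the sorted segment heights — smooth mucosal relief
    such as sinusoidal folds never produces one, so its ``crd`` is flagged
    absent).  Each pair's landmarks are emitted collinear along the villus
    axis, so VH and CrD are the vertical tip–junction and junction–base
    distances.

    Raises :class:`InsufficientPairsError` when fewer than three pairs are
    detectable (e.g. flat mucosa).
    """
    if not section.binary:
        raise ConfigurationError("auto_landmarks requires a binary section")
    profile = _height_profile(section)
    ps = section.pixel_spacing_um
    if profile.max() - profile.min() < min_prominence_um:
        raise InsufficientPairsError("no villous relief detectable in section")
    peaks, _ = signal.find_peaks(profile, prominence=min_prominence_um)
    if len(peaks) < 3:
        raise InsufficientPairsError(
            f"only {len(peaks)} villus tips detected; need >= 3 crypt-villous pairs"
        )

    gaps = []  # (junction level, crypt floor | None) per inter-peak segment
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = profile[a + 1:b]
        if len(seg) == 0:
            gaps.append(None)
            continue
        tips = float(min(profile[a], profile[b]))
        gaps.append(_analyze_gap(seg, tips, wall_jump_um,
                                 min_prominence_um, crypt_min_depth_um))

    pairs = []
    for i, p in enumerate(peaks):
        adj = [g for g in (gaps[i - 1] if i > 0 else None,
                           gaps[i] if i < len(gaps) else None) if g is not None]
        if not adj:
            continue
        junction_level = float(np.mean([g[0] for g in adj]))
        tip_level = float(profile[p])
        x = p * ps
        floors = [g[1] for g in adj if g[1] is not None]
        if floors:
            crd = junction_level - min(floors)
            base_pt = (x, junction_level - crd)
        else:
            crd = None
            base_pt = None
        pairs.append(
            VillusCryptPair(
                villus_tip=(x, tip_level),
                villus_crypt_junction=(x, junction_level),
                crypt_base=base_pt,
                vh_um=tip_level - junction_level,
                crd_um=crd,
            )
        )
    if len(pairs) < 3:
        raise InsufficientPairsError(
            f"only {len(pairs)} usable crypt-villous pairs detected; need >= 3"
        )
    return pairs


# ---------------------------------------------------------------------------
# landmark file IO
# ---------------------------------------------------------------------------

_LM_COLUMNS = ["sample", "section_id", "pair_id", "role", "x_um", "y_um"]
_ROLES = ("tip", "junction", "base")


def read_landmark_file(path) -> pd.DataFrame:
    """Read a delimited landmark table (comma or tab separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _LM_COLUMNS if c not in df.columns]
    if missing:
        raise MucoctError(f"landmark file {path} lacks columns {missing}")
    bad = set(df["role"]) - set(_ROLES)
    if bad:
        raise MucoctError(f"landmark file has unknown roles {sorted(bad)}")
    return df[_LM_COLUMNS]


def write_landmark_file(df: pd.DataFrame, path) -> None:
    df[_LM_COLUMNS].to_csv(path, index=False)


def pairs_from_landmarks(
    df: pd.DataFrame, section: SectionImage, sample=None, section_id=None
) -> list[VillusCryptPair]:
    """Assemble pairs from a landmark table for one section."""
    sel = df
    if sample is not None:
        sel = sel[sel["sample"] == sample]
    if section_id is not None:
        sel = sel[sel["section_id"] == section_id]
    pairs = []
    for pair_id, grp in sel.groupby("pair_id", sort=True):
        roles = {}
        for role in _ROLES:
            rows = grp[grp["role"] == role]
            if len(rows):
                roles[role] = (float(rows.iloc[0]["x_um"]), float(rows.iloc[0]["y_um"]))
        if "tip" not in roles or "junction" not in roles:
            raise MucoctError(f"pair {pair_id}: needs at least tip and junction landmarks")
        pairs.append(
            measure_pair(section, (roles["tip"], roles["junction"], roles.get("base")))
        )
    return pairs
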