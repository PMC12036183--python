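"""Optical strain measurement from landmark dots in snapshot sequences.

Tissue strain is measured from the separation of dark circular landmarks
(ink dots, or cell junctions treated as points) tracked across the snapshot
taken at each actuator step, in parallel with the strain implied by actuator
displacement.  The two pathways disagree whenever the specimen slips in its
grips — the landmark pathway is the trustworthy one, and the difference is
the slip.

Detection is global Otsu thresholding, connected components, an area filter
(which also rejects the large grip tags), and an intensity-weighted centroid
per component for sub-pixel localisation.  Tracking is frame-to-frame
nearest-neighbour matching under a maximum-displacement gate that fails
loudly — a lost landmark or an ambiguous assignment raises instead of
silently corrupting identities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .controller import ExperimentLog
from .errors import AmbiguousMatchError, PartialTrackError, TrackingError
from .instrument import Frame

__all__ = [
    "LandmarkTrack",
    "StrainSeries",
    "detect_landmarks",
    "track",
    "pixel_scale",
    "strain_pct",
    "landmark_strain",
    "grip_strain",
    "strain_series_from_run",
]


def detect_landmarks(frame: Frame | np.ndarray, min_area_px: float = 5,
                     max_area_px: float = 2000, polarity: str = "dark",
                     threshold: float | None = None) -> np.ndarray:
    """Sub-pixel centroids (x_px, y_px) of landmark blobs, sorted by x.

    ``polarity`` names the landmarks' appearance against the background
    (``"dark"`` for ink dots on a bright specimen).  ``threshold`` overrides
    the automatic Otsu choice.  A zero-variance image yields an empty result,
    not an error.  Blobs outside ``[min_area_px, max_area_px]`` are discarded,
    which is also how the grip tags (large) and noise specks (small) are
    rejected.
    """
    if min_area_px <= 0 or max_area_px <= 0:
        raise TrackingError("area bounds must be positive")
    img = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    img = img.astype(float)
    if img.std() == 0:
        return np.empty((0, 2))
    thr = float(threshold_otsu(img)) if threshold is None else float(threshold)
    if polarity == "dark":
        mask = img < thr
        weight = np.clip(thr - img, 0.0, None)
    elif polarity == "bright":
        mask = img > thr
        weight = np.clip(img - thr, 0.0, None)
    else:
        raise TrackingError(f"unknown polarity {polarity!r}")

    centroids = []
    for region in regionprops(label(mask), intensity_image=weight):
        if not (min_area_px <= region.area <= max_area_px):
            continue
        cy, cx = region.centroid_weighted
        centroids.append((cx, cy))
    centroids.sort(key=lambda c: c[0])
    return np.asarray(centroids).reshape(-1, 2)


@dataclass(frozen=True)
class LandmarkTrack:
    """Per-frame landmark centroids with stable identities.

    ``positions_px`` has shape (n_frames, n_landmarks, 2); column order fixes
    the identity, assigned in the first frame by increasing x.
    """

    positions_px: np.ndarray
    timestamps_us: np.ndarray
    scale_um_per_px: float

    @property
    def n_frames(self) -> int:
        return self.positions_px.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.positions_px.shape[1]

    def separation_um(self, pair: tuple[int, int]) -> np.ndarray:
        """Euclidean distance between two tracked landmarks, per frame (um)."""
        a, b = pair
        d = np.linalg.norm(self.positions_px[:, a] - self.positions_px[:, b],
                           axis=1)
        return d * self.scale_um_per_px


def _count_matchings(candidates: list[set[int]]) -> int:
    """Number of perfect matchings in a small bipartite candidate graph."""
    n = len(candidates)
    count = 0

    def rec(i: int, used: set[int]):
        nonlocal count
        if count > 1:
            return
        if i == n:
            count += 1
            return
        for j in candidates[i] - used:
            rec(i + 1, used | {j})

    rec(0, set())
    return count


def track(frames: Sequence[Frame | np.ndarray], scale_um_per_px: float | None = None,
          gate_px: float | None = None, min_area_px: float = 5,
          max_area_px: float = 2000,
          polarity: str = "dark") -> LandmarkTrack:
    """Detect and match landmarks across a snapshot sequence.

    The gate defaults to a quarter of the smallest landmark separation in the
    first frame (steps are small relative to dot spacing).  Matching requires
    a *unique* assignment with every displacement inside the gate; count
    changes raise :class:`PartialTrackError` naming the frame, multiple valid
    assignments raise :class:`AmbiguousMatchError` rather than risking a
    silent identity swap.
    """
    if len(frames) < 2:
        raise TrackingError("need at least two frames to track")
    if scale_um_per_px is None:
        first = frames[0]
        if not isinstance(first, Frame):
            raise TrackingError("scale_um_per_px required for bare arrays")
        scale_um_per_px = first.scale_um_per_px

    detections = [
        detect_landmarks(f, min_area_px=min_area_px, max_area_px=max_area_px,
                         polarity=polarity)
        for f in frames
    ]
    n = detections[0].shape[0]
    if n == 0:
        raise TrackingError("no landmarks detected in the first frame")
    if gate_px is None:
        if n >= 2:
            diffs = np.linalg.norm(
                detections[0][:, None] - detections[0][None, :], axis=2)
            gate_px = 0.25 * diffs[np.triu_indices(n, 1)].min()
        else:
            gate_px = np.inf

    positions = np.empty((len(frames), n, 2))
    positions[0] = detections[0]
    timestamps = np.array([
        f.timestamp_us if isinstance(f, Frame) else i
        for i, f in enumerate(frames)
    ])

    for fi in range(1, len(frames)):
        cur = detections[fi]
        if cur.shape[0] != n:
            raise PartialTrackError(fi)
        prev = positions[fi - 1]
        dists = np.linalg.norm(prev[:, None] - cur[None, :], axis=2)
        candidates = [set(np.nonzero(dists[i] <= gate_px)[0]) for i in range(n)]
        if any(not c for c in candidates):
            raise PartialTrackError(
                fi, f"a landmark moved beyond the {gate_px:.1f} px gate "
                    f"at frame {fi}")
        n_match = _count_matchings(candidates)
        if n_match == 0:
            raise PartialTrackError(fi)
        if n_match > 1:
            raise AmbiguousMatchError(fi)
        # unique matching: greedy by distance is now safe
        order = np.argsort(dists, axis=None)
        assigned_prev: dict[int, int] = {}
        used_cur: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), n)
            if i in assigned_prev or j in used_cur or j not in candidates[i]:
                continue
            assigned_prev[i] = j
            used_cur.add(j)
            if len(assigned_prev) == n:
                break
        positions[fi] = cur[[assigned_prev[i] for i in range(n)]]

    return LandmarkTrack(positions_px=positions, timestamps_us=timestamps,
                         scale_um_per_px=float(scale_um_per_px))


def pixel_scale(reference_length_um: float, measured_px: float) -> float:
    """um per pixel from an object of known physical size in the image.

    A mounting tag of known width (e.g. 12.7 mm) doubles as a scale bar.
    """
    if reference_length_um <= 0 or measured_px <= 0:
        raise TrackingError("reference length and measured pixels must be > 0")
    return reference_length_um / measured_px


def strain_pct(reference_length: float, current_length: float) -> float:
    """Engineering strain in percent: (L - L0) / L0 x 100."""
    if reference_length == 0:
        raise TrackingError("reference length must be nonzero")
    return (current_length - reference_length) / reference_length * 100.0


@dataclass(frozen=True)
class StrainSeries:
    """Per-step strain along the two pathways, in percent.

    ``slip_pct`` is grip minus landmark strain: the part of the imposed
    displacement the tissue never saw.
    """

    landmark_pct: np.ndarray
    grip_pct: np.ndarray

    @property
    def slip_pct(self) -> np.ndarray:
        return self.grip_pct - self.landmark_pct


def landmark_strain(track_: LandmarkTrack, pair: tuple[int, int] = (0, 1),
                    reference_frame: int = 0) -> np.ndarray:
    """Per-frame strain (%) of a landmark pair relative to a reference frame."""
    d = track_.separation_um(pair)
    d_ref = d[reference_frame]
    if d_ref == 0:
        raise TrackingError("reference separation is zero")
    return (d - d_ref) / d_ref * 100.0


def grip_strain(log: ExperimentLog, reference_length_um: float,
                reference_index: int = 0) -> np.ndarray:
    """Per-record strain (%) implied by actuator displacement.

    The displacement since the reference record is divided by
    ``reference_length_um`` — use the same reference distance as the landmark
    pathway when comparing the two, or the actuator's reference extension for
    the raw grip-pathway convention.
    """
    if reference_length_um <= 0:
        raise TrackingError("reference length must be > 0")
    pos_um = np.array([r.position_nm for r in log.records]) / 1e3
    return (pos_um - pos_um[reference_index]) / reference_length_um * 100.0


def strain_series_from_run(log: ExperimentLog, pair: tuple[int, int] = (0, 1),
                           reference_frame: int = 0,
                           track_kwargs: dict | None = None) -> StrainSeries:
    """Both strain pathways for a run that kept its frames in memory.

    The grip pathway is referenced to the landmark pair's initial separation,
    so the two series are directly comparable and their difference is the
    slip strain.
    """
    if not log.frames:
        raise TrackingError("run has no frames; was the camera enabled?")
    tr = track(log.frames, **(track_kwargs or {}))
    lm = landmark_strain(tr, pair=pair, reference_frame=reference_frame)
    d_ref = tr.separation_um(pair)[reference_frame]
    gp = grip_strain(log, reference_length_um=d_ref,
                     reference_index=reference_frame)
    return StrainSeries(landmark_pct=lm, grip_pct=gp)
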