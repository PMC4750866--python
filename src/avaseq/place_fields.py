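"""Place-cell classification and behavioral RUN-sequence definition.

A *classical place cell* is a pyramidal cell that passes the rate filters
(> 50 spikes during RUN, < 10 Hz during POST), has spatial coherence > 0.3,
a place field of more than nine contiguous 1x1 cm pixels at >= 3x the
session mean rate, and fires > 70% of its spikes within a contiguous 40% of
the angular distance around the track.  The RUN sequence is the classical
place cells ordered by the angular position of their firing peaks along the
travel direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .parsing import SpikeEnsemble

MIN_RUN_SPIKES = 50
MAX_POST_RATE_HZ = 10.0
COHERENCE_THRESHOLD = 0.3
FIELD_RATE_FACTOR = 3.0
MIN_FIELD_PIXELS = 9          # strict: field must exceed this count
ANGULAR_BINS = 200
ANGULAR_WINDOW_FRAC = 0.4
ANGULAR_SPIKE_FRAC = 0.7


@dataclass
class RateMap:
    """Firing-rate grid on square pixels with its occupancy and spike counts."""

    rate: np.ndarray          # Hz; NaN where unoccupied
    occupancy: np.ndarray     # seconds per pixel
    counts: np.ndarray
    pixel_m: float
    origin: tuple[float, float]   # (xmin, ymin) of pixel (0, 0)

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0

    def peak_position(self, min_occupancy_s: float = 0.5) -> tuple[float, float]:
        """(x, y) of the max-rate pixel among adequately sampled pixels.

        Pixels visited for less than ``min_occupancy_s`` are ignored: a lone
        spike during a 20 ms pass otherwise dominates the map.
        """
        mask = self.occupancy >= min_occupancy_s
        if not mask.any():
            mask = self.occupied
        rate = np.where(mask, np.nan_to_num(self.rate), -np.inf)
        iy, ix = np.unravel_index(int(np.argmax(rate)), rate.shape)
        return (self.origin[0] + (ix + 0.5) * self.pixel_m,
                self.origin[1] + (iy + 0.5) * self.pixel_m)


def spike_positions(spike_times: np.ndarray, trajectory: np.ndarray) -> np.ndarray:
    """(x, y) per spike via the nearest trajectory sample in time."""
    t = trajectory[:, 0]
    idx = np.searchsorted(t, spike_times)
    idx = np.clip(idx, 1, t.size - 1)
    left = np.abs(spike_times - t[idx - 1]) <= np.abs(t[idx] - spike_times)
    idx = np.where(left, idx - 1, idx)
    return trajectory[idx, 1:3]


def build_rate_map(
    spike_times: np.ndarray, trajectory: np.ndarray, pixel_m: float = 0.01
) -> RateMap:
    """Spikes-per-pixel divided by time-per-pixel on a square-pixel grid."""
    if trajectory.size == 0:
        raise ValueError("empty trajectory")
    t = trajectory[:, 0]
    dt = np.median(np.diff(t)) if t.size > 1 else 0.0
    xmin, ymin = trajectory[:, 1].min(), trajectory[:, 2].min()
    xi = np.floor((trajectory[:, 1] - xmin) / pixel_m).astype(int)
    yi = np.floor((trajectory[:, 2] - ymin) / pixel_m).astype(int)
    nx, ny = xi.max() + 1, yi.max() + 1
    occupancy = np.zeros((ny, nx))
    np.add.at(occupancy, (yi, xi), dt)
    counts = np.zeros((ny, nx))
    if spike_times.size:
        pos = spike_positions(np.asarray(spike_times), trajectory)
        sx = np.clip(np.floor((pos[:, 0] - xmin) / pixel_m).astype(int), 0, nx - 1)
        sy = np.clip(np.floor((pos[:, 1] - ymin) / pixel_m).astype(int), 0, ny - 1)
        np.add.at(counts, (sy, sx), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
    return RateMap(rate=rate, occupancy=occupancy, counts=counts,
                   pixel_m=pixel_m, origin=(float(xmin), float(ymin)))


def spatial_coherence(rate_map: RateMap) -> float:
    """Correlation of each occupied pixel's rate with its occupied neighbors' mean.

    The classic nearest-neighbor (8-neighborhood) autocorrelation on the
    unsmoothed rate map; returns NaN when either vector is degenerate.
    """
    occ = rate_map.occupied
    rate = np.where(occ, rate_map.rate, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(rate, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(occ.astype(float), kernel, mode="constant", cval=0.0)
    use = occ & (nbr_cnt > 0)
    if use.sum() < 2:
        raise ValueError("coherence needs at least 2 occupied pixels with neighbors")
    x = rate[use]
    y = nbr_sum[use] / nbr_cnt[use]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def detect_place_field(rate_map: RateMap, session_mean_rate: float) -> np.ndarray:
    """Largest 8-connected component of pixels at >= 3x the session mean rate.

    Returns the (row, col) index array of the component; the field criterion
    requires strictly more than nine pixels.
    """
    thresh = FIELD_RATE_FACTOR * session_mean_rate
    mask = rate_map.occupied & (np.nan_to_num(rate_map.rate) >= thresh) & (session_mean_rate > 0)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return np.empty((0, 2), dtype=int)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    return np.argwhere(labels == best)


def field_center(rate_map: RateMap, field_pixels: np.ndarray) -> tuple[float, float]:
    """Rate-weighted centroid (x, y) of a detected place field."""
    if field_pixels.shape[0] == 0:
        raise ValueError("empty field")
    rows = field_pixels[:, 0]
    cols = field_pixels[:, 1]
    w = np.nan_to_num(rate_map.rate[rows, cols])
    w = w / w.sum() if w.sum() > 0 else np.full(w.size, 1.0 / w.size)
    x = rate_map.origin[0] + (cols + 0.5) * rate_map.pixel_m
    y = rate_map.origin[1] + (rows + 0.5) * rate_map.pixel_m
    return float(np.sum(w * x)), float(np.sum(w * y))


def angular_concentration(
    spike_angles: np.ndarray,
    n_bins: int = ANGULAR_BINS,
    window_frac: float = ANGULAR_WINDOW_FRAC,
    threshold: float = ANGULAR_SPIKE_FRAC,
) -> tuple[float, bool]:
    """Max spike fraction in a circular sliding window of 40% of the track."""
    ang = np.mod(np.asarray(spike_angles, dtype=float), 2 * np.pi)
    if ang.size == 0:
        raise ValueError("need at least one spike")
    hist, _ = np.histogram(ang, bins=n_bins, range=(0, 2 * np.pi))
    w = int(round(window_frac * n_bins))
    wrapped = np.concatenate([hist, hist[: w - 1]])
    sums = np.convolve(wrapped, np.ones(w, dtype=int), mode="valid")[:n_bins]
    frac = float(sums.max() / ang.size)
    return frac, frac > threshold


@dataclass
class CellClassification:
    cell_id: int
    passed_rate_filters: bool
    spatial_coherence: float
    field_pixel_count: int
    angular_concentration_fraction: float
    peak_angle: float            # angular bin center of max firing rate
    cell_class: str              # classical_place | other_pyramidal | excluded


def _angles(positions: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    return np.mod(np.arctan2(positions[:, 1] - center[1],
                             positions[:, 0] - center[0]), 2 * np.pi)


def classify_cells(
    run_ensemble: SpikeEnsemble,
    trajectory: np.ndarray,
    post_ensemble: SpikeEnsemble,
    post_duration_s: float | None = None,
    pixel_m: float = 0.01,
) -> list[CellClassification]:
    """Classify every cell as classical place, other pyramidal, or excluded.

    Rate filters remove cells with <= 50 RUN spikes (too few for a rate map)
    or >= 10 Hz in POST (putative interneurons); surviving cells are
    classical place cells iff coherence, field-size, and angular
    concentration all pass.
    """
    t = trajectory[:, 0]
    total_time = float(t[-1] - t[0]) if t.size > 1 else 0.0
    if post_duration_s is None:
        pooled = post_ensemble.pooled_times()
        post_duration_s = float(pooled[-1] - pooled[0]) if pooled.size > 1 else 1.0
    cx = float(trajectory[:, 1].mean())
    cy = float(trajectory[:, 2].mean())

    out = []
    cells = sorted(set(run_ensemble.spike_times) | set(post_ensemble.spike_times))
    for cid in cells:
        run_spk = run_ensemble.spike_times.get(cid, np.empty(0))
        post_spk = post_ensemble.spike_times.get(cid, np.empty(0))
        post_rate = post_spk.size / post_duration_s
        ok = run_spk.size > MIN_RUN_SPIKES and post_rate < MAX_POST_RATE_HZ
        if not ok:
            out.append(CellClassification(cid, False, float("nan"), 0,
                                          float("nan"), float("nan"), "excluded"))
            continue
        rmap = build_rate_map(run_spk, trajectory, pixel_m=pixel_m)
        coherence = spatial_coherence(rmap)
        mean_rate = run_spk.size / total_time if total_time > 0 else 0.0
        field = detect_place_field(rmap, mean_rate)
        ang = _angles(spike_positions(run_spk, trajectory), (cx, cy))
        frac, conc_ok = angular_concentration(ang)
        hist, edges = np.histogram(ang, bins=ANGULAR_BINS, range=(0, 2 * np.pi))
        occ_ang = _angles(trajectory[:, 1:3], (cx, cy))
        occ_hist, _ = np.histogram(occ_ang, bins=ANGULAR_BINS, range=(0, 2 * np.pi))
        with np.errstate(divide="ignore", invalid="ignore"):
            ang_rate = np.where(occ_hist > 0, hist / occ_hist, 0.0)
        peak = float((edges[:-1] + edges[1:])[np.argmax(ang_rate)] / 2.0)
        is_place = (
            (not np.isnan(coherence)) and coherence > COHERENCE_THRESHOLD
            and field.shape[0] > MIN_FIELD_PIXELS
            and conc_ok
        )
        out.append(CellClassification(
            cid, True, coherence, int(field.shape[0]), frac, peak,
            "classical_place" if is_place else "other_pyramidal",
        ))
    return out


def define_run_sequence(
    classifications: list[CellClassification],
    direction: int = 1,
    anchor_angle: float = 0.0,
) -> tuple[int, ...] | None:
    """Classical place cells ordered by field-peak angle along the travel direction.

    ``direction=+1`` is counterclockwise (increasing angle).  Returns None
    when fewer than two classical place cells exist, in which case no RUN
    sequence (and no replay analysis) is defined for the session.
    """
    place = [c for c in classifications if c.cell_class == "classical_place"]
    if len(place) < 2:
        return None
    key = [np.mod(direction * (c.peak_angle - anchor_angle), 2 * np.pi) for c in place]
    order = np.argsort(key, kind="stable")
    return tuple(place[i].cell_id for i in order)
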