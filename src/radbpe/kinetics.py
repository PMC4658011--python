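"""Pharmacokinetic parametric maps from the 4-timepoint signal.

Three standard enhancement maps are computed per voxel from the baseline
signal S(t1) and the post-contrast course S(t2..t4):

* rate in   — (S_max − S(t1)) / (t_max − t1), in signal units per minute,
              where S_max is the maximum over the post-contrast timepoints and
              t_max its acquisition time.  Negative when the signal never
              exceeds baseline.
* PE        — percent enhancement, 100 · (S_max − S(t1)) / S(t1).
* SER       — signal enhancement ratio, (S_max − S(t1)) / (S(t4) − S(t1));
              equals 1 when the course peaks at t4 and exceeds 1 under
              washout kinetics.

The baseline is excluded from the maximum so flat or decreasing courses give
PE ≤ 0 rather than an indeterminate 0/0.  Voxels where a denominator is too
small (baseline below ``baseline_floor`` for PE, late-phase change below
``denom_floor`` for SER) are flagged invalid and excluded from texture
statistics rather than imputed.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyRegionError
from .volume import DceVolume, ParametricMaps


def _postcontrast_max(volume: DceVolume, mask: np.ndarray):
    """S_max over t2..t4 and its acquisition time, per masked voxel."""
    post = volume.data[mask][:, 1:]  # (n, 3)
    idx = np.argmax(post, axis=1)
    s_max = post[np.arange(len(post)), idx]
    t_max = np.asarray(volume.times[1:], dtype=float)[idx]
    return s_max, t_max


def _full(shape, values, mask):
    out = np.full(shape, np.nan)
    out[mask] = values
    return out


def compute_rate_in(volume: DceVolume, mask: np.ndarray) -> np.ndarray:
    """Contrast-material rate-in map (signal units / minute) over ``mask``."""
    mask = _check_mask(volume, mask)
    s1 = volume.data[mask][:, 0]
    s_max, t_max = _postcontrast_max(volume, mask)
    rate = (s_max - s1) / (t_max - volume.times[0])
    return _full(volume.grid_shape, rate, mask)


def compute_pe(volume: DceVolume, mask: np.ndarray, baseline_floor: float = 1.0):
    """Percent-enhancement map and its validity mask over ``mask``."""
    mask = _check_mask(volume, mask)
    s1 = volume.data[mask][:, 0]
    s_max, _ = _postcontrast_max(volume, mask)
    ok = s1 >= baseline_floor
    pe = np.full(len(s1), np.nan)
    pe[ok] = 100.0 * (s_max[ok] - s1[ok]) / s1[ok]
    valid = np.zeros(volume.grid_shape, dtype=bool)
    valid[mask] = ok
    return _full(volume.grid_shape, pe, mask), valid


def compute_ser(volume: DceVolume, mask: np.ndarray, denom_floor: float = 1.0):
    """Signal-enhancement-ratio map and its validity mask over ``mask``."""
    mask = _check_mask(volume, mask)
    s1 = volume.data[mask][:, 0]
    s4 = volume.data[mask][:, 3]
    s_max, _ = _postcontrast_max(volume, mask)
    denom = s4 - s1
    ok = np.abs(denom) >= denom_floor
    ser = np.full(len(s1), np.nan)
    ser[ok] = (s_max[ok] - s1[ok]) / denom[ok]
    valid = np.zeros(volume.grid_shape, dtype=bool)
    valid[mask] = ok
    return _full(volume.grid_shape, ser, mask), valid


def _check_mask(volume: DceVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.grid_shape:
        raise EmptyRegionError("mask shape does not match the volume grid")
    if not mask.any():
        raise EmptyRegionError("kinetics mask is empty")
    return mask


def compute_maps(
    volume: DceVolume,
    mask: np.ndarray,
    baseline_floor: float = 1.0,
    denom_floor: float = 1.0,
) -> ParametricMaps:
    """All three parametric maps over ``mask`` (typically the breast)."""
    mask = _check_mask(volume, mask)
    rate = compute_rate_in(volume, mask)
    pe, pe_valid = compute_pe(volume, mask, baseline_floor)
    ser, ser_valid = compute_ser(volume, mask, denom_floor)
    return ParametricMaps(
        maps={"rate in": rate, "PE": pe, "SER": ser},
        valid={"rate in": mask.copy(), "PE": pe_valid, "SER": ser_valid},
        mask=mask,
    )
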