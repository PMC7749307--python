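"""Order-parameter summaries, band geometry and regime classification.

Turns field snapshots (``rho``, ``f1``, ``f2`` on a periodic grid) and
trajectories into scalar diagnostics: global order amplitudes, density
contrast, band masks and orientations, and regime labels including the
detection of nematic-polar coexistence (polar order building up inside
nematic bands and interconverting with them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "RegimeLabel",
    "EventLog",
    "global_order",
    "band_geometry",
    "classify_trajectory",
]

#: local polar-presence threshold on |f1|/rho (well above the noise floor,
#: well below saturated polar order)
POLAR_PRESENCE = 0.05
#: density contrast (max rho / mean rho) above which a snapshot is "banded"
BAND_CONTRAST = 1.3
#: mean normalized order above which a uniform state counts as ordered
UNIFORM_ORDER = 0.05


@dataclass
class RegimeLabel:
    """A regime label with the scalar evidence used to assign it."""

    label: str  # disordered | uniform nematic | uniform polar | nematic bands
    #             | polar waves | nematic-polar coexistence | unresolved
    evidence: dict = field(default_factory=dict)


@dataclass
class EventLog:
    """Timestamped pattern events (monotone in time)."""

    events: list = field(default_factory=list)  # (t, kind) tuples

    def add(self, t: float, kind: str):
        if self.events and t < self.events[-1][0]:
            raise ValueError("events must be monotone in time")
        self.events.append((float(t), kind))

    def of_kind(self, kind: str):
        return [e for e in self.events if e[1] == kind]


def global_order(snapshot: dict) -> tuple:
    """``(mean |f1|/rho_bar, mean |f2|/rho_bar, max rho / rho_bar)``."""
    rho = np.asarray(snapshot["rho"], dtype=float)
    rho_bar = float(np.mean(rho))
    if rho_bar <= 0:
        raise ValueError("snapshot has non-positive mean density")
    p1 = float(np.mean(np.abs(snapshot["f1"]))) / rho_bar
    p2 = float(np.mean(np.abs(snapshot["f2"]))) / rho_bar
    return p1, p2, float(np.max(rho)) / rho_bar


def _structure_tensor_angle(rho: np.ndarray, mask: np.ndarray, smooth: float = 2.0):
    """Band orientation (angle of the along-band axis, mod pi) from the
    intensity structure tensor averaged over the mask."""
    gx = ndimage.gaussian_filter(rho, smooth, order=(0, 1), mode="wrap")
    gy = ndimage.gaussian_filter(rho, smooth, order=(1, 0), mode="wrap")
    jxx = float(np.sum(gx[mask] ** 2))
    jyy = float(np.sum(gy[mask] ** 2))
    jxy = float(np.sum((gx * gy)[mask]))
    # eigenvector of the smaller eigenvalue = direction of least variation
    theta_normal = 0.5 * np.arctan2(2 * jxy, jxx - jyy)  # larger-eigenvalue axis
    return theta_normal + np.pi / 2.0, theta_normal


def _angle_diff_mod(a: float, b: float, period: float) -> float:
    d = (a - b) % period
    return min(d, period - d)


def band_geometry(snapshot: dict, smooth: float = 2.0,
                  contrast_floor: float = BAND_CONTRAST) -> Optional[dict]:
    """Segment high-density bands and measure their geometry.

    Returns None when the density contrast is below ``contrast_floor``.
    Otherwise returns the band mask, the along-band direction (from the
    density structure tensor), the mean nematic director inside the bands
    (``arg(f2)/2``), the director-vs-band angle (mod pi), the polar
    direction (``arg(f1)``) where polar order is present, and its angle to
    the band normal.
    """
    rho = np.asarray(snapshot["rho"], dtype=float)
    rho_bar = float(np.mean(rho))
    if np.max(rho) / rho_bar < contrast_floor:
        return None
    thr = 0.5 * (rho_bar + np.max(rho))
    mask = rho > thr
    if not np.any(mask):
        return None
    along, normal = _structure_tensor_angle(rho, mask, smooth)
    f2 = np.asarray(snapshot["f2"])
    w2 = np.abs(f2[mask])
    director = 0.5 * np.angle(np.sum(f2[mask]))  # amplitude-weighted mean, mod pi
    f1 = np.asarray(snapshot["f1"])
    polar_mask = mask & (np.abs(f1) / np.maximum(rho, 1e-300) > POLAR_PRESENCE)
    polar_dir = float(np.angle(np.sum(f1[polar_mask]))) if np.any(polar_mask) else None
    out = {
        "mask": mask,
        "band_direction": float(along % np.pi),
        "band_normal": float(normal % np.pi),
        "director": float(director % np.pi),
        "director_band_angle": _angle_diff_mod(director, along, np.pi),
        "polar_fraction": float(np.mean(polar_mask[mask])) if np.any(mask) else 0.0,
        "polar_direction": polar_dir,
    }
    if polar_dir is not None:
        out["polar_front_angle"] = _angle_diff_mod(polar_dir, normal, np.pi)
    return out


def _snapshot_features(snapshot: dict) -> dict:
    p1, p2, contrast = global_order(snapshot)
    geo = band_geometry(snapshot)
    rho = np.asarray(snapshot["rho"], dtype=float)
    f1 = np.asarray(snapshot["f1"])
    polar_frac = float(np.mean(np.abs(f1) / np.maximum(rho, 1e-300) > POLAR_PRESENCE))
    return {"t": snapshot.get("t", np.nan), "p1": p1, "p2": p2,
            "contrast": contrast, "banded": geo is not None,
            "band_polar_fraction": geo["polar_fraction"] if geo else 0.0,
            "polar_fraction": polar_frac}


def classify_trajectory(trajectory, window: float = 0.5,
                        min_snapshots: int = 5) -> tuple:
    """Label a trajectory and log its pattern events.

    The label is computed from time-averaged diagnostics over the last
    ``window`` fraction of the trajectory.  "nematic-polar coexistence"
    requires band-like high-density structures together with local polar
    order inside them (simultaneously or alternating) within the analysis
    window.  Events: band-formation (contrast crosses the band threshold),
    local-polar-onset (polar fraction inside bands crosses the presence
    threshold upward), wave-detachment / band-reformation (the in-band
    polar fraction collapsing and recovering).
    """
    feats = [_snapshot_features(s) for s in trajectory]
    if len(feats) < min_snapshots:
        return RegimeLabel("unresolved", {"reason": "trajectory too short"}), EventLog()

    log = EventLog()
    banded_prev, polar_prev = False, False
    for f in feats:
        t = f["t"]
        if f["banded"] and not banded_prev:
            log.add(t, "band-formation")
        in_band_polar = f["banded"] and f["band_polar_fraction"] > 0.1
        if in_band_polar and not polar_prev:
            log.add(t, "local-polar-onset" if not polar_prev else "polar")
        if polar_prev and not in_band_polar:
            log.add(t, "wave-detachment" if f["banded"] else "band-dissolution")
        if f["banded"] and polar_prev and not in_band_polar:
            log.add(t, "band-reformation")
        banded_prev, polar_prev = f["banded"], in_band_polar

    n0 = int(len(feats) * (1.0 - window))
    win = feats[n0:]
    p1 = float(np.mean([f["p1"] for f in win]))
    p2 = float(np.mean([f["p2"] for f in win]))
    contrast = float(np.mean([f["contrast"] for f in win]))
    banded_frac = float(np.mean([f["banded"] for f in win]))
    polar_in_band = float(np.mean([f["band_polar_fraction"] for f in win]))
    any_polar = float(np.mean([f["band_polar_fraction"] > 0.1 for f in win]))
    evidence = {"p1": p1, "p2": p2, "contrast": contrast,
                "banded_frac": banded_frac, "polar_in_band": polar_in_band,
                "onsets": len(log.of_kind("local-polar-onset"))}

    if banded_frac < 0.5:
        if p1 > UNIFORM_ORDER:
            label = "uniform polar"
        elif p2 > UNIFORM_ORDER:
            label = "uniform nematic"
        else:
            label = "disordered"
    else:
        polar_always = any_polar > 0.9 and polar_in_band > 0.5
        polar_sometimes = any_polar > 0.05 or evidence["onsets"] > 0
        if polar_always and p1 > p2:
            label = "polar waves"
        elif polar_sometimes:
            label = "nematic-polar coexistence"
        else:
            label = "nematic bands"
    return RegimeLabel(label, evidence), log
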