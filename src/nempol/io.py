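"""Snapshot containers on disk (HDF5) and CSV sidecars."""

from __future__ import annotations

import numpy as np

__all__ = ["save_trajectory", "load_trajectory"]


def save_trajectory(path, snapshots, meta: dict | None = None) -> None:
    """Write a list of ``{t, rho, f1, f2}`` snapshots to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        if meta:
            for k, v in meta.items():
                f.attrs[k] = v
        for i, s in enumerate(snapshots):
            g = f.create_group(f"snap_{i:05d}")
            g.attrs["t"] = s["t"]
            g.create_dataset("rho", data=np.asarray(s["rho"], dtype=float))
            g.create_dataset("f1", data=np.asarray(s["f1"], dtype=complex))
            g.create_dataset("f2", data=np.asarray(s["f2"], dtype=complex))


def load_trajectory(path):
    """Read a trajectory written by :func:`save_trajectory`."""
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f.keys() if k.startswith("snap_")):
            g = f[name]
            out.append({"t": float(g.attrs["t"]), "rho": g["rho"][...],
                        "f1": g["f1"][...], "f2": g["f2"][...]})
        meta = dict(f.attrs)
    return out, meta
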