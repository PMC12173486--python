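"""Spatiotemporal displacement maps and their on-disk containers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpatioTemporalMap"]


@dataclass
class SpatioTemporalMap:
    """Transverse displacement sampled over position (rows) and time (cols).

    ``u[i, j]`` is the displacement (m) at position ``i * dx`` along the
    tissue and time ``j * dt``.  ``meta`` carries provenance (subtendon,
    cohort, twist, applied stress, ...).
    """

    u: np.ndarray
    dx: float  # m
    dt: float  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2:
            raise ValueError("map must be rectangular (2-D)")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")

    @property
    def n_positions(self) -> int:
        return self.u.shape[0]

    @property
    def n_times(self) -> int:
        return self.u.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.n_positions) * self.dx

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) * self.dt

    # -- CSV ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> Path:
        """Plain-text container: ``#`` header lines carry dx/dt/meta, then a
        position-by-time matrix, one row per position."""
        path = Path(path)
        header = [
            "# tendonwave spatiotemporal map",
            f"# dx_m={self.dx!r}",
            f"# dt_s={self.dt!r}",
            f"# meta={json.dumps(self.meta, sort_keys=True)}",
        ]
        body = "\n".join(
            ",".join(f"{v:.12e}" for v in row) for row in self.u
        )
        path.write_text("\n".join(header) + "\n" + body + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpatioTemporalMap":
        path = Path(path)
        dx = dt = None
        meta: dict = {}
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("# ")
                if stripped.startswith("dx_m="):
                    dx = float(stripped[5:])
                elif stripped.startswith("dt_s="):
                    dt = float(stripped[5:])
                elif stripped.startswith("meta="):
                    meta = json.loads(stripped[5:])
                continue
            rows.append([float(v) for v in line.split(",")])
        if dx is None or dt is None:
            raise ValueError(f"{path}: missing dx_m/dt_s header lines")
        return cls(u=np.array(rows), dx=dx, dt=dt, meta=meta)

    # -- HDF5 --------------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> Path:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("u", data=self.u)
            ds.attrs["dx_m"] = self.dx
            ds.attrs["dt_s"] = self.dt
            ds.attrs["meta"] = json.dumps(self.meta, sort_keys=True)
        return path

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SpatioTemporalMap":
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["u"]
            return cls(
                u=ds[...],
                dx=float(ds.attrs["dx_m"]),
                dt=float(ds.attrs["dt_s"]),
                meta=json.loads(ds.attrs["meta"]),
            )

    @classmethod
    def load(cls, path: str | Path) -> "SpatioTemporalMap":
        """Dispatch on file suffix (.csv or .h5/.hdf5)."""
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            return cls.from_hdf5(path)
        return cls.from_csv(path)
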