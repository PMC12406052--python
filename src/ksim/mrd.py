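"""Self-contained ISMRMRD-style raw-data container (HDF5 layout).

One acquisition record per shot, stored as parallel datasets indexed by a
global scan counter:

==================  =========================  =====================================
dataset             shape                      content
==================  =========================  =====================================
``data``            (n_shots, L, N) c8         interleaved complex float32 samples
``trajectory``      (n_shots, N, 3) f4         normalised k-space locations
``times``           (N,) f8                    echo-centred sample times (ms)
``frame_index``     (n_shots,) i4              volume each shot belongs to
``kz_plane``        (n_shots,) i4              plane index (-1 if not stacked)
``shot_time_s``     (n_shots,) f8              absolute echo time of the shot (s)
==================  =========================  =====================================

The run header (grid shape, sequence parameters, seed, ...) is a JSON
string in the root attribute ``header``.  Timestamps are disabled so a
rerun with the same seed produces a byte-identical payload.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

__all__ = ["MrdWriter", "MrdRun", "read_mrd"]


class MrdWriter:
    """Streaming writer: shots are appended one at a time, in scan order."""

    def __init__(self, path, header: dict, n_shots: int, n_coils: int, n_samples: int):
        self.path = str(path)
        self._fh = h5py.File(self.path, "w", track_order=False)
        self._fh.attrs["header"] = json.dumps(header, sort_keys=True)
        kw = dict(track_times=False)
        self._data = self._fh.create_dataset(
            "data", (n_shots, n_coils, n_samples), dtype=np.complex64, **kw
        )
        self._traj = self._fh.create_dataset(
            "trajectory", (n_shots, n_samples, 3), dtype=np.float32, **kw
        )
        self._times = self._fh.create_dataset("times", (n_samples,), dtype=np.float64, **kw)
        self._frame = self._fh.create_dataset("frame_index", (n_shots,), dtype=np.int32, **kw)
        self._plane = self._fh.create_dataset("kz_plane", (n_shots,), dtype=np.int32, **kw)
        self._t_abs = self._fh.create_dataset("shot_time_s", (n_shots,), dtype=np.float64, **kw)
        self._count = 0
        self.n_shots = n_shots

    def append(self, data, trajectory, times, frame_index, kz_plane, shot_time_s):
        i = self._count
        if i >= self.n_shots:
            raise RuntimeError("container is full")
        self._data[i] = np.asarray(data, dtype=np.complex64)
        self._traj[i] = np.asarray(trajectory, dtype=np.float32)
        if i == 0:
            self._times[:] = times
        self._frame[i] = frame_index
        self._plane[i] = -1 if kz_plane is None else kz_plane
        self._t_abs[i] = shot_time_s
        self._count += 1

    def close(self):
        self._fh.attrs["n_written"] = self._count
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class MrdRun:
    """In-memory view of a container produced by :class:`MrdWriter`."""

    def __init__(self, path):
        with h5py.File(path, "r") as fh:
            self.header = json.loads(fh.attrs["header"])
            self.data = fh["data"][...]
            self.trajectory = fh["trajectory"][...].astype(np.float64)
            self.times = fh["times"][...]
            self.frame_index = fh["frame_index"][...]
            self.kz_plane = fh["kz_plane"][...]
            self.shot_time_s = fh["shot_time_s"][...]

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.max()) + 1

    def frame_shots(self, t: int) -> np.ndarray:
        return np.nonzero(self.frame_index == t)[0]

    def frame_time_s(self, t: int) -> float:
        """Timestamp of a frame: the echo time of its first shot."""
        return float(self.shot_time_s[self.frame_shots(t)[0]])


def read_mrd(path) -> MrdRun:
    return MrdRun(path)
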