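"""Reading and writing of the pipeline's file formats.

Time series travel as 2-column CSV (time_s, value) or as an HDF5 dataset
with a ``rate`` attribute; avalanche sizes as 1-column CSV; spatial filter
sets and CSDs as HDF5 groups (/filters/session_i/source_r, /csd/session_i);
phase maps as CSV with axis metadata in the header.
"""

from __future__ import annotations

import numpy as np

from .crosnet import PhaseMap
from .synthgen import RNG_ALGORITHM
from .types import AvalancheSizes, TimeSeries

__all__ = [
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_timeseries_h5",
    "read_timeseries_h5",
    "write_sizes_csv",
    "read_sizes_csv",
    "write_sensor_set_h5",
    "read_sensor_set_h5",
    "write_events_csv",
    "write_voxel_maps_h5",
    "read_voxel_maps_h5",
    "write_phasemap_csv",
]


def write_timeseries_csv(ts: TimeSeries, path) -> None:
    data = np.column_stack([ts.times, ts.samples])
    np.savetxt(path, data, delimiter=",", header="time_s,value", comments="")


def read_timeseries_csv(path) -> TimeSeries:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, x = data[:, 0], data[:, 1]
    rate = 1.0 / np.median(np.diff(t))
    return TimeSeries(samples=x, rate=rate, t0=float(t[0]))


def write_timeseries_h5(ts: TimeSeries, path, dataset: str = "signal") -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        d = fh.create_dataset(dataset, data=ts.samples)
        d.attrs["rate"] = ts.rate
        d.attrs["t0"] = ts.t0
        d.attrs["rng"] = RNG_ALGORITHM


def read_timeseries_h5(path, dataset: str = "signal") -> TimeSeries:
    import h5py

    with h5py.File(path, "r") as fh:
        d = fh[dataset]
        return TimeSeries(samples=d[...], rate=float(d.attrs["rate"]), t0=float(d.attrs.get("t0", 0.0)))


def write_sizes_csv(sizes: AvalancheSizes, path) -> None:
    np.savetxt(path, sizes.sizes, fmt="%d", header="size", comments="")


def read_sizes_csv(path) -> AvalancheSizes:
    return AvalancheSizes(sizes=np.loadtxt(path, skiprows=1, dtype=np.int64, ndmin=1))


def write_sensor_set_h5(filters: np.ndarray, csds: np.ndarray, path, orientations=None) -> None:
    """HDF5 layout: /filters/session_i/source_r (sensors x 3), /csd/session_i."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i in range(filters.shape[0]):
            for r in range(filters.shape[1]):
                fh.create_dataset(f"filters/session_{i}/source_{r}", data=filters[i, r])
            fh.create_dataset(f"csd/session_{i}", data=csds[i])
        if orientations is not None:
            fh.create_dataset("true_orientations", data=orientations)


def read_sensor_set_h5(path) -> tuple[np.ndarray, np.ndarray]:
    import h5py

    with h5py.File(path, "r") as fh:
        sessions = sorted(fh["filters"], key=lambda s: int(s.split("_")[1]))
        filters = []
        for s in sessions:
            sources = sorted(fh["filters"][s], key=lambda r: int(r.split("_")[1]))
            filters.append([fh["filters"][s][r][...] for r in sources])
        csds = [fh["csd"][s][...] for s in sessions]
    return np.asarray(filters), np.asarray(csds)


def write_events_csv(raster, path) -> None:
    """Spike raster as an event list CSV (time_ms, unit_id)."""
    time_ms, unit = raster.events()
    np.savetxt(
        path,
        np.column_stack([time_ms, unit]),
        fmt=["%.3f", "%d"],
        delimiter=",",
        header="time_ms,unit_id",
        comments="",
    )


def write_voxel_maps_h5(maps, path) -> None:
    """Paired voxel maps plus adjacency as HDF5 (/cond_a, /cond_b, /adjacency)."""
    import h5py
    from scipy import sparse

    adj = sparse.coo_matrix(maps.adjacency)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cond_a", data=maps.cond_a)
        fh.create_dataset("cond_b", data=maps.cond_b)
        fh.create_dataset("adjacency/row", data=adj.row)
        fh.create_dataset("adjacency/col", data=adj.col)
        fh.attrs["n_voxels"] = maps.n_voxels


def read_voxel_maps_h5(path):
    import h5py
    from scipy import sparse

    from .types import PairedVoxelMaps

    with h5py.File(path, "r") as fh:
        a = fh["cond_a"][...]
        b = fh["cond_b"][...]
        n_vox = int(fh.attrs["n_voxels"])
        row = fh["adjacency/row"][...]
        col = fh["adjacency/col"][...]
    adj = sparse.csr_matrix((np.ones(row.size, dtype=bool), (row, col)), shape=(n_vox, n_vox))
    return PairedVoxelMaps(cond_a=a, cond_b=b, adjacency=adj)


def write_phasemap_csv(pm: PhaseMap, path) -> None:
    """Long-format CSV: x, y, kappa, alpha, rate_hz with labelled header."""
    xx, yy = np.meshgrid(pm.x_values, pm.y_values)
    data = np.column_stack(
        [xx.ravel(), yy.ravel(), pm.kappa.ravel(), pm.alpha.ravel(), pm.rate_hz.ravel()]
    )
    header = f"{pm.x_label},{pm.y_label},kappa,alpha,rate_hz"
    np.savetxt(path, data, delimiter=",", header=header, comments="")
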