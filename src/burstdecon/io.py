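"""Reading and writing the package's on-disk formats.

Traces travel as tidy CSV (``allele_id, bin, t_min, activity_cu``) or as
HDF5 groups; posterior samples are stored bit-packed in HDF5 with the
sampling metadata needed to reproduce them.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .deconvolution import ActivityTrace, PosteriorSamples

__all__ = [
    "read_traces_csv",
    "write_traces_csv",
    "read_traces_hdf5",
    "write_traces_hdf5",
    "write_posteriors_hdf5",
    "read_posteriors_hdf5",
    "read_dual_color_csv",
    "read_rate_table_csv",
    "read_counts_matrix",
]


def read_dual_color_csv(path: str | Path) -> np.ndarray:
    """Two-column (x, y) activity pairs for the dual-color noise fit."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns of paired activities")
    return df.iloc[:, :2].to_numpy(dtype=float)


def read_rate_table_csv(path: str | Path):
    """Tabulated telegraph rates: columns ``t_min, k_on, k_off, k``."""
    df = pd.read_csv(path)
    missing = {"t_min", "k_on", "k_off", "k"} - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    df = df.sort_values("t_min").reset_index(drop=True)
    return (
        df["t_min"].to_numpy(float),
        df["k_on"].to_numpy(float),
        df["k_off"].to_numpy(float),
        df["k"].to_numpy(float),
    )


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x cell integer count matrix from CSV or MatrixMarket."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense(), dtype=int)
        return pd.DataFrame(mat)
    return pd.read_csv(path, index_col=0).astype(int)


def write_traces_csv(traces: list[ActivityTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.allele_id, tr.bin_label, t, v))
    pd.DataFrame(
        rows, columns=["allele_id", "bin", "t_min", "activity_cu"]
    ).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[ActivityTrace]:
    df = pd.read_csv(path)
    out = []
    for (aid, b), grp in df.groupby(["allele_id", "bin"], sort=False, dropna=False):
        grp = grp.sort_values("t_min")
        out.append(
            ActivityTrace(
                times=grp["t_min"].to_numpy(),
                values=grp["activity_cu"].to_numpy(),
                allele_id=str(aid),
                bin_label="" if pd.isna(b) else str(b),
            )
        )
    return out


def write_traces_hdf5(traces: list[ActivityTrace], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for i, tr in enumerate(traces):
            g = f.create_group(f"trace_{i:05d}")
            g.create_dataset("times", data=tr.times)
            g.create_dataset("values", data=tr.values)
            g.attrs["allele_id"] = tr.allele_id
            g.attrs["bin"] = tr.bin_label


def read_traces_hdf5(path: str | Path) -> list[ActivityTrace]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                ActivityTrace(
                    times=g["times"][...],
                    values=g["values"][...],
                    allele_id=str(g.attrs.get("allele_id", key)),
                    bin_label=str(g.attrs.get("bin", "")),
                )
            )
    return out


def write_posteriors_hdf5(
    posteriors: list[PosteriorSamples], path: str | Path
) -> None:
    with h5py.File(path, "w") as f:
        for i, ps in enumerate(posteriors):
            g = f.create_group(f"posterior_{i:05d}")
            g.create_dataset(
                "configs_packed",
                data=np.packbits(ps.configs, axis=1),
                compression="gzip",
            )
            g.create_dataset("proposal_probs", data=ps.proposal_probs)
            g.attrs["n_fine"] = ps.configs.shape[1]
            g.attrs["acceptance_rate"] = ps.acceptance_rate
            g.attrs["dt_fine"] = ps.dt_fine
            g.attrs["dt"] = ps.dt
            g.attrs["n_t"] = ps.n_t
            g.attrs["seed"] = ps.seed


def read_posteriors_hdf5(path: str | Path) -> list[PosteriorSamples]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            n_fine = int(g.attrs["n_fine"])
            configs = np.unpackbits(
                g["configs_packed"][...], axis=1, count=n_fine
            )
            out.append(
                PosteriorSamples(
                    configs=configs,
                    proposal_probs=g["proposal_probs"][...],
                    acceptance_rate=float(g.attrs["acceptance_rate"]),
                    dt_fine=float(g.attrs["dt_fine"]),
                    dt=float(g.attrs["dt"]),
                    n_t=int(g.attrs["n_t"]),
                    seed=int(g.attrs["seed"]),
                )
            )
    return out
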