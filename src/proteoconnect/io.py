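"""Tab-delimited readers/writers for all pipeline inputs and outputs."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ConnectivityMatrix,
    ProteinMatrix,
    ROIGeometry,
    ROITimeSeries,
    StreamlineTable,
    validate_sample_meta,
)


def write_protein_matrix(m: ProteinMatrix, path: str | Path,
                         provenance: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# proteoconnect {provenance}\n")
        m.values.to_csv(fh, sep="\t", index_label="protein_id", na_rep="NA")


def read_protein_matrix(path: str | Path, is_log2: bool | None = None
                        ) -> ProteinMatrix:
    path = Path(path)
    flagged_log2 = False
    with open(path) as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            flagged_log2 = "log2" in first
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip,
                     na_values=["NA"])
    return ProteinMatrix(df, is_log2=flagged_log2 if is_log2 is None else is_log2)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_meta(meta)


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    conn.to_dataframe().to_csv(path, sep="\t", index_label="roi")


def read_connectivity(path: str | Path, kind: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(kind=kind, values=df.to_numpy(dtype=float),
                              labels=tuple(df.index))


def write_timeseries_dir(subjects: list[ROITimeSeries], out_dir: str | Path
                         ) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ts in subjects:
        df = pd.DataFrame(ts.values, columns=list(ts.labels))
        df.to_csv(out_dir / f"{ts.subject_id}.tsv", sep="\t", index=False)


def read_timeseries_dir(in_dir: str | Path) -> list[ROITimeSeries]:
    in_dir = Path(in_dir)
    subjects = []
    for name in sorted(os.listdir(in_dir)):
        if not name.endswith(".tsv"):
            continue
        df = pd.read_csv(in_dir / name, sep="\t")
        subjects.append(ROITimeSeries(subject_id=name[:-4],
                                      values=df.to_numpy(dtype=float),
                                      labels=tuple(df.columns)))
    if not subjects:
        raise ValueError(f"no time-series files found in {in_dir}")
    return subjects


def write_streamlines(st: StreamlineTable, counts_path: str | Path,
                      areas_path: str | Path) -> None:
    pd.DataFrame(st.counts, index=list(st.labels),
                 columns=list(st.labels)).to_csv(counts_path, sep="\t",
                                                 index_label="roi")
    st.areas.rename("area_mm2").to_csv(areas_path, sep="\t",
                                       index_label="roi")


def read_streamlines(counts_path: str | Path, areas_path: str | Path
                     ) -> StreamlineTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    areas = pd.read_csv(areas_path, sep="\t", index_col=0)["area_mm2"]
    return StreamlineTable(counts=counts.to_numpy(dtype=float), areas=areas,
                           labels=tuple(counts.index))


def write_geometry(geom: ROIGeometry, path: str | Path) -> None:
    df = pd.DataFrame({
        "roi_id": list(geom.labels),
        "hemisphere": list(geom.hemispheres),
        "x": geom.coords[:, 0], "y": geom.coords[:, 1], "z": geom.coords[:, 2],
        "area_mm2": geom.areas,
    })
    df.to_csv(path, sep="\t", index=False)


def read_geometry(path: str | Path) -> ROIGeometry:
    df = pd.read_csv(path, sep="\t")
    return ROIGeometry(labels=tuple(df["roi_id"]),
                       coords=df[["x", "y", "z"]].to_numpy(dtype=float),
                       areas=df["area_mm2"].to_numpy(dtype=float),
                       hemispheres=tuple(df["hemisphere"]))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mrna(mrna: pd.DataFrame, path: str | Path) -> None:
    mrna.to_csv(path, sep="\t", index_label="gene_id")


def read_mrna(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
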