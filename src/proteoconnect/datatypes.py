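"""Shared containers and region-label conventions.

The study system is a fixed panel of 13 language-related Brodmann areas
(BAs) sampled bilaterally, giving 26 regions of interest (ROIs).  All
matrices in the package use the canonical ROI order: the 13 left-hemisphere
labels followed by their right-hemisphere homologues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 13 language-related Brodmann areas, grouped by functional module:
#: Broca (BA44/45), Wernicke (BA22/21), Geschwind (BA39/40), primary
#: auditory cortex (BA41/42), ventral premotor (BA6), ventral sensorimotor
#: (BA4, BA312) plus BA37 and BA9.
REGIONS: tuple[str, ...] = (
    "BA44", "BA45", "BA22", "BA21", "BA39", "BA40", "BA41",
    "BA42", "BA6", "BA4", "BA312", "BA37", "BA9",
)

HEMISPHERES: tuple[str, str] = ("L", "R")

#: Canonical 26-ROI order: all left labels, then all right labels.
ROI_LABELS: tuple[str, ...] = tuple(f"{r}_L" for r in REGIONS) + tuple(
    f"{r}_R" for r in REGIONS
)

N_REGIONS = len(REGIONS)
N_ROIS = len(ROI_LABELS)


def roi_label(region: str, hemisphere: str) -> str:
    """Build the canonical ``BAxx_L``/``BAxx_R`` label."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return f"{region}_{hemisphere}"


def split_roi_label(label: str) -> tuple[str, str]:
    region, _, hemi = label.rpartition("_")
    if not region or hemi not in HEMISPHERES:
        raise ValueError(f"malformed ROI label {label!r}")
    return region, hemi


def homotopic_partner(label: str) -> str:
    """Label of the mirror-position homologue in the opposite hemisphere."""
    region, hemi = split_roi_label(label)
    return roi_label(region, "R" if hemi == "L" else "L")


@dataclass
class ProteinMatrix:
    """Protein abundance matrix, proteins x samples.

    ``values`` is indexed by unique protein identifiers (gene symbols) with
    one column per sample.  On the linear (LFQ intensity) scale, zero means
    "not detected"; on the log2 scale missing entries are NaN.
    """

    values: pd.DataFrame
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("protein identifiers must be unique")
        if not self.is_log2:
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr) < 0:
                raise ValueError("linear-scale intensities must be non-negative")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), self.is_log2)


REQUIRED_META_COLUMNS = ("sample_id", "donor", "region", "hemisphere")


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table (one row per sample).

    Requires columns sample_id/donor/region/hemisphere, recognised region
    labels, and a unique (donor, region, hemisphere) triple per row.
    """
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    bad_regions = set(meta["region"]) - set(REGIONS)
    if bad_regions:
        raise ValueError(f"unrecognised region labels: {sorted(bad_regions)}")
    bad_hemi = set(meta["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise ValueError(f"unrecognised hemisphere labels: {sorted(bad_hemi)}")
    if meta.duplicated(["donor", "region", "hemisphere"]).any():
        raise ValueError("(donor, region, hemisphere) must be unique")
    return meta


def group_labels(meta: pd.DataFrame) -> pd.Series:
    """Per-sample ROI group label (``BA22_L`` style), indexed by sample_id."""
    lab = meta["region"].astype(str) + "_" + meta["hemisphere"].astype(str)
    return pd.Series(lab.to_numpy(), index=meta["sample_id"].to_numpy())


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI connectivity.

    kind is one of ``fc`` (Pearson r, unit diagonal), ``sc_count``
    (streamline counts) or ``sc_density`` (counts per mm^2).
    """

    kind: str
    values: np.ndarray
    labels: tuple[str, ...] = ROI_LABELS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind == "fc":
            if np.nanmax(np.abs(v)) > 1 + 1e-9:
                raise ValueError("FC entries must lie in [-1, 1]")
        elif self.kind in ("sc_count", "sc_density"):
            if np.nanmin(v) < 0:
                raise ValueError("SC entries must be non-negative")
        else:
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def fisher_z(self) -> np.ndarray:
        """atanh-transformed values (FC only), clipped away from |r| = 1."""
        if self.kind != "fc":
            raise ValueError("Fisher z is defined for FC matrices")
        r = np.clip(self.values, -1 + 1e-7, 1 - 1e-7)
        return np.arctanh(r)


@dataclass
class ROITimeSeries:
    """One subject's ROI time series, T x n_rois, fixed ROI order."""

    subject_id: str
    values: np.ndarray
    labels: tuple[str, ...] = ROI_LABELS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be 2-D (T x ROIs)")
        if v.shape[0] < 2:
            raise ValueError("need at least two time points")
        if v.shape[1] != len(self.labels):
            raise ValueError("ROI count does not match labels")
        self.values = v


@dataclass
class StreamlineTable:
    """Symmetric streamline counts plus ROI surface areas (mm^2)."""

    counts: np.ndarray
    areas: pd.Series
    labels: tuple[str, ...] = ROI_LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("streamline count matrix must be square")
        if not np.allclose(c, c.T):
            raise ValueError("streamline counts must be symmetric")
        if c.min() < 0:
            raise ValueError("streamline counts must be non-negative")
        self.counts = c
        self.areas = self.areas.reindex(list(self.labels))
        if self.areas.isna().any():
            raise ValueError("missing surface area for some ROIs")
        if (self.areas <= 0).any():
            raise ValueError("surface areas must be positive")


@dataclass
class ROIGeometry:
    """ROI centroids on the unit sphere with surface areas.

    coords rows are unit-norm 3-vectors; right-hemisphere ROIs mirror their
    left partner through the x = 0 plane.
    """

    labels: tuple[str, ...]
    coords: np.ndarray
    areas: np.ndarray
    hemispheres: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coordinates must be n x 3")
        norms = np.linalg.norm(c, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("ROI coordinates must be unit-norm")
        if np.asarray(self.areas).min() <= 0:
            raise ValueError("surface areas must be positive")
        if self.hemispheres is None:
            self.hemispheres = tuple(
                split_roi_label(l)[1] if "_" in l else "L" for l in self.labels
            )
        self.coords = c
        self.areas = np.asarray(self.areas, dtype=float)

    @property
    def n_rois(self) -> int:
        return self.coords.shape[0]

    def hemisphere_subset(self, hemisphere: str) -> "ROIGeometry":
        """Geometry restricted to one hemisphere's ROIs."""
        sel = [i for i, h in enumerate(self.hemispheres) if h == hemisphere]
        if not sel:
            raise ValueError(f"no ROIs in hemisphere {hemisphere!r}")
        return ROIGeometry(
            labels=tuple(self.labels[i] for i in sel),
            coords=self.coords[sel],
            areas=self.areas[sel],
            hemispheres=tuple(self.hemispheres[i] for i in sel),
        )
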