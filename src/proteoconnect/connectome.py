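"""Functional and structural connectivity construction and summaries.

Subject FC is the Pearson correlation of ROI time series; group FC is the
Fisher-z mean across subjects (arithmetic-mean option available).  SC comes
in streamline counts and streamline density (counts divided by the mean of
the two ROI surface areas).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    ConnectivityMatrix,
    ROITimeSeries,
    StreamlineTable,
    homotopic_partner,
)

_CLIP = 1 - 1e-7


def subject_fc(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI time series (unit diagonal)."""
    v = ts.values
    if v.shape[0] <= 3:
        raise ValueError("need more than 3 time points")
    sd = v.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for ROI(s): {bad}")
    r = np.corrcoef(v, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(kind="fc", values=np.clip(r, -1, 1),
                              labels=ts.labels)


def group_fc(subject_fcs: list[ConnectivityMatrix],
             method: str = "fisher") -> ConnectivityMatrix:
    """Aggregate subject FC matrices.

    ``fisher`` (default): entrywise atanh -> mean -> tanh, with |r| = 1
    clipped just inside the open interval first; ``mean``: arithmetic mean.
    """
    if not subject_fcs:
        raise ValueError("need at least one subject")
    labels = subject_fcs[0].labels
    mats = []
    for fc in subject_fcs:
        if fc.labels != labels or fc.values.shape != subject_fcs[0].values.shape:
            raise ValueError("subject FC matrices must share shape and ROI order")
        mats.append(fc.values)
    stack = np.stack(mats)
    if method == "fisher":
        z = np.arctanh(np.clip(stack, -_CLIP, _CLIP))
        out = np.tanh(z.mean(axis=0))
    elif method == "mean":
        out = stack.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2
    return ConnectivityMatrix(kind="fc", values=out, labels=labels)


def node_strength(fc: ConnectivityMatrix, scope: str = "all") -> pd.Series:
    """Mean off-diagonal connectivity per ROI.

    scope='all' averages over every other ROI; scope='ipsilateral' restricts
    the partner set to the same hemisphere.
    """
    if scope not in ("all", "ipsilateral"):
        raise ValueError(f"unknown scope {scope!r}")
    labels = list(fc.labels)
    v = fc.values
    out = {}
    hemis = [l.rsplit("_", 1)[1] for l in labels]
    for i, lab in enumerate(labels):
        if scope == "all":
            sel = [j for j in range(len(labels)) if j != i]
        else:
            sel = [j for j in range(len(labels))
                   if j != i and hemis[j] == hemis[i]]
        out[lab] = v[i, sel].mean()
    return pd.Series(out)


def homotopic_summary(fc: ConnectivityMatrix
                      ) -> tuple[pd.Series, float]:
    """Homotopic FC values and the fraction of ROIs whose strongest partner
    is the contralateral homologue.

    Returns (r per left-hemisphere region against its right homologue,
    fraction over all ROIs).
    """
    labels = list(fc.labels)
    idx = {l: i for i, l in enumerate(labels)}
    v = fc.values
    homotopic = {}
    argmax_hits = 0
    for i, lab in enumerate(labels):
        partner = homotopic_partner(lab)
        if partner not in idx:
            raise ValueError(f"no homotopic partner for {lab}")
        j = idx[partner]
        if lab.endswith("_L"):
            homotopic[lab.rsplit("_", 1)[0]] = v[i, j]
        row = v[i].copy()
        row[i] = -np.inf
        if np.argmax(row) == j:
            argmax_hits += 1
    return pd.Series(homotopic), argmax_hits / len(labels)


def streamline_density(st: StreamlineTable) -> ConnectivityMatrix:
    """Streamline counts divided by the mean surface area of the pair."""
    areas = st.areas.to_numpy(dtype=float)
    denom = (areas[:, None] + areas[None, :]) / 2.0
    dens = st.counts / denom
    np.fill_diagonal(dens, 0.0)
    return ConnectivityMatrix(kind="sc_density", values=dens, labels=st.labels)


def streamline_count_matrix(st: StreamlineTable) -> ConnectivityMatrix:
    counts = st.counts.copy()
    np.fill_diagonal(counts, 0.0)
    return ConnectivityMatrix(kind="sc_count", values=counts, labels=st.labels)
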