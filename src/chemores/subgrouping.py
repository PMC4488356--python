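"""Cluster-3.0-style hierarchical subgrouping of patients.

The significant-gene submatrix is median-centered (genes then samples, one
pass each), samples are compared by centered Pearson correlation distance
``1 - r``, and average-linkage (UPGMA) agglomeration yields the dendrogram.
The tree is cut into ``k`` subgroups; when ``k`` is not given it is chosen
by maximal mean silhouette on the correlation distance over k = 2..10.
Subgroups with an NOCR majority are flagged resistant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .errors import InputError

__all__ = [
    "SubgroupModel",
    "median_center",
    "correlation_distance",
    "hierarchical_cluster",
    "cut_clusters",
    "summarize_subgroups",
]


@dataclass
class SubgroupModel:
    assignment: pd.Series  # sample_id -> subgroup index in 1..k
    k: int
    linkage: np.ndarray | None = None
    summary: pd.DataFrame | None = None
    resistant_subgroups: list[int] = field(default_factory=list)

    def samples_of(self, subgroup: int) -> list[str]:
        return self.assignment.index[self.assignment == subgroup].tolist()


def median_center(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract gene-row medians, then sample-column medians (one pass each)."""
    if m.size == 0:
        raise InputError("median_center: empty matrix")
    out = m.sub(m.median(axis=1), axis=0)
    return out.sub(out.median(axis=0), axis=1)


def correlation_distance(m: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample distance 1 - Pearson r between sample columns."""
    if m.shape[1] < 2:
        raise InputError("correlation_distance: need >= 2 samples")
    sds = m.std(axis=0, ddof=0)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise InputError(f"constant sample column(s): {constant}")
    D = 1.0 - np.corrcoef(m.to_numpy(dtype=float).T)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    return pd.DataFrame(D, index=m.columns, columns=m.columns)


def hierarchical_cluster(d: pd.DataFrame) -> np.ndarray:
    """UPGMA (average linkage) merge history for a precomputed distance matrix."""
    A = np.asarray(d, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise InputError("distance matrix must be symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=1e-10):
        raise InputError("distance matrix must have a zero diagonal")
    if (A < -1e-12).any():
        raise InputError("distance matrix must be nonnegative")
    return linkage(squareform(A, checks=False), method="average")


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (stable identity)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cut_clusters(
    tree: np.ndarray,
    sample_ids,
    k: int | None = None,
    distance: pd.DataFrame | None = None,
    max_k: int = 10,
) -> SubgroupModel:
    """Cut the dendrogram into k subgroups (silhouette-selected k if unset)."""
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if k is not None:
        if not 1 <= k <= n:
            raise InputError(f"k={k} outside 1..{n}")
    else:
        if distance is None:
            raise InputError("auto-k requires the distance matrix for silhouette scoring")
        D = distance.loc[sample_ids, sample_ids].to_numpy()
        best_k, best_s = None, -np.inf
        for kk in range(2, min(max_k, n - 1) + 1):
            labels = fcluster(tree, kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            s = silhouette_score(D, labels, metric="precomputed")
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        if best_k is None:
            raise InputError("auto-k: no valid k in range")
        k = best_k

    labels = np.ones(n, dtype=int) if k == 1 else fcluster(tree, k, criterion="maxclust")
    labels = _canonical_labels(labels)
    assignment = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="subgroup")
    return SubgroupModel(assignment=assignment, k=int(assignment.max()), linkage=tree)


def summarize_subgroups(model: SubgroupModel, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-subgroup size, CR/NOCR counts, dominant labels, and resistant flag.

    A subgroup is flagged resistant when NOCR strictly outnumbers CR; a tie
    leaves it sensitive with a warning.  Dominant-label ties break
    lexicographically (flagged in the ``dominant_tie`` column).  The summary
    and the resistant subgroup list are stored on the model.
    """
    missing = [s for s in model.assignment.index if s not in ann.index]
    if missing:
        raise InputError(f"samples without annotation: {missing[:5]}")
    rows = []
    for sub in sorted(model.assignment.unique()):
        samples = model.samples_of(sub)
        resp = ann.loc[samples, "response"]
        n_cr = int((resp == "CR").sum())
        n_nocr = int((resp == "NOCR").sum())
        if n_cr == n_nocr:
            warnings.warn(f"subgroup {sub}: CR/NOCR tie, flagged sensitive", RuntimeWarning)
        counts = resp.value_counts()
        top = counts[counts == counts.max()].index.sort_values()
        dominant_resp = top[0]
        resp_tie = len(top) > 1
        if "subtype" in ann.columns and (ann.loc[samples, "subtype"] != "").any():
            sc = ann.loc[samples, "subtype"].replace("", np.nan).dropna().value_counts()
            st_top = sc[sc == sc.max()].index.sort_values()
            dominant_subtype = st_top[0]
            subtype_tie = len(st_top) > 1
        else:
            dominant_subtype, subtype_tie = "", False
        rows.append(
            {
                "subgroup": int(sub),
                "size": len(samples),
                "n_cr": n_cr,
                "n_nocr": n_nocr,
                "dominant_response": dominant_resp,
                "dominant_subtype": dominant_subtype,
                "dominant_tie": bool(resp_tie or subtype_tie),
                "resistant": n_nocr > n_cr,
            }
        )
    summary = pd.DataFrame(rows).set_index("subgroup")
    model.summary = summary
    model.resistant_subgroups = summary.index[summary["resistant"]].tolist()
    return summary
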