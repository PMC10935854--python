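"""Auxiliary inference: Ne-trajectory divergence dating and linguistic trees.

Divergence dating compares a query population's effective-population-size
(Ne) trajectory against the per-time-bin spread of a reference group: bins
where the query falls outside mean +/- k_sd * SD are "divergent", and the
reported divergence time is the midpoint of the earliest (oldest) bin of the
most recent divergent run — the earliest time range of the latest
divergence.  Linguistic distances are D = (-log10 s) * 100 on a lexical
similarity matrix, turned into a neighbor-joining tree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NE_COLUMNS = ["pop", "left_years", "right_years", "ne"]


def _bins_of(table: pd.DataFrame, pop: str) -> pd.DataFrame:
    sub = table[table["pop"] == pop].sort_values("left_years").reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no Ne rows for population {pop!r}")
    return sub


def ne_divergence(
    ne_table: pd.DataFrame,
    group_pops: list[str],
    query_pop: str,
    k_sd: float = 3.0,
    pick: str = "oldest",
) -> float | None:
    """Date the query's divergence from a reference group of Ne trajectories.

    All populations must share identical time bins (ascending in years
    before present).  Per bin, the group's mean and sample SD are computed;
    the query is divergent in a bin when its Ne falls outside
    ``mean +/- k_sd * SD`` (with SD exactly zero, any difference counts).
    The most recent maximal run of divergent bins is located and the
    midpoint of its oldest bin returned (``pick="youngest"`` selects the
    other end of the run).  Returns ``None`` when no bin is divergent.
    The result is invariant to rescaling every Ne by a common constant.
    """
    if pick not in ("oldest", "youngest"):
        raise ValueError("pick must be 'oldest' or 'youngest'")
    ref_bins = _bins_of(ne_table, group_pops[0])[["left_years", "right_years"]]
    group = np.vstack([
        _check_bins(_bins_of(ne_table, p), ref_bins)["ne"].to_numpy()
        for p in group_pops
    ])
    query = _check_bins(_bins_of(ne_table, query_pop), ref_bins)["ne"].to_numpy()

    mean = group.mean(axis=0)
    sd = group.std(axis=0, ddof=1) if group.shape[0] > 1 else np.zeros(mean.size)
    with np.errstate(invalid="ignore"):
        divergent = np.where(
            sd > 0,
            np.abs(query - mean) > k_sd * sd,
            query != mean,
        )
    if not divergent.any():
        return None

    # bins ascend in age; the most recent run starts at the first divergent bin
    first = int(np.argmax(divergent))
    last = first
    while last + 1 < divergent.size and divergent[last + 1]:
        last += 1
    i = last if pick == "oldest" else first
    left = float(ref_bins.iloc[i]["left_years"])
    right = float(ref_bins.iloc[i]["right_years"])
    return (left + right) / 2.0


def _check_bins(sub: pd.DataFrame, ref_bins: pd.DataFrame) -> pd.DataFrame:
    same = (
        len(sub) == len(ref_bins)
        and np.allclose(sub["left_years"].to_numpy(), ref_bins["left_years"].to_numpy())
        and np.allclose(sub["right_years"].to_numpy(), ref_bins["right_years"].to_numpy())
    )
    if not same:
        raise ValueError("populations have mismatched time bins")
    return sub


# ---------------------------------------------------------------------------
# Linguistic distance and tree
# ---------------------------------------------------------------------------

def linguistic_distance(similarity: pd.DataFrame) -> pd.DataFrame:
    """D = (-log10 s) * 100 elementwise; diagonal 0; s = 0 maps to inf.

    ``similarity`` is a symmetric matrix of lexical-cognate sharing
    proportions in (0, 1] with unit diagonal.
    """
    s = similarity.to_numpy(dtype=float)
    if s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("similarities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        d = -np.log10(s) * 100.0
    d[s == 0] = np.inf
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=similarity.index, columns=similarity.columns)


def build_tree(distance: pd.DataFrame) -> str:
    """Neighbor-joining tree from a distance matrix, returned as Newick.

    Requires a symmetric matrix with zero diagonal; labels are taken from
    the index (ties resolved by the NJ implementation's deterministic
    ordering, with rows pre-sorted by label).
    """
    import io as _io

    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = [str(x) for x in distance.index]
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    dm = DistanceMatrix(d[np.ix_(order, order)], [labels[i] for i in order])
    tree = nj(dm)
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
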