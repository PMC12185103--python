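"""Interregional cytochrome-oxidase (CO) covariance networks.

CO histochemistry gives a per-region metabolic activity estimate for
each subject (optical density readings normalized against per-batch
thickness standards and averaged over replicates and hemispheres).
Within each group, every unordered pair of regions is tested for
Pearson correlation; significance is controlled at a 0.01 false
discovery rate (Benjamini–Hochberg), and group differences per edge use
the Fisher z transform. Edges at two tiers (p < 0.05; FDR < 0.01) form
a graph over the canonical 14-region set.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: The canonical region set (retrosplenial, reuniens, amygdala,
#: dorsal/ventral hippocampus, dorsal subiculum).
CANONICAL_REGIONS = (
    "RSD", "RSG", "RE", "CEA", "BMA", "BLA",
    "dCA1", "dCA2", "dCA3", "dDG", "vCA1", "vCA3", "vDG", "DS",
)

FDR_Q = 0.01
EDGE_P = 0.05


def average_replicates(readings: pd.DataFrame, value_col: str = "od") -> pd.DataFrame:
    """Mean value per subject x region across readings and hemispheres.

    ``readings`` is a long table with at least ``subject``, ``region``
    and the value column (typically 3–6 optical-density readings per
    site per hemisphere). Returns a wide subject x region table;
    subject/region combinations with no readings stay NaN and are
    dropped pairwise downstream.
    """
    required = {"subject", "region", value_col}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings table missing columns: {sorted(missing)}")
    wide = readings.pivot_table(index="subject", columns="region",
                                values=value_col, aggfunc="mean")
    if "group" in readings.columns:
        groups = readings.groupby("subject")["group"].first()
        wide.insert(0, "group", groups.reindex(wide.index))
    return wide


def normalize_to_standards(raw: pd.DataFrame, standards: pd.DataFrame,
                           od_col: str = "od") -> pd.Series:
    """Normalize optical densities against per-batch thickness standards.

    Each staining batch includes homogenate standards of known section
    thickness (e.g. 20/40/60/80 um). A least-squares line of standard OD
    on thickness gives the batch slope (OD per um); subject readings are
    divided by their batch's slope, expressing activity per um of
    tissue. Because this is a common rescaling within a batch, Pearson
    correlations are unchanged when all subjects share a batch.
    """
    slopes = {}
    for batch, grp in standards.groupby("batch"):
        x = grp["thickness_um"].to_numpy(dtype=float)
        y = grp[od_col].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(f"degenerate standards for batch {batch!r}")
        slope = np.polyfit(x, y, 1)[0]
        if abs(slope) < 1e-12:
            raise ValueError(f"zero standards slope for batch {batch!r}")
        slopes[batch] = slope
    unknown = set(raw["batch"]) - set(slopes)
    if unknown:
        raise ValueError(f"readings reference unknown batches: {sorted(unknown)}")
    return raw[od_col] / raw["batch"].map(slopes)


def correlation_matrix(table: pd.DataFrame, group: str | None = None,
                       regions: tuple[str, ...] | None = None,
                       fdr_q: float = FDR_Q) -> pd.DataFrame:
    """Pearson r and p for every unordered region pair, with BH-FDR flags.

    ``table`` is a wide subject x region frame, optionally with a
    ``group`` column used to subset. Missing values are dropped per
    pair; every pair needs at least four subjects. For the canonical
    14-region set this evaluates C(14, 2) = 91 pairs.
    """
    if group is not None:
        if "group" not in table.columns:
            raise ValueError("table has no 'group' column")
        table = table.loc[table["group"] == group]
    data = table.drop(columns=["group"], errors="ignore")
    regions = tuple(regions) if regions is not None else tuple(data.columns)
    rows = []
    for a, b in combinations(regions, 2):
        sub = data[[a, b]].dropna()
        n = len(sub)
        if n < 4:
            raise ValueError(f"pair ({a}, {b}) has only {n} subjects (need >= 4)")
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"region_a": a, "region_b": b, "r": float(r),
                     "p": float(p), "n": n})
    edges = pd.DataFrame(rows)
    edges["significant_p05"] = edges["p"] < EDGE_P
    edges["significant_fdr"] = fdr_select(edges["p"].to_numpy(), q=fdr_q)
    if group is not None:
        edges.insert(0, "group", group)
    return edges


def fdr_select(pvalues: np.ndarray, q: float = FDR_Q) -> np.ndarray:
    """Benjamini–Hochberg step-up selection at FDR level q."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via the Fisher z transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p. Requires |r| < 1 and n >= 4 in both groups.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (atanh diverges)")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt( p(1-p) (1/n1 + 1/n2) ) with the pooled
    p = (k1 + k2) / (n1 + n2).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n == 0:
            raise ValueError("require 0 <= k <= n with n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def compare_groups(edges_a: pd.DataFrame, edges_b: pd.DataFrame) -> pd.DataFrame:
    """Per-edge Fisher-z comparison of two groups' correlation tables."""
    key = ["region_a", "region_b"]
    merged = edges_a.merge(edges_b, on=key, suffixes=("_a", "_b"))
    zs, ps = [], []
    for _, row in merged.iterrows():
        z, p = fisher_z_compare(row["r_a"], int(row["n_a"]), row["r_b"], int(row["n_b"]))
        zs.append(z)
        ps.append(p)
    out = merged[key + ["r_a", "n_a", "r_b", "n_b"]].copy()
    out["fisher_z"] = zs
    out["p"] = ps
    return out


def build_graph(edges: pd.DataFrame,
                regions: tuple[str, ...] | None = None) -> nx.Graph:
    """Graph of significant correlations with two significance tiers.

    Every region is a node; edges with p < 0.05 are included and carry
    ``r``, ``p`` and ``fdr_significant`` (survived BH at 0.01, a nested
    subset of the p < 0.05 tier).
    """
    G = nx.Graph()
    nodes = regions if regions is not None else sorted(
        set(edges["region_a"]) | set(edges["region_b"]))
    G.add_nodes_from(nodes)
    for _, row in edges.iterrows():
        if row["significant_p05"]:
            G.add_edge(row["region_a"], row["region_b"], r=row["r"], p=row["p"],
                       fdr_significant=bool(row["significant_fdr"]))
    return G
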