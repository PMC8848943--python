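"""Paired-mass-distance (PMD) redundant-peak reduction and precursor election.

One compound rarely yields one LC-MS feature: adducts, isotopologues,
neutral losses and in-source reactions spread it over several co-eluting
peaks. The m/z differences between such redundant peaks recur across the
whole run (e.g. 21.98 Da for Na/H exchange, 18.01 Da for water loss), so
recurrent PMDs can be learned from the data itself instead of from a
predefined adduct list:

1. group features by retention time (co-elution candidates),
2. tabulate all within-group pairwise m/z differences, rounded to two
   decimals, counting each PMD at most once per RT group,
3. keep the high-frequency PMDs (explicit cutoff, or automatic elbow),
4. inside each RT group, connect feature pairs whose PMD is high-frequency;
   every connected component is one putative compound ("pseudo-spectrum")
   and its most intense member is the *independent peak*,
5. merge clusters that share member ions, prune members whose intensity
   profile across study samples does not track the base peak, and elect
   the most intense remaining member as the MS/MS *precursor ion*.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io import FeatureTable

__all__ = [
    "RTGroupAssignment",
    "PMDRecord",
    "IonCluster",
    "assign_rt_groups",
    "round_pmd",
    "compute_pmd_frequency",
    "select_high_frequency_pmds",
    "reduce_redundant_peaks",
    "build_and_merge_clusters",
    "prune_by_correlation",
    "select_precursors",
    "pick_precursors",
]


@dataclass
class RTGroupAssignment:
    """Flat RT clustering: one integer group label per feature."""

    group_ids: np.ndarray
    rt_cutoff: float
    method: str = "complete"

    def groups(self) -> dict[int, np.ndarray]:
        """Map group label -> feature index array (ascending indices)."""
        out: dict[int, np.ndarray] = {}
        for g in np.unique(self.group_ids):
            out[int(g)] = np.nonzero(self.group_ids == g)[0]
        return out


@dataclass(frozen=True)
class PMDRecord:
    """A paired mass distance and the number of RT groups it occurs in."""

    pmd: float
    frequency: int


@dataclass
class IonCluster:
    """A pseudo-spectrum: member feature ids, base (independent) peak,
    and — after election — the precursor targeted for MS/MS."""

    members: set[str]
    base_peak: str
    precursor: str | None = None
    component_pmds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_peak not in self.members:
            raise ValueError("base peak must be a cluster member")


def assign_rt_groups(
    table: FeatureTable, rt_cutoff: float = 10.0, method: str = "complete"
) -> RTGroupAssignment:
    """Hierarchically cluster features on RT and cut at ``rt_cutoff`` seconds.

    The default complete linkage bounds each group's RT diameter by the
    cutoff, which keeps groups local even when consecutive features are
    closer together than the cutoff across the whole gradient (single
    linkage would chain a dense run into one group). ``method`` accepts
    any scipy linkage method for experimentation.
    """
    if table.n_features == 0:
        raise ValueError("cannot group an empty feature table")
    if table.n_features == 1:
        return RTGroupAssignment(np.array([1]), rt_cutoff, method)
    z = linkage(table.rt[:, None], method=method)
    labels = fcluster(z, t=rt_cutoff, criterion="distance")
    return RTGroupAssignment(labels, rt_cutoff, method)


def round_pmd(delta: float) -> float:
    """Round a non-negative mass distance to 2 decimals, half away from zero.

    A 1e-7 guard absorbs binary representation error at the .xx5 boundary.
    """
    return math.floor(delta * 100.0 + 0.5 + 1e-7) / 100.0


def compute_pmd_frequency(
    table: FeatureTable, groups: RTGroupAssignment
) -> list[PMDRecord]:
    """Tabulate within-RT-group pairwise PMDs.

    Each distinct rounded PMD counts at most once per RT group, so a PMD's
    frequency is the number of RT groups containing at least one feature
    pair at that distance. Records are sorted by descending frequency,
    ties broken by ascending PMD.
    """
    counter: Counter[float] = Counter()
    for idx in groups.groups().values():
        if idx.size < 2:
            continue
        mz = table.mz[idx]
        diffs = np.abs(mz[:, None] - mz[None, :])[np.triu_indices(idx.size, k=1)]
        counter.update({round_pmd(d) for d in diffs})
    return [
        PMDRecord(pmd, freq)
        for pmd, freq in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def select_high_frequency_pmds(
    records: list[PMDRecord], freq_cutoff: int | None = None
) -> set[float]:
    """Pick the PMDs treated as redundant-ion relationships.

    With an explicit ``freq_cutoff``, keep PMDs with frequency >= cutoff.
    In automatic mode, cut at the largest drop in the descending frequency
    sequence (elbow), never keeping PMDs observed in fewer than 2 groups.
    """
    if not records:
        return set()
    if freq_cutoff is not None:
        return {r.pmd for r in records if r.frequency >= freq_cutoff}
    freqs = sorted({r.frequency for r in records}, reverse=True)
    seq = freqs + [0]
    gaps = [seq[i] - seq[i + 1] for i in range(len(seq) - 1)]
    cut = freqs[int(np.argmax(gaps))]
    cut = max(cut, 2)
    return {r.pmd for r in records if r.frequency >= cut}


def _best_feature(indices: np.ndarray, table: FeatureTable, mean_int: np.ndarray) -> int:
    """Most intense feature index; ties broken by lower m/z, then id."""
    return int(min(indices, key=lambda i: (-mean_int[i], table.mz[i], str(table.ids[i]))))


def reduce_redundant_peaks(
    table: FeatureTable,
    groups: RTGroupAssignment,
    high_pmds: set[float],
) -> tuple[set[str], list[set[str]]]:
    """Collapse redundant co-eluting ions into independent peaks.

    Within each RT group, feature pairs whose rounded PMD is in
    ``high_pmds`` are connected; each connected component contributes a
    single independent peak (its member with maximal mean study
    intensity). Singletons are independent by themselves. Returns the set
    of independent peak ids and all components (as id sets, including
    singletons).
    """
    mean_int = table.mean_study_intensity()
    independent: set[str] = set()
    components: list[set[str]] = []
    for idx in groups.groups().values():
        g = nx.Graph()
        g.add_nodes_from(int(i) for i in idx)
        if high_pmds and idx.size > 1:
            mz = table.mz[idx]
            for a in range(idx.size):
                for b in range(a + 1, idx.size):
                    if round_pmd(abs(mz[a] - mz[b])) in high_pmds:
                        g.add_edge(int(idx[a]), int(idx[b]))
        for comp in nx.connected_components(g):
            comp_idx = np.array(sorted(comp), dtype=int)
            best = _best_feature(comp_idx, table, mean_int)
            independent.add(str(table.ids[best]))
            components.append({str(table.ids[i]) for i in comp_idx})
    return independent, components


def build_and_merge_clusters(
    independent: set[str],
    components: list[set[str]],
    table: FeatureTable,
) -> list[IonCluster]:
    """Turn components into ion clusters, merging any that share an ion.

    Each component carries one independent peak as its base. Components
    sharing a member feature are merged (union-find via a bipartite
    feature/component graph); the merged cluster's base peak is the most
    intense of the merged bases.
    """
    mean_int = table.mean_study_intensity()

    g = nx.Graph()
    for ci, comp in enumerate(components):
        cnode = ("c", ci)
        g.add_node(cnode)
        for fid in comp:
            g.add_edge(cnode, ("f", fid))

    clusters: list[IonCluster] = []
    for blob in nx.connected_components(g):
        members = {nid for kind, nid in blob if kind == "f"}
        bases = sorted(members & independent)
        if not bases:
            # pathological hand-built input: fall back to intensity election
            bases = sorted(members)
        base = min(
            bases,
            key=lambda fid: (-mean_int[table.index_of(fid)], table.mz[table.index_of(fid)], fid),
        )
        clusters.append(IonCluster(members=members, base_peak=base))
    clusters.sort(key=lambda c: table.rt[table.index_of(c.base_peak)])
    return clusters


def prune_by_correlation(
    cluster: IonCluster,
    table: FeatureTable,
    r_min: float = 0.9,
) -> IonCluster:
    """Drop members whose study-intensity profile does not track the base peak.

    Ions of one compound co-vary across samples; a member whose Pearson
    correlation with the base peak's study-intensity vector falls below
    ``r_min`` (strictly) is excluded. The base peak itself is always kept.
    With fewer than 3 study samples the correlation is not meaningful and
    pruning is skipped with a warning; a zero-variance member vector has
    undefined correlation and is removed with a warning.
    """
    if table.study_indices.size < 3:
        warnings.warn("fewer than 3 study samples; correlation pruning skipped", stacklevel=2)
        return IonCluster(set(cluster.members), cluster.base_peak)
    study = table.study_intensities()
    base_vec = study[table.index_of(cluster.base_peak)]
    base_sd = base_vec.std()
    kept = {cluster.base_peak}
    for fid in cluster.members:
        if fid == cluster.base_peak:
            continue
        vec = study[table.index_of(fid)]
        if vec.std() == 0 or base_sd == 0:
            warnings.warn(f"member {fid}: zero-variance intensity vector; removed", stacklevel=2)
            continue
        r = float(np.corrcoef(base_vec, vec)[0, 1])
        if r >= r_min - 1e-12:
            kept.add(fid)
    return IonCluster(kept, cluster.base_peak)


def select_precursors(clusters: list[IonCluster], table: FeatureTable) -> pd.DataFrame:
    """Elect one precursor ion per cluster for targeted MS/MS.

    The precursor is the member with maximal mean study intensity (ties:
    lower m/z, then id). Clusters are annotated in place; the returned
    frame has columns id, mz, rt, intensity, sorted by RT then m/z.
    """
    mean_int = table.mean_study_intensity()
    rows = []
    for cluster in clusters:
        if not cluster.members:
            raise ValueError("cannot elect a precursor from an empty cluster")
        pid = min(
            cluster.members,
            key=lambda fid: (-mean_int[table.index_of(fid)], table.mz[table.index_of(fid)], fid),
        )
        cluster.precursor = pid
        i = table.index_of(pid)
        rows.append({"id": pid, "mz": table.mz[i], "rt": table.rt[i],
                     "intensity": mean_int[i]})
    df = pd.DataFrame(rows, columns=["id", "mz", "rt", "intensity"])
    return df.sort_values(["rt", "mz"], kind="stable").reset_index(drop=True)


def pick_precursors(
    table: FeatureTable,
    rt_cutoff: float = 10.0,
    freq_cutoff: int | None = None,
    r_min: float = 0.9,
    rt_method: str = "complete",
) -> tuple[pd.DataFrame, list[IonCluster], dict]:
    """Full reduction pipeline: RT groups -> PMD frequencies -> independent
    peaks -> merged, correlation-pruned clusters -> one precursor each.

    Returns (precursor frame, clusters, diagnostics) where diagnostics
    holds the PMD records, the selected high-frequency PMDs and the
    independent-peak set.
    """
    groups = assign_rt_groups(table, rt_cutoff, rt_method)
    records = compute_pmd_frequency(table, groups)
    high = select_high_frequency_pmds(records, freq_cutoff)
    independent, components = reduce_redundant_peaks(table, groups, high)
    clusters = build_and_merge_clusters(independent, components, table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clusters = [prune_by_correlation(c, table, r_min) for c in clusters]
    precursors = select_precursors(clusters, table)
    diag = {
        "pmd_records": records,
        "high_pmds": high,
        "independent": independent,
        "rt_groups": groups,
    }
    return precursors, clusters, diag
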