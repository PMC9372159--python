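"""CCF clustering, clone-tree assembly and the trunk-proportion statistic.

Substitutions are clustered across a patient's biopsies by cancer cell
fraction (CCF) under a Dirichlet-process binomial mixture: a cluster is a
vector of CCFs (one per biopsy) and a mutation's alt count in biopsy b is
binomial with success probability ``CCF * m * rho / (rho*CNt + 2*(1-rho))``.
A Chinese-restaurant-process Gibbs sampler with a uniform grid prior on
cluster CCFs yields posterior partitions, summarised by the
maximum-posterior-similarity partition (Dahl's method; ties broken towards
fewer clusters).

The clone tree nests clusters by the pigeonhole principle (a child's CCF
cannot exceed its parent's in any biopsy) and the trunk proportion is

    n_trunk / (n_trunk + sum_tips dist(trunk -> tip) / n_tips)

where mutations on internal branches shared by several tips are counted
once per tip passing through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

CCF_FLAG_MAX = 1.5


def compute_ccf(alt, total, purity, total_cn, multiplicity):
    """Per-mutation per-biopsy CCF: ``VAF * (rho*CNt + 2*(1-rho)) / (rho*m)``.

    Values are reported as-is; entries above 1.5 should be flagged by the
    caller (they usually indicate a wrong multiplicity or copy state).
    """
    alt = np.asarray(alt, dtype=float)
    total = np.asarray(total, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        ccf = vaf * (purity * total_cn + 2 * (1 - purity)) / (purity * multiplicity)
    return ccf


# ---------------------------------------------------------------------------
# Dirichlet-process clustering

@dataclass
class ClusterResult:
    assignments: np.ndarray          # cluster id per mutation, -1 = unassigned
    clusters: pd.DataFrame           # cluster, n_subs, ccf_<biopsy> columns
    n_sweeps_used: int
    biopsies: list = field(default_factory=list)


def _loglik_table(alt, total, coeff, grid):
    """L[i, b, g]: binomial log-likelihood of mutation i in biopsy b at grid CCF g."""
    p = np.clip(grid[None, None, :] * coeff[:, :, None], 1e-12, 1 - 1e-12)
    a = alt[:, :, None]
    n = total[:, :, None]
    L = a * np.log(p) + (n - a) * np.log1p(-p)
    return np.where(n > 0, L, 0.0)


def cluster_ccf(
    alt: np.ndarray,
    total: np.ndarray,
    purity: np.ndarray,
    total_cn: np.ndarray,
    multiplicity: np.ndarray,
    iters: int = 1000,
    burnin: int = 200,
    concentration: float = 1.0,
    seed: int | None = None,
    biopsies: list | None = None,
    chrom: np.ndarray | None = None,
    grid_step: float = 0.02,
    grid_max: float = 1.2,
    max_stored: int = 100,
) -> ClusterResult:
    """Cluster substitutions by CCF across biopsies.

    Parameters
    ----------
    alt, total : (n, B) int arrays
        Read counts per mutation per biopsy.
    purity : (B,) array
    total_cn, multiplicity : (n, B) arrays
        Local total copy number and mutation multiplicity.
    iters, burnin : int
        Gibbs sweeps and discarded burn-in.  Patients with five or fewer
        samples are conventionally run at 3000/1000 and highly multi-sampled
        ones at 1000/200; the defaults follow the latter.
    chrom : optional (n,) array
        When given, non-autosomal mutations are excluded from clustering
        and returned unassigned.

    Returns
    -------
    ClusterResult
        Point clustering (maximum-posterior-similarity partition over the
        retained sweeps) and per-cluster CCF medians.  Mutations with zero
        depth in every biopsy are unassigned (-1).
    """
    alt = np.atleast_2d(np.asarray(alt, dtype=float))
    total = np.atleast_2d(np.asarray(total, dtype=float))
    purity = np.asarray(purity, dtype=float)
    total_cn = np.broadcast_to(np.asarray(total_cn, dtype=float), alt.shape)
    multiplicity = np.broadcast_to(np.asarray(multiplicity, dtype=float), alt.shape)
    n, B = alt.shape
    if biopsies is None:
        biopsies = [f"b{j}" for j in range(B)]

    usable = np.ones(n, dtype=bool)
    if chrom is not None:
        usable &= np.isin(np.asarray(chrom, dtype=str), list(AUTOSOMES))
    usable &= total.sum(axis=1) > 0

    assignments = np.full(n, -1, dtype=int)
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        return ClusterResult(assignments, _cluster_table([], [], biopsies), 0, biopsies)

    a_u, t_u = alt[idx], total[idx]
    coeff = multiplicity[idx] * purity[None, :] / (
        purity[None, :] * total_cn[idx] + 2 * (1 - purity[None, :])
    )
    grid = np.arange(0.0, grid_max + 1e-9, grid_step)
    G = grid.size
    L = _loglik_table(a_u, t_u, coeff, grid)  # (m, B, G)
    m = idx.size
    rng = np.random.default_rng(seed)

    # marginal likelihood of a singleton cluster under the uniform grid prior
    lse = np.logaddexp.reduce(L, axis=2) - np.log(G)  # (m, B)
    log_marg = lse.sum(axis=1)                         # (m,)

    z = np.zeros(m, dtype=int)
    theta = [rng.integers(G, size=B)]  # grid indices per cluster
    counts = [m]
    log_alpha = np.log(concentration)

    stored: list[np.ndarray] = []
    store_every = max(1, (iters - burnin) // max_stored)
    barange = np.arange(B)

    def resample_theta():
        for k in range(len(theta)):
            members = z == k
            if not members.any():
                continue
            post = L[members].sum(axis=0)  # (B, G)
            post -= post.max(axis=1, keepdims=True)
            w = np.exp(post)
            w /= w.sum(axis=1, keepdims=True)
            theta[k] = np.array([rng.choice(G, p=w[b]) for b in range(B)])

    def cluster_scores(theta_k):
        # likelihood of every mutation under one cluster's CCF vector, (m,)
        return L[:, barange, theta_k].sum(axis=1)

    for sweep in range(iters):
        resample_theta()
        # cached per-cluster likelihood columns, refreshed each sweep and
        # patched incrementally as clusters are created or destroyed
        score_cols = [cluster_scores(t) for t in theta]
        uniform = rng.random(m)
        for i in range(m):
            k_old = z[i]
            counts[k_old] -= 1
            if counts[k_old] == 0:
                # remove the emptied cluster, relabelling the last one
                last = len(theta) - 1
                if k_old != last:
                    theta[k_old] = theta[last]
                    counts[k_old] = counts[last]
                    score_cols[k_old] = score_cols[last]
                    z[z == last] = k_old
                theta.pop()
                counts.pop()
                score_cols.pop()
            K = len(theta)
            logp = np.empty(K + 1)
            for k in range(K):
                logp[k] = np.log(counts[k]) + score_cols[k][i]
            logp[K] = log_alpha + log_marg[i]
            logp -= logp.max()
            p = np.exp(logp)
            cum = np.cumsum(p)
            k_new = int(np.searchsorted(cum, uniform[i] * cum[-1]))
            if k_new >= K:
                post = L[i]  # (B, G)
                w = np.exp(post - post.max(axis=1, keepdims=True))
                w /= w.sum(axis=1, keepdims=True)
                new_theta = np.array([rng.choice(G, p=w[b]) for b in range(B)])
                theta.append(new_theta)
                counts.append(1)
                score_cols.append(cluster_scores(new_theta))
                k_new = K
            else:
                counts[k_new] += 1
            z[i] = k_new
        if sweep >= burnin and (sweep - burnin) % store_every == 0:
            stored.append(z.copy())

    if not stored:
        stored.append(z.copy())

    best = _max_posterior_similarity(stored)
    labels = _relabel(best)
    assignments[idx] = labels

    ccf_obs = compute_ccf(a_u, t_u, purity[None, :], total_cn[idx], multiplicity[idx])
    cluster_ids = sorted(set(labels))
    medians = []
    sizes = []
    for k in cluster_ids:
        members = labels == k
        sizes.append(int(members.sum()))
        medians.append(np.nanmedian(ccf_obs[members], axis=0))
    table = _cluster_table(list(zip(cluster_ids, sizes)), medians, biopsies)
    return ClusterResult(assignments, table, len(stored), biopsies)


def _cluster_table(id_sizes, medians, biopsies) -> pd.DataFrame:
    cols = ["cluster", "n_subs"] + [f"ccf_{b}" for b in biopsies]
    rows = []
    for (cid, size), med in zip(id_sizes, medians):
        rows.append([cid, size] + list(np.asarray(med, dtype=float)))
    return pd.DataFrame(rows, columns=cols)


def _max_posterior_similarity(partitions: list[np.ndarray]) -> np.ndarray:
    """Dahl's method: stored partition closest to the posterior similarity matrix."""
    m = partitions[0].size
    psm = np.zeros((m, m))
    for z in partitions:
        psm += z[:, None] == z[None, :]
    psm /= len(partitions)
    best, best_score, best_k = None, np.inf, np.inf
    for z in partitions:
        ind = (z[:, None] == z[None, :]).astype(float)
        score = float(((ind - psm) ** 2).sum())
        k = np.unique(z).size
        if score < best_score - 1e-12 or (abs(score - best_score) <= 1e-12 and k < best_k):
            best, best_score, best_k = z, score, k
    return best


def _relabel(z: np.ndarray) -> np.ndarray:
    _, labels = np.unique(z, return_inverse=True)
    return labels


def filter_clusters(
    clusters: pd.DataFrame,
    assignments: np.ndarray | None = None,
    min_fraction: float = 0.01,
    min_count: int = 20,
    violating: set | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Remove clusters below the size thresholds (and flagged tree violators).

    A cluster is dropped if it holds fewer than ``min_count`` substitutions
    or under ``min_fraction`` of the patient's total, or if it appears in
    ``violating`` (small clusters inconsistent with the rest of the tree,
    as flagged by :func:`build_tree`).  Mutations of dropped clusters are
    set to unassigned (-1) in the returned assignment copy.
    """
    total = clusters["n_subs"].sum()
    keep = (clusters["n_subs"] >= min_count) & (clusters["n_subs"] >= min_fraction * total)
    if violating:
        keep &= ~clusters["cluster"].isin(violating)
    kept = clusters[keep].reset_index(drop=True)
    new_assign = None
    if assignments is not None:
        new_assign = assignments.copy()
        dropped = set(clusters.loc[~keep, "cluster"])
        new_assign[np.isin(assignments, list(dropped))] = -1
    return kept, new_assign


# ---------------------------------------------------------------------------
# clone tree

@dataclass
class CloneTree:
    """Mutation clusters with parent links and a designated trunk."""

    clusters: pd.DataFrame           # cluster, n_subs, ccf_<biopsy>
    parent: dict                     # cluster id -> parent id (trunk -> None)
    trunk: int | None
    biopsies: list
    violations: dict = field(default_factory=dict)  # cluster id -> pigeonhole residual
    diagnostic: str = ""

    @property
    def is_forest(self) -> bool:
        return self.trunk is None

    def children(self, cid) -> list:
        return [c for c, p in self.parent.items() if p == cid]

    def tips(self) -> list:
        have_children = set(p for p in self.parent.values() if p is not None)
        return [c for c in self.parent if c not in have_children and c != self.trunk]

    def n_subs(self, cid) -> int:
        row = self.clusters.loc[self.clusters["cluster"] == cid, "n_subs"]
        return int(row.iloc[0])

    def path_to_trunk(self, cid) -> list:
        path = []
        cur = cid
        while cur is not None and cur != self.trunk:
            path.append(cur)
            cur = self.parent.get(cur)
        return path

    def flagged_small_violators(self, residual_min: float = 0.1, trunk_fraction_max: float = 0.05) -> set:
        """Clusters whose pigeonhole residual exceeds 0.1 and whose size is
        under 5% of the trunk — candidates for removal as artefact."""
        if self.trunk is None:
            return set()
        trunk_n = self.n_subs(self.trunk)
        out = set()
        for cid, resid in self.violations.items():
            if resid > residual_min and self.n_subs(cid) < trunk_fraction_max * trunk_n:
                out.add(cid)
        return out

    def to_newick(self) -> str:
        def fmt(cid):
            kids = self.children(cid)
            label = f"c{cid}:{self.n_subs(cid)}"
            if not kids:
                return label
            return "(" + ",".join(fmt(k) for k in sorted(kids)) + ")" + label
        if self.trunk is None:
            raise ValueError("cannot export a forest as newick")
        return fmt(self.trunk) + ";"

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"child": c, "parent": (-1 if p is None else p), "n_subs": self.n_subs(c)}
            for c, p in sorted(self.parent.items())
        ]
        return pd.DataFrame(rows, columns=["child", "parent", "n_subs"])


def build_tree(
    clusters: pd.DataFrame,
    presence_ccf: float = 0.1,
    tol: float = 0.05,
    gcnis: dict | None = None,
) -> CloneTree:
    """Assemble a clone tree from a filtered cluster table.

    The trunk is the cluster present (CCF strictly > ``presence_ccf``) in
    every biopsy with the highest summed CCF.  Remaining clusters are
    nested by pigeonhole ordering: each attaches to the already-placed
    cluster with the smallest total CCF that dominates it (parent CCF >=
    child CCF - ``tol``) in every biopsy; clusters no placed cluster
    dominates hang off the trunk with their residual recorded in
    ``violations``.

    ``gcnis`` optionally maps biopsy name -> bool (in-situ compartment).
    Clusters present in both the GCNIS and the invasive compartment are
    merged into the trunk, following the convention that mutations shared
    between in-situ and invasive disease are truncal.
    """
    if len(clusters) == 0:
        raise ValueError("no clusters to build a tree from")
    ccf_cols = [c for c in clusters.columns if c.startswith("ccf_")]
    biopsies = [c[4:] for c in ccf_cols]
    tab = clusters.copy().reset_index(drop=True)
    ccf = tab[ccf_cols].to_numpy(dtype=float)
    present = ccf > presence_ccf

    in_all = present.all(axis=1)
    if not in_all.any():
        parent = {int(c): None for c in tab["cluster"]}
        return CloneTree(tab, parent, None, biopsies,
                         diagnostic="no cluster present in all biopsies; returning a forest")
    trunk_pos = int(np.argmax(np.where(in_all, ccf.sum(axis=1), -np.inf)))
    trunk_id = int(tab.loc[trunk_pos, "cluster"])

    if gcnis is not None and any(gcnis.values()) and not all(gcnis.values()):
        situ = np.array([bool(gcnis.get(b, False)) for b in biopsies])
        merged = []
        for pos in range(len(tab)):
            if pos == trunk_pos:
                continue
            if present[pos][situ].any() and present[pos][~situ].any():
                merged.append(pos)
        if merged:
            tab.loc[trunk_pos, "n_subs"] += int(tab.loc[merged, "n_subs"].sum())
            keep = [p for p in range(len(tab)) if p not in set(merged)]
            tab = tab.iloc[keep].reset_index(drop=True)
            ccf = tab[ccf_cols].to_numpy(dtype=float)
            trunk_pos = int(tab.index[tab["cluster"] == trunk_id][0])

    order = np.argsort(-ccf.sum(axis=1))
    parent: dict[int, int | None] = {trunk_id: None}
    placed = [trunk_pos]
    violations: dict[int, float] = {}
    for pos in order:
        pos = int(pos)
        if pos == trunk_pos:
            continue
        cid = int(tab.loc[pos, "cluster"])
        candidates = []
        for p in placed:
            if np.all(ccf[p] >= ccf[pos] - tol):
                candidates.append(p)
        if candidates:
            best = min(candidates, key=lambda p: ccf[p].sum())
            parent[cid] = int(tab.loc[best, "cluster"])
        else:
            parent[cid] = trunk_id
            violations[cid] = float(np.max(ccf[pos] - ccf[trunk_pos]))
        placed.append(pos)
    return CloneTree(tab, parent, trunk_id, biopsies, violations=violations)


def trunk_proportion(tree: CloneTree) -> float:
    """Proportion of substitutions in the phylogenetic trunk.

    ``n_trunk / (n_trunk + mean tip distance)`` where a tip's distance is
    the summed substitution count of every cluster on its path back to (but
    excluding) the trunk.  Internal branches shared by several tips are
    thereby counted once per tip.  A tree with no subclonal branches scores
    1.0.
    """
    if tree.is_forest:
        raise ValueError("trunk proportion undefined for a forest")
    n_trunk = tree.n_subs(tree.trunk)
    tips = tree.tips()
    if not tips:
        return 1.0
    dists = [sum(tree.n_subs(c) for c in tree.path_to_trunk(t)) for t in tips]
    mean_branch = sum(dists) / len(tips)
    return n_trunk / (n_trunk + mean_branch)
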