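"""Neighbor-joining trees and the homogeneous-seed-source (star-cluster)
detector.

Populations founded from one seed lot show (i) near-zero pairwise F_ST and
(ii) individuals whose nearest neighbours sit in *other* populations of the
group — the quantitative form of a star-shaped cluster in a dissimilarity
tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TreeResult:
    newick: str
    leaf_labels: list[str]


@dataclass
class SourceGroup:
    populations: list[str]
    mixing_index: dict[str, float]
    mean_mixing: float
    max_pairwise_fst: float
    flagged: bool


@dataclass
class SourceGroupReport:
    esu_groups: dict[str, list[SourceGroup]] = field(default_factory=dict)

    def flagged_populations(self) -> set[str]:
        out: set[str] = set()
        for groups in self.esu_groups.values():
            for g in groups:
                if g.flagged:
                    out.update(g.populations)
        return out


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(D: pd.DataFrame | np.ndarray, labels=None) -> TreeResult:
    """Saitou & Nei neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling edge.  Ties in the Q criterion break on the smallest row index.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(M.shape[0])]
        labels = list(labels)
    n = M.shape[0]
    if M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(M, M.T, atol=1e-9, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 leaves")

    nodes = [str(lab) for lab in labels]  # newick fragment per active node
    M = M.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = M[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # ties -> smallest flat index = smallest row then col
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        d_ij = sub[i_loc, j_loc]
        li = 0.5 * d_ij + (totals[i_loc] - totals[j_loc]) / (2.0 * (m - 2))
        lj = d_ij - li
        # clamp negatives, move deficit to sibling
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        gi, gj = active[i_loc], active[j_loc]
        new_label = f"({nodes[gi]}:{li:.10g},{nodes[gj]}:{lj:.10g})"
        # distances from the new node to remaining nodes
        new_row = np.zeros(M.shape[0] + 1)
        for k_loc, gk in enumerate(active):
            if k_loc in (i_loc, j_loc):
                continue
            new_row[gk] = 0.5 * (M[gi, gk] + M[gj, gk] - d_ij)
        M = np.pad(M, ((0, 1), (0, 1)))
        M[-1, :-1] = new_row[:-1]
        M[:-1, -1] = new_row[:-1]
        nodes.append(new_label)
        active = [g for g in active if g not in (gi, gj)] + [M.shape[0] - 1]

    gi, gj = active
    d = max(M[gi, gj], 0.0)
    newick = f"({nodes[gi]}:{d / 2.0:.10g},{nodes[gj]}:{d / 2.0:.10g});"
    return TreeResult(newick=newick, leaf_labels=[str(lab) for lab in labels])


# ---------------------------------------------------------------------------
# Star-cluster / homogeneous seed source detection


def population_mixing_index(
    D: pd.DataFrame, pop_labels: dict[str, str], group: set[str]
) -> dict[str, float]:
    """Per-population fraction of individuals whose nearest neighbour (among
    all individuals of the group's populations, excluding self) belongs to a
    different population.  Ties break on smallest individual index."""
    inds = [i for i in D.index if pop_labels.get(i) in group]
    for pop in group:
        if sum(1 for i in inds if pop_labels[i] == pop) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
    sub = D.loc[inds, inds].to_numpy(dtype=float)
    np.fill_diagonal(sub, np.inf)
    sub = np.where(np.isnan(sub), np.inf, sub)
    nn = np.argmin(sub, axis=1)  # argmin -> smallest index on ties
    out: dict[str, float] = {}
    for pop in group:
        members = [k for k, i in enumerate(inds) if pop_labels[i] == pop]
        cross = sum(1 for k in members if pop_labels[inds[nn[k]]] != pop)
        out[pop] = cross / len(members)
    return out


def detect_homogeneous_source(
    pop_fst: pd.DataFrame,
    D: pd.DataFrame,
    pop_labels: dict[str, str],
    esu_of_pop: dict[str, str],
    natural_pops: set[str] | None = None,
    theta_fst: float = 0.02,
    theta_mix: float = 0.5,
) -> SourceGroupReport:
    """Flag sets of populations sharing a homogeneous seed source.

    Within each assigned-ESU group, candidate sets are grown greedily from
    the lowest-F_ST pair; a set is flagged when all pairwise population F_ST
    are < ``theta_fst`` and its mean mixing index is >= ``theta_mix``.
    ``pop_fst`` is a symmetric population-level F_ST matrix covering the
    populations considered.
    """
    natural_pops = natural_pops or set()
    report = SourceGroupReport()
    by_esu: dict[str, list[str]] = {}
    for pop, esu in esu_of_pop.items():
        by_esu.setdefault(esu, []).append(pop)

    for esu, pops in sorted(by_esu.items()):
        pops = sorted(p for p in pops if p in pop_fst.index)
        groups: list[SourceGroup] = []
        if len(pops) >= 2:
            remaining = set(pops)
            while len(remaining) >= 2:
                # seed with the lowest-FST remaining pair below threshold
                best_pair = None
                best_v = np.inf
                rem = sorted(remaining)
                for a_i in range(len(rem)):
                    for b_i in range(a_i + 1, len(rem)):
                        v = float(pop_fst.loc[rem[a_i], rem[b_i]])
                        if np.isfinite(v) and v < best_v:
                            best_v = v
                            best_pair = (rem[a_i], rem[b_i])
                if best_pair is None or best_v >= theta_fst:
                    break
                cand = set(best_pair)
                grown = True
                while grown:
                    grown = False
                    for p in sorted(remaining - cand):
                        fsts = [float(pop_fst.loc[p, q]) for q in cand]
                        if all(np.isfinite(v) and v < theta_fst for v in fsts):
                            cand.add(p)
                            grown = True
                if len(cand) >= 2:
                    sub = pop_fst.loc[sorted(cand), sorted(cand)].to_numpy()
                    iu = np.triu_indices(len(cand), k=1)
                    max_fst = float(np.nanmax(sub[iu]))
                    try:
                        mix = population_mixing_index(D, pop_labels, cand)
                    except ValueError:
                        mix = {}
                    mean_mix = float(np.mean(list(mix.values()))) if mix else 0.0
                    flagged = len(cand) >= 2 and max_fst < theta_fst and mean_mix >= theta_mix
                    groups.append(
                        SourceGroup(
                            populations=sorted(cand),
                            mixing_index=mix,
                            mean_mixing=mean_mix,
                            max_pairwise_fst=max_fst,
                            flagged=flagged,
                        )
                    )
                remaining -= cand
        report.esu_groups[esu] = groups
    return report


def write_source_report(report: SourceGroupReport, path) -> None:
    rows = []
    for esu, groups in report.esu_groups.items():
        for g in groups:
            rows.append(
                {
                    "esu": esu,
                    "populations": ";".join(g.populations),
                    "mean_mixing": round(g.mean_mixing, 4),
                    "max_pairwise_fst": round(g.max_pairwise_fst, 4),
                    "flagged": g.flagged,
                }
            )
    pd.DataFrame(rows, columns=["esu", "populations", "mean_mixing",
                                "max_pairwise_fst", "flagged"]).to_csv(
        path, sep="\t", index=False
    )
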