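"""Per-individual diversity, group allele frequencies, pairwise F_ST and
identity-by-state dissimilarity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING


@dataclass
class GroupFrequencies:
    """Per-group, per-locus alt-allele frequency and allele-copy count."""

    groups: list[str]
    freq: dict[str, np.ndarray]  # NaN where zero copies
    copies: dict[str, np.ndarray]


def observed_heterozygosity(G: GenotypeMatrix) -> pd.Series:
    """H_o per individual: heterozygous calls / non-missing calls."""
    het = (G.dosages == 1).sum(axis=1)
    called = (G.dosages != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.Series(ho, index=G.individual_ids, name="H_o")


def group_allele_freqs(G: GenotypeMatrix, groups: dict[str, str]) -> GroupFrequencies:
    """Alt-allele frequency and copy count per site within each group."""
    missing = [i for i in G.individual_ids if i not in groups]
    if missing:
        raise ValueError(f"unmapped individuals: {missing[:5]}")
    labels = sorted({groups[i] for i in G.individual_ids})
    freq: dict[str, np.ndarray] = {}
    copies: dict[str, np.ndarray] = {}
    for lab in labels:
        idx = [k for k, i in enumerate(G.individual_ids) if groups[i] == lab]
        d = G.dosages[idx]
        called = d != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        freq[lab] = p
        copies[lab] = n.astype(float)
    return GroupFrequencies(groups=labels, freq=freq, copies=copies)


def inbreeding_F(
    G: GenotypeMatrix,
    freqs: GroupFrequencies,
    groups: dict[str, str],
    drop_monomorphic: bool = False,
) -> pd.DataFrame:
    """Method-of-moments inbreeding F = (O - E) / (N - E) per individual.

    O = observed homozygous sites, N = sites used, and E sums the
    small-sample-corrected expected homozygosity 1 - 2p(1-p) n/(n-1) over the
    individual's non-missing sites, with p and n taken from its group.
    Sites monomorphic in the group contribute 1 to E unless
    ``drop_monomorphic``.
    """
    rows = []
    for i, ind in enumerate(G.individual_ids):
        lab = groups[ind]
        p = freqs.freq[lab]
        n = freqs.copies[lab]
        d = G.dosages[i].astype(float)
        use = (G.dosages[i] != MISSING) & np.isfinite(p) & (n >= 2)
        if drop_monomorphic:
            use &= (p > 0) & (p < 1)
        dsub = d[use]
        psub = p[use]
        nsub = n[use]
        N = int(use.sum())
        O = int(((dsub == 0) | (dsub == 2)).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            e_site = 1.0 - 2.0 * psub * (1.0 - psub) * nsub / (nsub - 1.0)
        E = float(e_site.sum())
        F = (O - E) / (N - E) if abs(N - E) > 1e-12 else np.nan
        ho = (dsub == 1).mean() if N else np.nan
        rows.append(
            {"individual_id": ind, "group": lab, "N": N, "O": O, "E": E, "H_o": ho, "F": F}
        )
    return pd.DataFrame(rows).set_index("individual_id")


# ---------------------------------------------------------------------------
# F_ST


def _counts(G: GenotypeMatrix, idx: list[int]):
    d = G.dosages[idx]
    called = d != MISSING
    n = called.sum(axis=0).astype(float)  # diploid individuals called
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    het = ((d == 1) & called).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
    return n, p, het


def _wc_fst(G: GenotypeMatrix, idx1: list[int], idx2: list[int]) -> float:
    """Weir & Cockerham (1984) two-population multi-locus theta,
    ratio of sums of the a and a+b+c variance components."""
    n1, p1, het1 = _counts(G, idx1)
    n2, p2, het2 = _counts(G, idx2)
    ok = (n1 >= 1) & (n2 >= 1) & np.isfinite(p1) & np.isfinite(p2)
    n1, p1, het1 = n1[ok], p1[ok], het1[ok]
    n2, p2, het2 = n2[ok], p2[ok], het2[ok]
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (het1 + het2) / (r * nbar)
    good = nbar > 1.0
    nbar, nc, pbar, s2, hbar = nbar[good], nc[good], pbar[good], s2[good], hbar[good]
    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pq - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    denom = (a + b + c).sum()
    if denom == 0.0:
        return np.nan
    return float(a.sum() / denom)


def _hudson_fst(G: GenotypeMatrix, idx1: list[int], idx2: list[int]) -> float:
    """Hudson estimator (Bhatia et al. 2013 form), ratio of averages."""
    n1, p1, _ = _counts(G, idx1)
    n2, p2, _ = _counts(G, idx2)
    c1 = 2.0 * n1
    c2 = 2.0 * n2
    ok = (c1 >= 2) & (c2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    p1, p2, c1, c2 = p1[ok], p2[ok], c1[ok], c2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (c1 - 1) - p2 * (1 - p2) / (c2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total = den.sum()
    if total == 0.0:
        return np.nan
    return float(num.sum() / total)


def pairwise_fst(
    G: GenotypeMatrix,
    pop_labels: dict[str, str],
    estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Symmetric pairwise multi-locus F_ST among the labelled groups.

    Only individuals present in ``pop_labels`` enter (the caller excludes
    admixed individuals beforehand).  Groups need >= 2 individuals.
    """
    if estimator not in ("weir_cockerham", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    members: dict[str, list[int]] = {}
    for k, ind in enumerate(G.individual_ids):
        lab = pop_labels.get(ind)
        if lab is not None:
            members.setdefault(lab, []).append(k)
    for lab, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 individuals")
    labels = sorted(members)
    fn = _wc_fst if estimator == "weir_cockerham" else _hudson_fst
    mat = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            v = fn(G, members[labels[i]], members[labels[j]])
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=labels, columns=labels)


def ibs_dissimilarity(G: GenotypeMatrix, min_overlap: int = 50) -> pd.DataFrame:
    """Pairwise mean |g_i - g_j| / 2 over shared non-missing loci.

    Pairs with fewer than ``min_overlap`` shared loci get NaN (warned).
    """
    X = G.dosage_float()
    called = np.isfinite(X)
    Xz = np.nan_to_num(X, nan=0.0)
    n = G.n_individuals
    # sum |gi - gj| over shared loci via expansion on dosage indicator matrices
    D = np.zeros((n, n))
    overlap = called.astype(float) @ called.astype(float).T
    ind = {v: ((X == v) & called).astype(float) for v in (0.0, 1.0, 2.0)}
    absdiff = np.zeros((n, n))
    for a in (0.0, 1.0, 2.0):
        for b in (0.0, 1.0, 2.0):
            w = abs(a - b)
            if w:
                absdiff += w * (ind[a] @ ind[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = absdiff / (2.0 * overlap)
    low = overlap < min_overlap
    if low.any():
        np.fill_diagonal(low, False)
        if low.any():
            warnings.warn("some pairs fall below min_overlap; entries set to NaN")
            D[low] = np.nan
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=G.individual_ids, columns=G.individual_ids)
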