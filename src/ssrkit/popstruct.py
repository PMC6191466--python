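"""Weir-Cockerham F-statistics and distance-based AMOVA.

F_IS and F_ST are estimated with the Weir-Cockerham (1984) variance
components a (among groups), b (among individuals within groups) and c
(within individuals), computed per allele, summed within loci, and summed
across loci for the multilocus estimates:

    theta (F_ST) = sum a / sum (a + b + c)
    f     (F_IS) = 1 - sum c / sum (b + c)

The estimator assumes diploid genotypes; accessions with more than two
distinct alleles at a locus are reduced to two alleles sampled without
replacement under the run seed.  Significance comes from permutation:
individuals among groups for F_ST, allele copies among individuals within
groups for F_IS.  A jackknife over loci gives standard errors.

AMOVA partitions squared-Euclidean distances on the 0/1 allele-presence
encoding among and within groups; the Phi statistic is tested by permuting
individuals among groups.  The binary encoding makes the AMOVA agnostic to
ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import BinaryMatrix, GenotypeTable

__all__ = [
    "FStatResult",
    "AmovaResult",
    "weir_cockerham_fstats",
    "amova_distance",
]


@dataclass
class FStatResult:
    per_locus: pd.DataFrame       # locus, FIS, FST
    fis: float
    fst: float
    fis_se: float                 # jackknife over loci
    fst_se: float
    fst_p: float
    fis_p: float


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    var_among: float              # signed variance component
    var_within: float
    pct_among: float              # negative components truncated at 0
    pct_within: float
    phi: float
    p_value: float


# ---------------------------------------------------------------------------
# Weir-Cockerham

def _diploidized(table: GenotypeTable, rng: np.random.Generator
                 ) -> dict[tuple[str, str], tuple[int, int] | None]:
    """Two-allele genotypes per (accession, locus); polyploids subsampled."""
    out = {}
    for acc in table.accession_ids:
        for locus in table.loci:
            call = table.calls[(acc, locus)]
            if call.is_missing:
                out[(acc, locus)] = None
                continue
            sizes = call.sorted_sizes()
            if len(sizes) == 1:
                out[(acc, locus)] = (sizes[0], sizes[0])
            elif len(sizes) == 2:
                out[(acc, locus)] = (sizes[0], sizes[1])
            else:
                pick = rng.choice(len(sizes), size=2, replace=False)
                a, b = sorted(sizes[i] for i in pick)
                out[(acc, locus)] = (a, b)
    return out


def _wc_components(G: np.ndarray, grp: np.ndarray, r: int, n_alleles: int
                   ) -> tuple[float, float, float]:
    """Summed (a, b, c) over alleles at one locus.

    G is an (n, 2) array of allele codes for the typed individuals, grp the
    group index (0..r-1) of each.
    """
    n_i = np.bincount(grp, minlength=r).astype(float)
    if np.sum(n_i > 0) < 2 or n_i.max() < 2:
        return np.nan, np.nan, np.nan
    present = n_i > 0
    n_i = n_i[present]
    remap = np.cumsum(present) - 1
    grp = remap[grp]
    r_eff = len(n_i)
    if r_eff < 2:
        return np.nan, np.nan, np.nan
    nbar = n_i.mean()
    if nbar <= 1:
        return np.nan, np.nan, np.nan
    nc = (r_eff * nbar - (n_i**2).sum() / (r_eff * nbar)) / (r_eff - 1)
    nA = n_alleles
    cnt = (
        np.bincount(grp * nA + G[:, 0], minlength=r_eff * nA)
        + np.bincount(grp * nA + G[:, 1], minlength=r_eff * nA)
    ).reshape(r_eff, nA).astype(float)
    het = G[:, 0] != G[:, 1]
    hcnt = (
        np.bincount(grp[het] * nA + G[het, 0], minlength=r_eff * nA)
        + np.bincount(grp[het] * nA + G[het, 1], minlength=r_eff * nA)
    ).reshape(r_eff, nA).astype(float)
    p_i = cnt / (2 * n_i[:, None])
    h_i = hcnt / n_i[:, None]
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r_eff * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / \
        ((r_eff - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r_eff * nbar)
    a = nbar / nc * (
        s2 - 1.0 / (nbar - 1) * (
            pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2 - hbar / 4
        )
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def weir_cockerham_fstats(
    table: GenotypeTable,
    groups: dict[str, str],
    n_perm: int = 999,
    seed: int | None = 0,
) -> FStatResult:
    """Multilocus Weir-Cockerham F_IS and F_ST with permutation p-values."""
    rng = np.random.default_rng(seed)
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        n = sum(1 for a in groups if groups[a] == lab)
        if n < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 individuals")
    genos = _diploidized(table, rng)
    lab_code = {lab: i for i, lab in enumerate(labels)}
    accs = sorted(a for a in groups if a in set(table.accession_ids))
    grp_vec = np.array([lab_code[groups[a]] for a in accs])
    r = len(labels)

    # per-locus coded genotype arrays for the typed individuals
    locus_data: list[tuple[np.ndarray, np.ndarray, int]] = []
    for locus in table.loci:
        typed_idx, pairs = [], []
        codes = {a: i for i, a in enumerate(table.alleles_at(locus))}
        for k, acc in enumerate(accs):
            g = genos[(acc, locus)]
            if g is None:
                continue
            typed_idx.append(k)
            pairs.append((codes[g[0]], codes[g[1]]))
        locus_data.append((
            np.array(pairs, dtype=int).reshape(-1, 2),
            np.array(typed_idx, dtype=int),
            len(codes),
        ))

    def all_components(grp_assign: np.ndarray) -> np.ndarray:
        comps = []
        for G, typed, nA in locus_data:
            if len(typed) == 0 or nA < 2:
                comps.append((np.nan, np.nan, np.nan))
                continue
            comps.append(_wc_components(G, grp_assign[typed], r, nA))
        return np.array(comps)

    def _safe_fst(a, b, c):
        return a / (a + b + c) if (a + b + c) != 0 else np.nan

    def _safe_fis(b, c):
        return 1.0 - c / (b + c) if (b + c) != 0 else np.nan

    comps = all_components(grp_vec)
    ok = ~np.isnan(comps[:, 0])
    A, B, C = comps[ok].sum(axis=0)
    fst = _safe_fst(A, B, C)
    fis = _safe_fis(B, C)
    per_locus = pd.DataFrame({
        "locus": table.loci,
        "FIS": [
            1.0 - c / (b + c) if not np.isnan(a) and (b + c) != 0 else np.nan
            for a, b, c in comps
        ],
        "FST": [
            a / (a + b + c) if not np.isnan(a) and (a + b + c) != 0
            else np.nan
            for a, b, c in comps
        ],
    })

    # jackknife over loci
    idx = np.where(ok)[0]
    fst_jk, fis_jk = [], []
    for drop in idx:
        keep = comps[[i for i in idx if i != drop]]
        a, b, c = keep.sum(axis=0)
        fst_jk.append(_safe_fst(a, b, c))
        fis_jk.append(_safe_fis(b, c))
    L = len(idx)
    fst_se = float(np.sqrt((L - 1) / L * np.sum(
        (np.array(fst_jk) - np.mean(fst_jk)) ** 2)))
    fis_se = float(np.sqrt((L - 1) / L * np.sum(
        (np.array(fis_jk) - np.mean(fis_jk)) ** 2)))

    # F_ST: permute individuals among groups
    fst_ge = 0
    for _ in range(n_perm):
        pcomps = all_components(rng.permutation(grp_vec))
        pok = ~np.isnan(pcomps[:, 0])
        a, b, c = pcomps[pok].sum(axis=0)
        stat = _safe_fst(a, b, c)
        if not np.isnan(stat) and stat >= fst:
            fst_ge += 1
    fst_p = (fst_ge + 1) / (n_perm + 1)

    # F_IS: permute allele copies among individuals within groups
    fis_ge = 0
    for _ in range(n_perm):
        comps_p = []
        for G, typed, nA in locus_data:
            if len(typed) == 0 or nA < 2:
                continue
            Gp = G.copy()
            tg = grp_vec[typed]
            for gi in range(r):
                sel = np.where(tg == gi)[0]
                pool = Gp[sel].ravel()
                pool = rng.permutation(pool)
                Gp[sel] = pool.reshape(-1, 2)
            comps_p.append(_wc_components(Gp, tg, r, nA))
        arr = np.array(comps_p)
        pok = ~np.isnan(arr[:, 0])
        a, b, c = arr[pok].sum(axis=0)
        stat = _safe_fis(b, c)
        if not np.isnan(stat) and stat >= fis:
            fis_ge += 1
    fis_p = (fis_ge + 1) / (n_perm + 1)

    return FStatResult(per_locus, float(fis), float(fst),
                       fis_se, fst_se, fst_p, fis_p)


# ---------------------------------------------------------------------------
# AMOVA

def _ss_from_d2(d2: np.ndarray) -> float:
    n = d2.shape[0]
    return float(d2[np.triu_indices(n, 1)].sum() / n)


def amova_distance(
    matrix: BinaryMatrix,
    groups: dict[str, str],
    n_perm: int = 999,
    seed: int | None = 0,
) -> AmovaResult:
    """One-level AMOVA on squared Euclidean distances of binary rows."""
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    idx_of = {acc: i for i, acc in enumerate(matrix.rows)}
    members = {
        lab: [idx_of[a] for a in sorted(groups) if groups[a] == lab
              and a in idx_of]
        for lab in labels
    }
    if all(len(m) < 2 for m in members.values()):
        raise ValueError("all groups are singletons")
    used = sorted(i for m in members.values() for i in m)
    x = matrix.values[used].astype(float)
    g = x @ x.T
    d2 = np.maximum(np.diag(g)[:, None] + np.diag(g)[None, :] - 2 * g, 0.0)
    pos_of = {orig: k for k, orig in enumerate(used)}
    group_idx = [
        np.array([pos_of[i] for i in members[lab]]) for lab in labels
    ]
    N = len(used)
    r = len(labels)
    n_g = np.array([len(gi) for gi in group_idx], dtype=float)

    def phi_and_parts(group_idx):
        ss_total = _ss_from_d2(d2)
        ss_within = sum(
            _ss_from_d2(d2[np.ix_(gi, gi)]) for gi in group_idx
        )
        ss_among = ss_total - ss_within
        df_a, df_w = r - 1, N - r
        ms_a = ss_among / df_a
        ms_w = ss_within / df_w
        n0 = (N - (n_g**2).sum() / N) / (r - 1)
        var_w = ms_w
        var_a = (ms_a - ms_w) / n0
        denom = max(var_a, 0.0) + var_w
        phi = max(var_a, 0.0) / denom if denom > 0 else 0.0
        return phi, ss_among, ss_within, var_a, var_w, df_a, df_w

    phi, ss_a, ss_w, var_a, var_w, df_a, df_w = phi_and_parts(group_idx)

    rng = np.random.default_rng(seed)
    sizes = [len(gi) for gi in group_idx]
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        start = 0
        pidx = []
        for s in sizes:
            pidx.append(perm[start:start + s])
            start += s
        p_phi = phi_and_parts(pidx)[0]
        if p_phi >= phi:
            ge += 1
    p = (ge + 1) / (n_perm + 1)

    tot = max(var_a, 0.0) + var_w
    return AmovaResult(
        ss_among=ss_a, ss_within=ss_w, df_among=df_a, df_within=df_w,
        var_among=var_a, var_within=var_w,
        pct_among=100.0 * max(var_a, 0.0) / tot,
        pct_within=100.0 * var_w / tot,
        phi=phi, p_value=p,
    )
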