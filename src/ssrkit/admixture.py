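"""Bayesian admixture-model clustering of multilocus SSR genotypes.

The model assumes K ancestral clusters, each with its own allele
frequencies P_k at every locus in Hardy-Weinberg equilibrium, and gives
every individual a membership vector q_i over clusters (Dirichlet(alpha)
prior with a single symmetric concentration alpha).  Each allele copy
carries a latent origin z; the Gibbs sampler alternates

  z | q, P        (categorical per allele copy)
  P | z           (Dirichlet; under the correlated-frequency model the
                   prior is centred on the sample-wide ancestral
                   frequencies with a per-cluster drift parameter F_k,
                   updated by a Metropolis step)
  q | z, alpha    (Dirichlet(alpha + origin counts))
  alpha           (Metropolis random walk, uniform prior on (0, 10])

Diploids contribute two allele copies per locus (a singleton call counted
twice); an individual flagged polyploid contributes its observed distinct
alleles as copies, and any unobserved dosage slots (triploid with fewer
than three distinct alleles at a locus) are imputed each sweep by sampling
from the individual's observed allele set proportional to the current
cluster frequencies — a concrete realization of presence-only (recessive
allele) genotype handling.

Model choice across K uses the Evanno second-order statistic
Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) over replicate runs, and
individuals are assigned to their argmax cluster when the membership
coefficient q_I reaches a threshold (default 0.80), otherwise labelled
admixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable

__all__ = [
    "AdmixtureRun",
    "EvannoTable",
    "AssignmentResult",
    "run_admixture",
    "evanno_delta_k",
    "assign_memberships",
    "align_labels",
]

ALPHA_MAX = 10.0
ALPHA_STEP = 0.05
DRIFT_STEP = 0.02


@dataclass
class AdmixtureRun:
    K: int
    Q: pd.DataFrame                  # accessions x K posterior means
    P_state: pd.DataFrame            # (K x columns) posterior mean freqs
    alpha: float
    lnP_trace: np.ndarray = field(repr=False)
    mean_lnP: float = float("nan")
    seed: int = 0
    burn_in: int = 0
    n_iter: int = 0
    freq_model: str = "independent"


@dataclass
class EvannoTable:
    table: pd.DataFrame              # K, mean_L, sd_L, L1, absL2, deltaK
    best_k: int | None


@dataclass
class AssignmentResult:
    labels: pd.DataFrame             # accession_id, group, q_max, label
    threshold: float
    n_admixed: int


def _prepare_copies(table: GenotypeTable, polyploid_ids: set[str]):
    """Flatten the table into allele-copy arrays plus imputation slots."""
    columns: list[tuple[str, int]] = []
    seg_start: list[int] = []
    col_of: dict[tuple[str, int], int] = {}
    for locus in table.loci:
        seg_start.append(len(columns))
        for a in table.alleles_at(locus):
            col_of[(locus, a)] = len(columns)
            columns.append((locus, a))
    seg_start.append(len(columns))
    ind_idx, col_idx = [], []
    imputed: list[tuple[int, np.ndarray]] = []  # (individual, candidate cols)
    for i, acc in enumerate(table.accession_ids):
        ploidy = 3 if acc in polyploid_ids else 2
        for locus in table.loci:
            call = table.calls[(acc, locus)]
            if call.is_missing:
                continue
            sizes = call.sorted_sizes()
            cols = [col_of[(locus, a)] for a in sizes]
            if ploidy == 2:
                if len(sizes) == 1:
                    cols = cols * 2
                elif len(sizes) > 2:
                    cols = cols[:2]  # inconsistent diploid call: cap at 2
            else:
                for _ in range(max(ploidy - len(sizes), 0)):
                    imputed.append((i, np.array(cols)))
            ind_idx.extend([i] * len(cols))
            col_idx.extend(cols)
    return (
        np.array(ind_idx), np.array(col_idx), columns,
        np.array(seg_start), imputed,
    )


def _dirichlet_rows(rng, shape_mat: np.ndarray) -> np.ndarray:
    g = rng.gamma(np.maximum(shape_mat, 1e-9))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


def _normalize_segments(mat: np.ndarray, seg: np.ndarray) -> np.ndarray:
    sums = np.add.reduceat(mat, seg[:-1], axis=1)
    widths = np.diff(seg)
    denom = np.repeat(sums, widths, axis=1)
    return mat / np.maximum(denom, 1e-300)


def run_admixture(
    table: GenotypeTable,
    K: int,
    seed: int = 0,
    burn_in: int = 5_000,
    n_iter: int = 20_000,
    freq_model: str = "independent",
    polyploid_ids: set[str] | None = None,
) -> AdmixtureRun:
    """Gibbs sampler for the K-cluster admixture model.

    ``n_iter`` is the total chain length; posterior means use iterations
    after ``burn_in``.  ``polyploid_ids`` defaults to accessions whose
    metadata declares them polyploid.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_iter <= burn_in or n_iter <= 0:
        raise ValueError("need n_iter > burn_in > 0")
    if freq_model not in ("independent", "correlated"):
        raise ValueError(f"unknown freq_model {freq_model!r}")
    if polyploid_ids is None:
        polyploid_ids = {
            a.accession_id for a in table.accessions
            if a.declared_ploidy == "P"
        }
    rng = np.random.default_rng(seed)
    ind0, col0, columns, seg, imputed = _prepare_copies(table, polyploid_ids)
    n = table.n_accessions
    m = len(columns)
    # ancestral (sample-wide) frequencies for the correlated prior
    base_counts = np.bincount(col0, minlength=m).astype(float)
    p_anc = _normalize_segments(
        (base_counts + 1.0)[None, :], seg
    )[0]

    alpha = 1.0
    drift = np.full(K, 0.1)
    Q = np.full((n, K), 1.0 / K)
    if freq_model == "independent":
        lam = np.ones((K, m))
    else:
        lam = p_anc[None, :] * ((1 - drift) / drift)[:, None]
    P = _normalize_segments(_dirichlet_rows(rng, lam), seg)

    q_acc = np.zeros((n, K))
    p_acc = np.zeros((K, m))
    alpha_acc = 0.0
    n_kept = 0
    lnP_trace = np.empty(n_iter)

    for it in range(n_iter):
        # impute unobserved polyploid dosage slots from the observed set
        if imputed:
            extra_ind = np.empty(len(imputed), dtype=int)
            extra_col = np.empty(len(imputed), dtype=int)
            for s, (i, cand) in enumerate(imputed):
                w = Q[i] @ P[:, cand]
                w = np.maximum(w, 1e-300)
                extra_ind[s] = i
                extra_col[s] = cand[
                    rng.choice(len(cand), p=w / w.sum())
                ]
            ind = np.concatenate([ind0, extra_ind])
            col = np.concatenate([col0, extra_col])
        else:
            ind, col = ind0, col0

        # z | q, P
        probs = Q[ind, :] * P[:, col].T          # (copies, K)
        tot = probs.sum(axis=1, keepdims=True)
        probs /= np.maximum(tot, 1e-300)
        if K > 1:
            u = rng.random(len(ind))
            z = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            z = np.minimum(z, K - 1)
        else:
            z = np.zeros(len(ind), dtype=int)

        # P | z
        counts_p = np.bincount(z * m + col, minlength=K * m).reshape(K, m)
        if freq_model == "correlated":
            lam = p_anc[None, :] * ((1 - drift) / drift)[:, None]
        P = _normalize_segments(
            rng.gamma(np.maximum(lam + counts_p, 1e-9)), seg
        )
        P = np.maximum(P, 1e-300)

        # q | z, alpha
        counts_q = np.bincount(ind * K + z, minlength=n * K).reshape(n, K)
        if K > 1:
            Q = _dirichlet_rows(rng, alpha + counts_q)
        # alpha | q (Metropolis, uniform prior on (0, ALPHA_MAX])
        if K > 1:
            log_q_sum = float(np.log(np.maximum(Q, 1e-300)).sum())
            prop = alpha + rng.normal(0.0, ALPHA_STEP)
            if 0.0 < prop <= ALPHA_MAX:
                def logp(a: float) -> float:
                    return n * (
                        math.lgamma(K * a) - K * math.lgamma(a)
                    ) + (a - 1.0) * log_q_sum
                if math.log(rng.random() + 1e-300) < \
                        logp(prop) - logp(alpha):
                    alpha = prop
        # drift | P (Metropolis per cluster, correlated model)
        if freq_model == "correlated":
            logP = np.log(P)
            for k in range(K):
                f_cur = drift[k]
                f_prop = f_cur + rng.normal(0.0, DRIFT_STEP)
                if not 0.001 < f_prop < 0.99:
                    continue

                def logp_f(f: float) -> float:
                    lam_k = p_anc * (1 - f) / f
                    lam_seg = np.add.reduceat(lam_k, seg[:-1])
                    return float(
                        np.sum([math.lgamma(s) for s in lam_seg])
                        - np.sum([
                            math.lgamma(max(v, 1e-9)) for v in lam_k
                        ])
                        + np.sum((lam_k - 1.0) * logP[k])
                    )
                if math.log(rng.random() + 1e-300) < \
                        logp_f(f_prop) - logp_f(f_cur):
                    drift[k] = f_prop

        # data log-likelihood given current (Q, P), observed copies only
        mix = np.einsum("ck,ck->c", Q[ind0, :], P[:, col0].T)
        lnP_trace[it] = float(np.log(np.maximum(mix, 1e-300)).sum())

        if it >= burn_in:
            q_acc += Q
            p_acc += P
            alpha_acc += alpha
            n_kept += 1

    q_mean = q_acc / n_kept
    p_mean = p_acc / n_kept
    col_names = [f"{l}_{a}" for l, a in columns]
    return AdmixtureRun(
        K=K,
        Q=pd.DataFrame(
            q_mean, index=table.accession_ids,
            columns=[f"cluster_{k + 1}" for k in range(K)],
        ),
        P_state=pd.DataFrame(
            p_mean, index=[f"cluster_{k + 1}" for k in range(K)],
            columns=col_names,
        ),
        alpha=alpha_acc / n_kept,
        lnP_trace=lnP_trace,
        mean_lnP=float(lnP_trace[burn_in:].mean()),
        seed=seed, burn_in=burn_in, n_iter=n_iter, freq_model=freq_model,
    )


def evanno_delta_k(
    mean_lnp_by_k: dict[int, list[float]],
) -> EvannoTable:
    """Evanno Delta-K table from replicate mean log-likelihoods per K.

    Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), defined on interior K
    with positive replicate sd; best K maximizes Delta K.
    """
    ks = sorted(mean_lnp_by_k)
    if len(ks) < 3:
        raise ValueError("need runs for at least 3 consecutive K values")
    for k in ks:
        if len(mean_lnp_by_k[k]) < 1:
            raise ValueError(f"no runs for K={k}")
    L = {k: float(np.mean(mean_lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(mean_lnp_by_k[k], ddof=1))
          if len(mean_lnp_by_k[k]) > 1 else 0.0 for k in ks}
    rows = []
    for i, k in enumerate(ks):
        l1 = L[k] - L[ks[i - 1]] if i > 0 else np.nan
        if 0 < i < len(ks) - 1:
            l2 = abs(L[ks[i + 1]] - 2 * L[k] + L[ks[i - 1]])
            dk = l2 / sd[k] if sd[k] > 0 else np.nan
        else:
            l2, dk = np.nan, np.nan
        rows.append({
            "K": k, "mean_L": L[k], "sd_L": sd[k],
            "L_prime": l1, "abs_L_doubleprime": l2, "delta_K": dk,
        })
    df = pd.DataFrame(rows)
    valid = df.dropna(subset=["delta_K"])
    best = int(valid.loc[valid["delta_K"].idxmax(), "K"]) \
        if len(valid) and valid["delta_K"].max() > 0 else None
    return EvannoTable(df, best)


def assign_memberships(run: AdmixtureRun,
                       threshold: float = 0.80) -> AssignmentResult:
    """Assign each accession to its argmax cluster at q_I >= threshold."""
    q = run.Q.to_numpy()
    argmax = q.argmax(axis=1)
    qmax = q.max(axis=1)
    labels = [
        run.Q.columns[a] if qm >= threshold else "admixture"
        for a, qm in zip(argmax, qmax)
    ]
    df = pd.DataFrame({
        "accession_id": run.Q.index,
        "group": [run.Q.columns[a] for a in argmax],
        "q_max": qmax,
        "label": labels,
    })
    return AssignmentResult(
        df, threshold, int(sum(x == "admixture" for x in labels))
    )


def align_labels(reference: pd.DataFrame, other: pd.DataFrame) -> list[int]:
    """Greedy column matching of two Q matrices by correlation.

    Returns ``perm`` with ``other.iloc[:, perm[k]]`` matching reference
    column k (for reporting across label-switched replicate runs).
    """
    K = reference.shape[1]
    corr = np.zeros((K, K))
    a = reference.to_numpy()
    b = other.to_numpy()
    for i in range(K):
        for j in range(K):
            sa, sb = np.std(a[:, i]), np.std(b[:, j])
            if sa == 0 or sb == 0:
                corr[i, j] = -np.inf if i != j else 0.0
                continue
            corr[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    perm = [-1] * K
    used: set[int] = set()
    for i, j in sorted(
        ((i, j) for i in range(K) for j in range(K)),
        key=lambda t: -corr[t[0], t[1]],
    ):
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return perm
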