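"""Spearman rank-correlation screens of allele presence against traits.

Every (locus, allele) presence column of the binary encoding is correlated
with every ordinal morphological trait (Spearman with midrank ties,
pairwise-complete observations).  P-values use the t approximation, with an
optional seeded Monte-Carlo permutation test for small samples; screening
follows the raw-p convention at alpha = 0.001 by default, with
Benjamini-Hochberg adjustment available for the full allele x trait family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import BinaryMatrix

__all__ = [
    "AssociationResult",
    "allele_trait_correlations",
    "trait_trait_correlations",
]


@dataclass
class AssociationResult:
    locus_allele: str
    trait: str
    n: int
    r: float
    p: float
    passed: bool
    skipped_reason: str | None = None


def _spearman(x: np.ndarray, y: np.ndarray, exact_perm: bool,
              n_perm: int, rng: np.random.Generator
              ) -> tuple[float, float]:
    r, p = stats.spearmanr(x, y)
    if exact_perm:
        obs = abs(r)
        hits = 0
        for _ in range(n_perm):
            rp, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(rp) >= obs - 1e-15:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return float(r), float(p)


def allele_trait_correlations(
    matrix: BinaryMatrix,
    traits: pd.DataFrame,
    alpha: float = 0.001,
    adjust: str = "none",
    small_n_perm: int = 2000,
    seed: int = 0,
) -> list[AssociationResult]:
    """Screen every allele-presence column against every trait column.

    ``traits`` is indexed by accession id with one ordinal column per
    trait; missing scores are allowed.  Samples smaller than 30 use a
    seeded permutation p-value instead of the t approximation.  ``adjust``
    is "none" (raw-p screening) or "BH".
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    common = [a for a in matrix.rows if a in traits.index]
    if len(common) < 10:
        raise ValueError("need >= 10 accessions with both data types")
    rng = np.random.default_rng(seed)
    frame = matrix.to_frame().loc[common]
    miss = pd.DataFrame(
        matrix.missing_mask, index=matrix.rows,
        columns=frame.columns,
    ).loc[common]
    results: list[AssociationResult] = []
    for col in frame.columns:
        presence_all = frame[col].to_numpy(dtype=float)
        missing_col = miss[col].to_numpy()
        for trait in traits.columns:
            scores = traits.loc[common, trait].to_numpy(dtype=float)
            okay = ~np.isnan(scores) & ~missing_col
            x = presence_all[okay]
            y = scores[okay]
            n = len(x)
            if n < 3 or np.all(x == x[0]):
                results.append(AssociationResult(
                    col, trait, n, float("nan"), float("nan"), False,
                    "constant allele column" if n >= 3 else "too few data",
                ))
                continue
            if np.all(y == y[0]):
                results.append(AssociationResult(
                    col, trait, n, float("nan"), float("nan"), False,
                    "constant trait",
                ))
                continue
            r, p = _spearman(
                x, y, exact_perm=n < 30, n_perm=small_n_perm, rng=rng
            )
            results.append(AssociationResult(col, trait, n, r, p, False))
    tested = [a for a in results if a.skipped_reason is None]
    if adjust == "BH" and tested:
        ps = np.array([a.p for a in tested])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank, i in enumerate(reversed(order), start=1):
            running = min(running, ps[i] * m / (m - rank + 1))
            adj[i] = running
        for a, q in zip(tested, adj):
            a.passed = bool(q <= alpha)
    else:
        for a in tested:
            a.passed = bool(a.p <= alpha)
    return results


def trait_trait_correlations(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman (r, p) among traits, pairwise-complete."""
    cols = list(traits.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 traits")
    rows = []
    for i, t1 in enumerate(cols):
        for t2 in cols[i:]:
            x = traits[t1].to_numpy(dtype=float)
            y = traits[t2].to_numpy(dtype=float)
            okay = ~np.isnan(x) & ~np.isnan(y)
            if t1 == t2:
                rows.append({"trait_1": t1, "trait_2": t2, "n": okay.sum(),
                             "r": 1.0, "p": 0.0})
                continue
            r, p = stats.spearmanr(x[okay], y[okay])
            rows.append({"trait_1": t1, "trait_2": t2,
                         "n": int(okay.sum()),
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
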