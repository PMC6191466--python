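"""Per-locus and aggregate SSR diversity statistics.

For each locus the module computes the observed allele count (Na), effective
allele count (Ne = 1/Sum p_i^2), percentage of rare alleles (frequency
< 0.01), observed and expected heterozygosity (Ho, He), the fixation index
F = 1 - Ho/He, the polymorphic information content

    PIC = 1 - Sum p_i^2 - (Sum p_i^2)^2 + Sum p_i^4,

the probability of identity between two unrelated individuals drawn from a
Hardy-Weinberg population

    P_ID = Sum p_i^4 + Sum_{i<j} (2 p_i p_j)^2,

the probability of identity among full sibs

    P_IDsib = 0.25 + 0.5 Sum p_i^2 + 0.5 (Sum p_i^2)^2 - 0.25 Sum p_i^4,

and the power of discrimination PD = 1 - P_ID.  Multilocus P_ID values are
products over loci (independent loci).

Allele frequencies weight each individual's distinct alleles by presence:
a diploid contributes two observations (a singleton counted twice, i.e.
homozygous), an individual with k >= 3 distinct alleles contributes one
observation per distinct allele because dosage is unknown.

Also provided: a seeded Monte-Carlo exact test of Hardy-Weinberg equilibrium
on the diploid subset, and a null-allele screen based on the heterozygote
deficit estimator r = (He - Ho) / (1 + He) with a bootstrap confidence
interval over individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "LocusDiversity",
    "allele_frequencies",
    "locus_diversity",
    "combined_pid",
    "hwe_test",
    "null_allele_screen",
    "diversity_table",
]

RARE_FREQ = 0.01


@dataclass
class AlleleFrequencies:
    locus_id: str
    freq: dict[int, float]
    n_obs: int

    def vector(self) -> np.ndarray:
        return np.array([self.freq[a] for a in sorted(self.freq)])


@dataclass
class LocusDiversity:
    locus_id: str
    size_range: tuple[int, int]
    Na: int
    Ne: float
    RA: float
    Ho: float
    He: float
    F: float  # NaN when He == 0
    PIC: float
    PID: float
    PIDsib: float
    PD: float
    hwe_p: float  # NaN when untestable
    null_freq: float
    null_flag: bool


def allele_frequencies(table: GenotypeTable, locus: str) -> AlleleFrequencies:
    """Presence-weighted allele frequencies at one locus."""
    if locus not in table.loci:
        raise KeyError(f"locus {locus!r} not in table")
    counts: dict[int, int] = {}
    n_obs = 0
    for acc in table.accession_ids:
        call = table.calls[(acc, locus)]
        if call.is_missing:
            continue
        sizes = call.sorted_sizes()
        if len(sizes) == 1:  # diploid homozygote: two copies
            counts[sizes[0]] = counts.get(sizes[0], 0) + 2
            n_obs += 2
        else:
            for a in sizes:
                counts[a] = counts.get(a, 0) + 1
            n_obs += len(sizes)
    if n_obs == 0:
        raise ValueError(f"locus {locus!r} entirely missing")
    freq = {a: c / n_obs for a, c in sorted(counts.items())}
    return AlleleFrequencies(locus, freq, n_obs)


def _pid_formulas(p: np.ndarray) -> tuple[float, float, float]:
    """(PIC, P_ID, P_IDsib) from a frequency vector."""
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    pic = 1.0 - s2 - s2**2 + s4
    # Sum_{i<j} (2 p_i p_j)^2 = 2 * (s2^2 - s4) ... since
    # (Sum p^2)^2 = Sum p^4 + 2 Sum_{i<j} p_i^2 p_j^2
    pid = s4 + 2.0 * (s2**2 - s4)
    pidsib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return pic, pid, pidsib


def locus_diversity(
    freqs: AlleleFrequencies,
    table: GenotypeTable,
    locus: str,
    hwe_reps: int = 2000,
    null_boot: int = 1000,
    seed: int | None = 0,
) -> LocusDiversity:
    """All per-locus diversity statistics from frequencies plus the table."""
    if freqs.locus_id != locus:
        raise ValueError("frequency record is for a different locus")
    p = freqs.vector()
    alleles = sorted(freqs.freq)
    na = len(alleles)
    s2 = float(np.sum(p**2))
    ne = 1.0 / s2
    he = 1.0 - s2
    n_typed = 0
    n_het = 0
    for acc in table.accession_ids:
        call = table.calls[(acc, locus)]
        if call.is_missing:
            continue
        n_typed += 1
        if len(call.sizes) >= 2:
            n_het += 1
    ho = n_het / n_typed
    f = 1.0 - ho / he if he > 0 else float("nan")
    pic, pid, pidsib = _pid_formulas(p)
    ra = 100.0 * sum(1 for a in alleles if freqs.freq[a] < RARE_FREQ) / na
    rng = np.random.default_rng(seed)
    hwe_p = hwe_test(table, locus, n_mc=hwe_reps,
                     seed=int(rng.integers(2**31)))
    null_freq, null_flag = null_allele_screen(
        table, locus, n_boot=null_boot, seed=int(rng.integers(2**31))
    )
    return LocusDiversity(
        locus_id=locus,
        size_range=(min(alleles), max(alleles)),
        Na=na, Ne=ne, RA=ra, Ho=ho, He=he, F=f,
        PIC=pic, PID=pid, PIDsib=pidsib, PD=1.0 - pid,
        hwe_p=hwe_p, null_freq=null_freq, null_flag=null_flag,
    )


def combined_pid(per_locus: list[LocusDiversity]) -> tuple[float, float]:
    """Multilocus (P_ID, P_IDsib): products across independent loci."""
    if not per_locus:
        raise ValueError("need at least one locus")
    pid = math.prod(d.PID for d in per_locus)
    pidsib = math.prod(d.PIDsib for d in per_locus)
    return pid, pidsib


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo)

def _diploid_genotypes(table: GenotypeTable, locus: str) -> list[tuple[int, int]]:
    out = []
    for acc in table.accession_ids:
        call = table.calls[(acc, locus)]
        if call.is_missing or len(call.sizes) > 2:
            continue  # polyploids excluded: dosage unknown
        s = call.sorted_sizes()
        out.append((s[0], s[-1]))
    return out


def _log_cond_prob(genos: np.ndarray, n_alleles: int) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Up to a constant depending only on allele counts:
    log P ∝ n_het * log 2 - sum_g log(count_g!).
    """
    n_het = int(np.sum(genos[:, 0] != genos[:, 1]))
    pairs = genos[:, 0] * n_alleles + genos[:, 1]
    _, counts = np.unique(pairs, return_counts=True)
    return n_het * math.log(2.0) - float(
        sum(math.lgamma(c + 1) for c in counts)
    )


def hwe_test(table: GenotypeTable, locus: str, n_mc: int = 2000,
             seed: int | None = 0) -> float:
    """Monte-Carlo exact HWE test on the diploid subset at one locus.

    Permutes the pooled allele copies into genotype pairs and compares the
    conditional probability of each permuted genotype array with the
    observed one; less-or-equally probable tables count toward p.  Returns
    NaN when fewer than 5 diploids are typed or the locus is monomorphic
    among them.
    """
    genos = _diploid_genotypes(table, locus)
    if len(genos) < 5:
        return float("nan")
    alleles = sorted({a for g in genos for a in g})
    if len(alleles) < 2:
        return float("nan")
    code = {a: i for i, a in enumerate(alleles)}
    g = np.array([[code[a], code[b]] for a, b in genos])
    g.sort(axis=1)
    n_alleles = len(alleles)
    obs = _log_cond_prob(g, n_alleles)
    pool = g.ravel().copy()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        sim = pool.reshape(-1, 2).copy()
        sim.sort(axis=1)
        if _log_cond_prob(sim, n_alleles) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# null-allele screen (heterozygote deficit + bootstrap)

def _ho_he_from_calls(calls: list[frozenset[int]]) -> tuple[float, float]:
    counts: dict[int, int] = {}
    n_obs = 0
    n_het = 0
    for s in calls:
        sizes = sorted(s)
        if len(sizes) == 1:
            counts[sizes[0]] = counts.get(sizes[0], 0) + 2
            n_obs += 2
        else:
            n_het += 1
            for a in sizes:
                counts[a] = counts.get(a, 0) + 1
            n_obs += len(sizes)
    ho = n_het / len(calls)
    he = 1.0 - sum((c / n_obs) ** 2 for c in counts.values())
    return ho, he


def null_allele_screen(table: GenotypeTable, locus: str, n_boot: int = 1000,
                       seed: int | None = 0) -> tuple[float, bool]:
    """Heterozygote-deficit null-allele estimate with a bootstrap flag.

    Estimator r = (He - Ho) / (1 + He) on the diploid calls; the flag is
    True when the bootstrap 95% percentile interval (resampling
    individuals) excludes 0.  A monomorphic locus returns (0.0, False).
    """
    calls = [
        table.calls[(acc, locus)].sizes
        for acc in table.accession_ids
        if not table.calls[(acc, locus)].is_missing
        and len(table.calls[(acc, locus)].sizes) <= 2
    ]
    if not calls:
        return 0.0, False
    ho, he = _ho_he_from_calls(calls)
    if he <= 0:
        return 0.0, False
    r_hat = (he - ho) / (1.0 + he)
    if n_boot <= 0:
        return r_hat, False
    rng = np.random.default_rng(seed)
    n = len(calls)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bho, bhe = _ho_he_from_calls([calls[i] for i in idx])
        reps[b] = (bhe - bho) / (1.0 + bhe) if bhe > 0 else 0.0
    lo, hi = np.percentile(reps, [2.5, 97.5])
    flag = bool(lo > 0.0 or hi < 0.0) and r_hat > 0
    return r_hat, flag


# ---------------------------------------------------------------------------
# full table

def diversity_table(table: GenotypeTable, hwe_reps: int = 2000,
                    null_boot: int = 1000, seed: int | None = 0
                    ) -> pd.DataFrame:
    """Per-locus diversity report plus mean and total rows.

    The mean row averages Na, Ne, Ho, He, F and PIC arithmetically; the
    total row carries the summed allele count and the multilocus P_ID and
    P_IDsib products.
    """
    rng = np.random.default_rng(seed)
    records: list[LocusDiversity] = []
    for locus in table.loci:
        freqs = allele_frequencies(table, locus)
        records.append(
            locus_diversity(freqs, table, locus, hwe_reps=hwe_reps,
                            null_boot=null_boot,
                            seed=int(rng.integers(2**31)))
        )
    rows = []
    for d in records:
        row = asdict(d)
        row["size_range"] = f"{d.size_range[0]}-{d.size_range[1]}"
        rows.append(row)
    df = pd.DataFrame(rows)
    pid_tot, pidsib_tot = combined_pid(records)
    mean_row = {"locus_id": "Mean"}
    for colname in ("Na", "Ne", "Ho", "He", "F", "PIC"):
        mean_row[colname] = float(np.nanmean(df[colname].astype(float)))
    total_row = {"locus_id": "Total", "Na": int(df["Na"].sum()),
                 "PID": pid_tot, "PIDsib": pidsib_tot}
    return pd.concat(
        [df, pd.DataFrame([mean_row, total_row])], ignore_index=True
    )
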