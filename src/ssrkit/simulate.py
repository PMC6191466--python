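"""Synthetic germplasm collections with known ground truth.

The generator emulates the statistical structure of a mixed-ploidy SSR
fingerprinting panel: ~19 unlinked loci with 5-26 alleles each, 2-5
subpopulations whose allele frequencies are drawn from the Balding-Nichols
distribution around a common ancestral frequency vector at a chosen F_ST,
Hardy-Weinberg diploid founders within subpopulations, triploids formed by
an unreduced (two-allele) gamete plus a normal gamete, exact clone copies,
Mendelian offspring of named founder pairs, and ordinal morphological trait
scores with planted allele effects.  Genotyping error (random allele
mistyping) and missing data are injected last, after clones are copied, so
the truth manifest always refers to the error-free profiles.

Every run is fully determined by the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import AccessionRecord, AlleleCall, GenotypeTable

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "simulate_collection",
    "truth_report",
    "TRAIT_LEVELS",
]

#: Ordinal coding of the morphological traits (score levels).
TRAIT_LEVELS: dict[str, tuple[float, ...]] = {
    "maturity": (1, 3, 5, 7),
    "fruit_shape": (1, 2, 3, 4, 5, 6, 7),
    "ground_color": (1, 3, 5),
    "over_color": (1, 3, 5, 7, 9),
    "rustiness": (1, 9),
    "pulp_color": (1, 3, 5, 7),
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic collection.

    Defaults emulate the apple study panel: 19 loci with 5-26 alleles,
    a 20% triploid fraction and subpopulations differentiated at
    F_ST ~ 0.15.
    """

    seed: int
    n_loci: int = 19
    alleles_per_locus: tuple[int, int] = (5, 26)
    n_subpops: int = 3
    fst_target: float = 0.15
    n_founders: int = 30          # per subpopulation
    n_clone_groups: int = 0
    clone_copies: int = 2         # group size (source + copies-1)
    triploid_fraction: float = 0.2
    n_offspring: int = 0
    missing_rate: float = 0.0
    mistyping_rate: float = 0.0
    trait_effects: list[tuple[str, int, str, float]] = field(
        default_factory=list
    )
    make_traits: bool = False

    def __post_init__(self) -> None:
        for name in ("fst_target", "triploid_fraction", "missing_rate",
                     "mistyping_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 or (name == "fst_target" and v >= 1.0):
                raise ValueError(f"{name}={v} out of range")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_loci < 1 or self.n_subpops < 1 or self.n_founders < 1:
            raise ValueError("counts must be positive")
        if self.n_clone_groups * max(self.clone_copies - 1, 0) > \
                self.n_subpops * self.n_founders:
            raise ValueError("clone copies exceed available accessions")


@dataclass
class TruthManifest:
    """Ground truth of a simulated collection."""

    clone_groups: list[list[str]]
    true_ploidy: dict[str, int]
    pedigree: dict[str, tuple[str, str]]
    subpop_label: dict[str, int]
    ancestral_freqs: dict[str, dict[int, float]]
    subpop_freqs: dict[int, dict[str, dict[int, float]]]
    trait_linked: list[tuple[str, int, str, float]]


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    g = rng.gamma(np.maximum(alpha, 1e-12))
    g = np.maximum(g, 1e-300)
    return g / g.sum()


def simulate_collection(
    config: SimulationConfig,
) -> tuple[GenotypeTable, pd.DataFrame | None, TruthManifest]:
    """Generate (genotypes, traits, truth) for one synthetic collection."""
    rng = np.random.default_rng(config.seed)
    loci = [f"L{j:02d}" for j in range(1, config.n_loci + 1)]

    # allele panels and ancestral frequencies (symmetric Dirichlet(1))
    lo, hi = config.alleles_per_locus
    panel: dict[str, np.ndarray] = {}
    anc: dict[str, np.ndarray] = {}
    for j, locus in enumerate(loci):
        n_all = int(rng.integers(lo, hi + 1))
        base = 80 + 10 * j
        panel[locus] = base + 2 * np.arange(n_all)
        anc[locus] = _dirichlet(rng, np.ones(n_all))

    # Balding-Nichols subpopulation frequencies
    f = config.fst_target
    sub: dict[int, dict[str, np.ndarray]] = {}
    for s in range(config.n_subpops):
        sub[s] = {}
        for locus in loci:
            if f == 0.0:
                sub[s][locus] = anc[locus].copy()
            else:
                sub[s][locus] = _dirichlet(
                    rng, anc[locus] * (1.0 - f) / f
                )

    def draw_allele(s: int, locus: str) -> int:
        p = sub[s][locus]
        return int(panel[locus][rng.choice(len(p), p=p)])

    # diploid founders (HWE within subpop), some promoted to triploids
    genotypes: dict[str, dict[str, tuple[int, ...]]] = {}
    subpop_label: dict[str, int] = {}
    true_ploidy: dict[str, int] = {}
    names: dict[str, str] = {}
    statuses: dict[str, str] = {}
    order: list[str] = []
    idx = 0
    for s in range(config.n_subpops):
        for _ in range(config.n_founders):
            idx += 1
            acc = f"A{idx:04d}"
            geno = {
                locus: (draw_allele(s, locus), draw_allele(s, locus))
                for locus in loci
            }
            if rng.random() < config.triploid_fraction:
                # unreduced gamete (both alleles) + one normal gamete
                geno = {
                    locus: geno[locus] + (draw_allele(s, locus),)
                    for locus in loci
                }
                true_ploidy[acc] = 3
            else:
                true_ploidy[acc] = 2
            genotypes[acc] = geno
            subpop_label[acc] = s
            names[acc] = f"Var{idx:04d}"
            statuses[acc] = "LV"
            order.append(acc)

    founders = list(order)

    # offspring: Mendelian gametes from two distinct diploid founder parents
    pedigree: dict[str, tuple[str, str]] = {}
    diploid_founders = [a for a in founders if true_ploidy[a] == 2]
    for _ in range(config.n_offspring):
        if len(diploid_founders) < 2:
            raise ValueError("not enough diploid founders for offspring")
        i1, i2 = rng.choice(len(diploid_founders), size=2, replace=False)
        p1, p2 = diploid_founders[i1], diploid_founders[i2]
        idx += 1
        acc = f"A{idx:04d}"
        geno = {}
        for locus in loci:
            g1 = genotypes[p1][locus]
            g2 = genotypes[p2][locus]
            geno[locus] = (g1[rng.integers(2)], g2[rng.integers(2)])
        genotypes[acc] = geno
        true_ploidy[acc] = 2
        subpop_label[acc] = subpop_label[p1]
        names[acc] = "Unknown"
        statuses[acc] = "UA"
        pedigree[acc] = (p1, p2)
        order.append(acc)

    # clone groups: exact copies of distinct source accessions
    clone_groups: list[list[str]] = []
    if config.n_clone_groups > 0:
        sources = rng.choice(
            len(founders), size=config.n_clone_groups, replace=False
        )
        for si in sources:
            src = founders[si]
            group = [src]
            for _ in range(config.clone_copies - 1):
                idx += 1
                acc = f"A{idx:04d}"
                genotypes[acc] = {
                    locus: genotypes[src][locus] for locus in loci
                }
                true_ploidy[acc] = true_ploidy[src]
                subpop_label[acc] = subpop_label[src]
                names[acc] = names[src]  # same name: duplicates
                statuses[acc] = statuses[src]
                order.append(acc)
                group.append(acc)
            clone_groups.append(sorted(group))

    # error injection: mistyping then missingness
    calls: dict[tuple[str, str], AlleleCall] = {}
    for acc in order:
        for locus in loci:
            alleles = list(genotypes[acc][locus])
            if config.mistyping_rate > 0 and \
                    rng.random() < config.mistyping_rate:
                slot = int(rng.integers(len(alleles)))
                alleles[slot] = int(
                    panel[locus][rng.integers(len(panel[locus]))]
                )
            if config.missing_rate > 0 and \
                    rng.random() < config.missing_rate:
                call = AlleleCall(locus)
            else:
                call = AlleleCall(locus, frozenset(alleles))
            calls[(acc, locus)] = call

    records = [
        AccessionRecord(
            acc, names[acc], "c01", statuses[acc],
            "P" if true_ploidy[acc] > 2 else "D",
        )
        for acc in order
    ]
    table = GenotypeTable(records, loci, calls)

    traits = None
    if config.make_traits or config.trait_effects:
        traits = _simulate_traits(table, config, rng)

    manifest = TruthManifest(
        clone_groups=clone_groups,
        true_ploidy=true_ploidy,
        pedigree=pedigree,
        subpop_label=subpop_label,
        ancestral_freqs={
            locus: {int(a): float(p) for a, p in
                    zip(panel[locus], anc[locus])}
            for locus in loci
        },
        subpop_freqs={
            s: {locus: {int(a): float(p) for a, p in
                        zip(panel[locus], sub[s][locus])}
                for locus in loci}
            for s in range(config.n_subpops)
        },
        trait_linked=list(config.trait_effects),
    )
    return table, traits, manifest


def _simulate_traits(table: GenotypeTable, config: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Ordinal trait scores: thresholded latent normal + planted effects.

    The latent score for a trait is standard normal noise plus
    effect * presence for every planted (locus, allele, trait, effect);
    scores are then binned by equal-probability thresholds onto the trait's
    ordinal levels, so planted effects shift individuals monotonically
    across categories.
    """
    n = table.n_accessions
    out = {}
    for trait, levels in TRAIT_LEVELS.items():
        latent = rng.standard_normal(n)
        for locus, allele, t, effect in config.trait_effects:
            if t != trait:
                continue
            presence = np.array([
                1.0 if allele in table.calls[(acc, locus)].sizes else 0.0
                for acc in table.accession_ids
            ])
            latent = latent + effect * presence
        cuts = np.quantile(
            rng.standard_normal(4096),
            np.linspace(0, 1, len(levels) + 1)[1:-1],
        )
        out[trait] = [
            float(levels[int(np.searchsorted(cuts, v))]) for v in latent
        ]
    df = pd.DataFrame(out, index=table.accession_ids)
    df.index.name = "accession_id"
    return df


def truth_report(manifest: TruthManifest) -> str:
    """Serialize the manifest as JSON with stable key order."""
    d = asdict(manifest)
    # json keys must be strings; keep per-locus frequency sums at 1
    d["subpop_freqs"] = {
        str(s): v for s, v in sorted(d["subpop_freqs"].items())
    }
    return json.dumps(d, sort_keys=True, indent=1)
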