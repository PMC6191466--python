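"""End-to-end orchestration of the SSR characterization workflow.

The stage order follows the analysis logic of a germplasm characterization
study: null-allele screen and diversity statistics on the raw table, clone
detection and deduplication, Ward clustering and admixture on the reduced
table, F-statistics and AMOVA on the admixture-assigned groups, parentage
scanning of unknown accessions, and the allele-trait screen.  Loci flagged
by the null-allele screen are excluded from downstream stages by default.

A run is fully determined by its config (including the global seed); the
manifest written alongside the outputs records inputs, parameters and seeds
so any output can be reproduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import admixture, clustering, diversity, identity, parentage, \
    popstruct, traits as traits_mod
from .genotype_io import GenotypeTable, encode_binary, read_genotypes

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = (
    "diversity", "dedup", "cluster", "admixture", "fstats", "amova",
    "parentage", "traits",
)


@dataclass
class PipelineConfig:
    genotypes: str
    out_dir: str
    seed: int = 0
    traits_path: str | None = None
    stages: tuple[str, ...] = STAGES
    exclude_null_loci: bool = True
    min_compared_loci: int = 15
    qi_threshold: float = 0.80
    admixture_k: int = 3
    burn_in: int = 500
    n_iter: int = 2_000
    n_boot: int = 100
    n_perm: int = 199
    lod_n_sim: int = 20_000
    lod_epsilon: float = 0.001
    group_labels: dict[str, str] | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_genotypes(config.genotypes)
    manifest: dict = {
        "inputs": {"genotypes": str(config.genotypes),
                   "traits": config.traits_path},
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("extra", "group_labels")
        },
        "stages_run": [],
        "outputs": {},
    }

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"][name] = str(path)

    excluded_loci: list[str] = []
    if "diversity" in config.stages:
        div = diversity.diversity_table(
            table, hwe_reps=500, null_boot=200, seed=config.seed
        )
        save("diversity.csv", div)
        flagged = div.loc[
            div["null_flag"].map(lambda v: bool(v) and v == v), "locus_id"
        ].tolist()
        manifest["null_flagged_loci"] = flagged
        if config.exclude_null_loci and flagged:
            excluded_loci = flagged
        manifest["stages_run"].append("diversity")

    if excluded_loci:
        keep = [l for l in table.loci if l not in excluded_loci]
        calls = {
            (a, l): table.calls[(a, l)]
            for a in table.accession_ids for l in keep
        }
        table = GenotypeTable(table.accessions, keep, calls)
        manifest["excluded_loci"] = excluded_loci

    clone_groups: list[list[str]] = []
    if "dedup" in config.stages:
        report = identity.find_identical_profiles(
            table, min_compared_loci=min(config.min_compared_loci,
                                         table.n_loci)
        )
        report, homonyms = identity.classify_relations(report, table)
        clone_groups = report.groups
        ploidy = identity.classify_ploidy(table)
        table, removed = identity.deduplicate(table, report)
        pairs = pd.DataFrame([
            {"a": a, "b": b, "label": lab}
            for (a, b), lab in sorted(report.pair_labels.items())
        ])
        save("clone_pairs.csv", pairs if len(pairs) else
             pd.DataFrame(columns=["a", "b", "label"]))
        save("ploidy.csv", pd.DataFrame([asdict(p) for p in ploidy]))
        (out / "removed_ids.txt").write_text("\n".join(removed) + "\n")
        manifest["outputs"]["removed_ids.txt"] = str(out / "removed_ids.txt")
        manifest["n_removed_duplicates"] = len(removed)
        manifest["n_homonyms"] = len(homonyms)
        manifest["stages_run"].append("dedup")

    matrix = encode_binary(table)

    if "cluster" in config.stages:
        root = clustering.bootstrap_support(
            matrix, n_boot=config.n_boot, seed=config.seed
        )
        (out / "dendrogram.nwk").write_text(clustering.to_newick(root))
        manifest["outputs"]["dendrogram.nwk"] = str(out / "dendrogram.nwk")
        labels = clustering.cut_clusters(root, k=config.admixture_k)
        save("ward_clusters.csv", pd.DataFrame(
            sorted(labels.items()), columns=["accession_id", "cluster"]
        ))
        manifest["stages_run"].append("cluster")

    groups = dict(config.group_labels or {})
    if "admixture" in config.stages:
        run = admixture.run_admixture(
            table, K=config.admixture_k, seed=config.seed,
            burn_in=config.burn_in, n_iter=config.n_iter,
        )
        qdf = run.Q.reset_index(names="accession_id")
        save("q_matrix.csv", qdf)
        assign = admixture.assign_memberships(run, config.qi_threshold)
        save("assignments.csv", assign.labels)
        manifest["n_admixed"] = assign.n_admixed
        if not groups:
            groups = {
                row.accession_id: row.label
                for row in assign.labels.itertuples()
                if row.label != "admixture"
            }
        manifest["stages_run"].append("admixture")

    if groups and len(set(groups.values())) >= 2:
        if "fstats" in config.stages:
            fres = popstruct.weir_cockerham_fstats(
                table, groups, n_perm=config.n_perm, seed=config.seed
            )
            save("fstats_per_locus.csv", fres.per_locus)
            manifest["fst"] = fres.fst
            manifest["fis"] = fres.fis
            manifest["fst_p"] = fres.fst_p
            manifest["stages_run"].append("fstats")
        if "amova" in config.stages:
            sub = matrix  # AMOVA ignores accessions without a group label
            ares = popstruct.amova_distance(
                sub, groups, n_perm=config.n_perm, seed=config.seed
            )
            manifest["amova"] = {
                "pct_among": ares.pct_among,
                "pct_within": ares.pct_within,
                "phi": ares.phi, "p": ares.p_value,
            }
            manifest["stages_run"].append("amova")

    if "parentage" in config.stages:
        thr = parentage.simulate_lod_threshold(
            table, n_sim=config.lod_n_sim, epsilon=config.lod_epsilon,
            seed=config.seed,
        )
        targets = [
            a.accession_id for a in table.accessions if a.status == "UA"
        ]
        hits = parentage.scan_parents(
            table, targets, thr, clone_groups=clone_groups,
            seed=config.seed,
        )
        save("parentage_hits.csv", pd.DataFrame(
            [asdict(h) for h in hits]
        ) if hits else pd.DataFrame(columns=[
            "offspring_id", "candidate_id", "lod"
        ]))
        manifest["lod_threshold"] = thr.threshold
        manifest["stages_run"].append("parentage")

    if "traits" in config.stages and config.traits_path:
        tdf = pd.read_csv(config.traits_path, index_col="accession_id")
        tdf.index = tdf.index.astype(str)
        assoc = traits_mod.allele_trait_correlations(
            matrix, tdf, seed=config.seed
        )
        save("trait_associations.csv", pd.DataFrame(
            [asdict(a) for a in assoc]
        ))
        save("trait_correlations.csv",
             traits_mod.trait_trait_correlations(tdf))
        manifest["stages_run"].append("traits")

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest
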