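"""End-to-end orchestration: simulate/load -> diversity -> PERMANOVA ->
phylosymbiosis signal -> ancestral reconstruction, with a machine-readable
run summary.

Each stage draws randomness from its own generator, seeded by mixing the
master seed with a stable hash of the stage name, so re-running a config
reproduces every artifact byte for byte and any stage can be replayed in
isolation by calling the corresponding module function with the logged seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, ancestral, congruence, diversity, ordination
from .abundance import (AbundanceTable, SampleMetadata, TaxonomyMap,
                        mean_species_profile, read_abundance_table,
                        read_metadata, read_taxonomy, to_relative)
from .trees import HostTree, patristic_distances

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    tree_path: str
    table_path: str
    metadata_path: str
    taxonomy_path: str
    out_dir: str
    sites: list[str] | None = None        # default: every site in the metadata
    diversity_rank: str = "genus"
    signal_rank: str = "ASV"
    ancestral_rank: str = "order"
    beta_metric: str = "bray_curtis"
    signal_metric: str = "jaccard"
    top_n_taxa: int = 14
    n_resamplings: int = 100
    n_permutations: int = 999
    subsample_size: int | str = "auto"
    permanova_terms: list[str] = field(
        default_factory=lambda: ["body_site", "host_species"])
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = cls(**json.load(fh))
        for name in ("tree_path", "table_path", "metadata_path", "taxonomy_path"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if cfg.n_permutations < 99 or cfg.n_resamplings < 1:
            raise ValueError("permutation/resampling counts too small")
        return cfg


def _write_manifest(out: Path) -> None:
    lines = []
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "MANIFEST":
            digest = hashlib.sha256(f.read_bytes()).hexdigest()
            lines.append(f"{digest}  {f.relative_to(out)}")
    (out / "MANIFEST").write_text("\n".join(lines) + "\n")


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the run summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": {}, "sites": {}}

    def _timed(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        dt = time.perf_counter() - t0
        # wall time goes to the log only, so summary.json is reproducible
        logger.info("stage %s finished in %.2fs", stage, dt)
        summary["stages"][stage] = {"seed": stage_seed(cfg.seed, stage)}
        return result

    host = HostTree.from_newick(cfg.tree_path)
    table = read_abundance_table(cfg.table_path, rank="ASV")
    metadata = read_metadata(cfg.metadata_path)
    taxonomy = read_taxonomy(cfg.taxonomy_path)
    sites = cfg.sites or sorted(metadata.data["body_site"].unique())

    # ---- diversity -------------------------------------------------------
    def _diversity():
        t = abundance.aggregate_rank(table, taxonomy, cfg.diversity_rank) \
            if cfg.diversity_rank != "ASV" else table
        alpha = diversity.alpha_with_letters(t, metadata)
        pd.DataFrame({"shannon": alpha.values,
                      "body_site": alpha.groups,
                      "letter": alpha.groups.map(alpha.letters)}
                     ).to_csv(out / "alpha.tsv", sep="\t", index_label="sample_id")
        beta = diversity.beta_matrix(to_relative(t), metric=cfg.beta_metric)
        pd.DataFrame(beta.data, index=list(beta.ids), columns=list(beta.ids)
                     ).to_csv(out / "beta.tsv", sep="\t")
        corr = diversity.site_correlation(t, metadata)
        corr.to_csv(out / "site_correlation.tsv", sep="\t")
        return {"kruskal_p": alpha.kruskal_p, "letters": dict(alpha.letters)}, beta

    (summary["diversity"], beta) = _timed("diversity", _diversity)

    # ---- permanova -------------------------------------------------------
    def _permanova():
        res = ordination.permanova(beta, metadata.data, cfg.permanova_terms,
                                   n_permutations=cfg.n_permutations,
                                   seed=stage_seed(cfg.seed, "permanova"))
        res.to_frame().to_csv(out / "permanova.tsv", sep="\t")
        return {t.name: {"omega2_partial": t.omega_squared_partial,
                         "pseudo_F": t.pseudo_f, "p": t.p_value}
                for t in res.terms}

    summary["permanova"] = _timed("permanova", _permanova)

    # ---- per-site phylosymbiosis signal + ancestral ----------------------
    profiles = {}
    for site in sites:
        profiles[site] = mean_species_profile(table, metadata, site)
    if cfg.subsample_size == "auto":
        k = min(p.n_samples for p in profiles.values())
    else:
        k = int(cfg.subsample_size)

    for site in sites:
        prof = profiles[site]
        species = prof.sample_ids
        site_summary: dict = {"n_species": len(species), "subsample_size": k}

        def _signal():
            host_d = patristic_distances(host, species)
            micro = diversity.beta_matrix(prof, metric=cfg.signal_metric)
            batch = congruence.subsampled_mantel(
                host_d, micro, subsample_size=min(k, len(species)),
                n_resamplings=cfg.n_resamplings,
                n_permutations=cfg.n_permutations,
                seed=stage_seed(cfg.seed, f"signal:{site}"))
            pd.DataFrame({"r": batch.r_values, "p": batch.p_values}).to_csv(
                out / f"mantel_{site}.tsv", sep="\t", index_label="resampling")
            dendro = congruence.upgma(micro)
            with open(out / f"dendrogram_{site}.nwk", "w") as fh:
                fh.write(dendro.as_string(schema="newick", unquoted_underscores=True))
            restricted = host.restrict_to(species)
            cong = congruence.congruence_test(
                restricted, dendro, n_permutations=cfg.n_permutations,
                seed=stage_seed(cfg.seed, f"congruence:{site}"))
            return {"mean_mantel_r": batch.mean_r,
                    "fraction_significant": batch.fraction_significant,
                    "nRF": cong.nrf, "nMC": cong.nmc,
                    "p_nRF": cong.p_rf, "p_nMC": cong.p_mc}

        site_summary.update(_timed(f"signal:{site}", _signal))

        def _ancestral():
            t_order = abundance.aggregate_rank(prof, taxonomy, cfg.ancestral_rank) \
                if cfg.ancestral_rank != prof.rank else prof
            states = ancestral.reconstruct_composition(
                t_order, host, n_taxa=min(cfg.top_n_taxa, t_order.n_taxa))
            states.composition.to_csv(out / f"ancestral_{site}.tsv", sep="\t",
                                      index_label="node")
            states.tree.to_newick(out / f"ancestral_{site}.nwk")
            h2 = {}
            for taxon in t_order.taxon_ids:
                fit = ancestral.phylo_heritability(t_order.data[taxon], host)
                h2[taxon] = fit.h2_percent
            pd.Series(h2, name="h2_percent").to_csv(
                out / f"heritability_{site}.tsv", sep="\t", index_label="taxon")
            return {"h2_range": [min(h2.values()), max(h2.values())],
                    "h2_mean": float(np.mean(list(h2.values())))}

        site_summary.update(_timed(f"ancestral:{site}", _ancestral))
        summary["sites"][site] = site_summary

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_manifest(out)
    return summary
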