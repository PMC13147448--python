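"""Synthetic host trees and multi-body-site 16S-style community tables.

The generator produces the statistical structure the detection battery
assumes: each host species carries a latent per-taxon profile that is a
mixture of a tree-heritable component (Brownian motion on a Yule host
phylogeny, depth-scaled to 1 so the BM marginal variance is the rate) and
independent species-level noise.  The mixture weight phi in [0, 1] is the
proportion of heritable variance — components are variance-standardized and
combined with weights sqrt(phi) and sqrt(1 - phi) — so phi = 0 is a
phylosymbiosis-free null and phi = 1 a fully heritable community.  Body
sites add their own baseline shifts; compositions come from a softmax over
logits, and per-sample counts from a Dirichlet-multinomial so sequencing
overdispersion is tunable via the concentration parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, SampleMetadata, TaxonomyMap
from .trees import HostTree


@dataclass
class SimConfig:
    """Settings of one synthetic phylosymbiosis study."""

    n_species: int = 32
    n_taxa: int = 100
    n_sites: int = 2
    samples_per_species_site: int = 3
    phi: float | list = 0.5          # scalar or one value per site
    bm_rate: float = 1.0             # BM rate on the depth-1 tree
    site_effect_sd: float = 1.0      # per-site baseline shift SD (logit scale)
    taxon_base_sd: float = 1.0       # uneven taxon prevalence (logit scale)
    latent_scale: float = 2.0        # logit-scale amplitude of the species signal
    depth: int = 10_000              # reads per sample
    concentration: float = 50.0      # Dirichlet concentration (higher = less overdispersed)
    seed: int = 0

    def phi_for_site(self, s: int) -> float:
        phi = self.phi[s] if isinstance(self.phi, (list, tuple)) else self.phi
        if not 0.0 <= phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {phi}")
        return float(phi)

    def validate(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        for name in ("n_taxa", "n_sites", "samples_per_species_site", "depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.concentration <= 0 or self.bm_rate <= 0:
            raise ValueError("concentration and bm_rate must be positive")
        for s in range(self.n_sites):
            self.phi_for_site(s)


@dataclass
class GroundTruth:
    """What the generator actually used, for parameter-recovery checks."""

    config: dict
    phi_by_site: dict
    site_effects: pd.DataFrame      # sites x taxa
    taxon_base: np.ndarray
    z_phylo: pd.DataFrame           # species x taxa, standardized BM component
    compositions: dict              # (species, site) -> composition vector


# ---------------------------------------------------------------------------

class _YuleNode:
    __slots__ = ("birth", "death", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.death = None
        self.children = []
        self.label = None


def simulate_tree(n_species: int, seed: int | None = None) -> HostTree:
    """Pure-birth (Yule, rate 1) tree on ``n_species`` tips, depth scaled to 1."""
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _YuleNode(0.0)
    left, right = _YuleNode(0.0), _YuleNode(0.0)
    root.death = 0.0
    root.children = [left, right]
    tips = [left, right]
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        parent = tips.pop(rng.integers(len(tips)))
        parent.death = t
        a, b = _YuleNode(t), _YuleNode(t)
        parent.children = [a, b]
        tips.extend([a, b])
    t += rng.exponential(1.0 / len(tips))
    for tip in tips:
        tip.death = t
    width = len(str(n_species))
    for i, tip in enumerate(sorted(tips, key=lambda x: x.birth)):
        tip.label = f"sp{i + 1:0{width}d}"

    def newick(node: _YuleNode) -> str:
        length = (node.death - node.birth) / t
        if not node.children:
            return f"{node.label}:{length:.10f}"
        inner = ",".join(newick(ch) for ch in node.children)
        return f"({inner}):{length:.10f}"

    return HostTree.from_newick(newick(root) + ";", is_path=False)


def _bm_on_tree(host: HostTree, n_taxa: int, rate: float,
                rng: np.random.Generator) -> pd.DataFrame:
    """One BM realization per taxon; rows = tips, marginal variance = rate."""
    tree = host.tree
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.zeros(n_taxa)
        else:
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(rate * bl), size=n_taxa)
            values[node] = values[node.parent_node] + step
    tips = {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}
    return pd.DataFrame.from_dict(tips, orient="index").sort_index()


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _taxonomy(n_taxa: int, rng: np.random.Generator) -> TaxonomyMap:
    """Random nested phylum > order > genus assignment for ASV ids."""
    n_phyla = max(2, min(6, n_taxa // 10))
    n_orders = max(n_phyla, min(15, n_taxa // 4))
    n_genera = max(n_orders, min(40, n_taxa // 2))
    order_phylum = rng.integers(n_phyla, size=n_orders)
    genus_order = rng.integers(n_orders, size=n_genera)
    asv_genus = rng.integers(n_genera, size=n_taxa)
    rows = []
    for i in range(n_taxa):
        g = asv_genus[i]
        o = genus_order[g]
        p = order_phylum[o]
        rows.append((f"t{i + 1:03d}", f"p{p + 1:02d}", f"o{o + 1:02d}", f"g{g + 1:02d}"))
    df = pd.DataFrame(rows, columns=["taxon_id", "phylum", "order", "genus"])
    return TaxonomyMap(df.set_index("taxon_id"))


def simulate_dataset(cfg: SimConfig
                     ) -> tuple[HostTree, AbundanceTable, SampleMetadata,
                                TaxonomyMap, GroundTruth]:
    """Generate a full synthetic study: tree, counts, metadata, taxonomy, truth."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(5)
    tree_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    host = simulate_tree(cfg.n_species, seed=tree_seed)
    rng_latent = np.random.default_rng(seeds[1])
    rng_effects = np.random.default_rng(seeds[2])
    rng_counts = np.random.default_rng(seeds[3])
    rng_tax = np.random.default_rng(seeds[4])

    species = sorted(host.tip_labels)
    taxa = [f"t{i + 1:03d}" for i in range(cfg.n_taxa)]
    sites = [f"site{s + 1}" for s in range(cfg.n_sites)]

    # depth-1 tree + rate: BM marginal SD = sqrt(rate); standardize to unit SD
    z_phylo = _bm_on_tree(host, cfg.n_taxa, cfg.bm_rate, rng_latent)
    z_phylo = z_phylo / np.sqrt(cfg.bm_rate)
    z_phylo.columns = taxa
    taxon_base = rng_effects.normal(0.0, cfg.taxon_base_sd, size=cfg.n_taxa)
    site_effects = pd.DataFrame(
        rng_effects.normal(0.0, cfg.site_effect_sd, size=(cfg.n_sites, cfg.n_taxa)),
        index=sites, columns=taxa)

    rows, meta_rows, comps = [], [], {}
    sample_idx = 0
    phi_by_site = {}
    for s, site in enumerate(sites):
        phi = cfg.phi_for_site(s)
        phi_by_site[site] = phi
        w_p, w_e = np.sqrt(phi), np.sqrt(1.0 - phi)
        for sp in species:
            z_noise = rng_latent.normal(0.0, 1.0, size=cfg.n_taxa)
            latent = w_p * z_phylo.loc[sp].to_numpy() + w_e * z_noise
            logits = taxon_base + site_effects.loc[site].to_numpy() \
                + cfg.latent_scale * latent
            comp = _softmax(logits)
            comps[(sp, site)] = comp
            alpha = np.maximum(comp * cfg.concentration, 1e-9)
            for _ in range(cfg.samples_per_species_site):
                sample_idx += 1
                p = rng_counts.dirichlet(alpha)
                counts = rng_counts.multinomial(cfg.depth, p)
                rows.append(counts)
                meta_rows.append((f"S{sample_idx:05d}", sp, site))

    sample_ids = [m[0] for m in meta_rows]
    table = AbundanceTable(
        pd.DataFrame(np.array(rows, dtype=float), index=sample_ids, columns=taxa),
        rank="ASV", is_relative=False)
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "host_species", "body_site"]
                     ).set_index("sample_id"))
    taxonomy = _taxonomy(cfg.n_taxa, rng_tax)
    truth = GroundTruth(config=asdict(cfg), phi_by_site=phi_by_site,
                        site_effects=site_effects, taxon_base=taxon_base,
                        z_phylo=z_phylo, compositions=comps)
    return host, table, metadata, taxonomy, truth
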