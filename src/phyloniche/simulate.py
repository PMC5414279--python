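"""Synthetic comparative study generator.

Emulates a mammal-style dataset of ~32 species with ~384 gene-function
categories, Brownian-motion trait covariance on a Yule tree, and exactly one
category causally linked to climatic niche breadth, so that every analysis
stage — envelope scoring, duplicated-gene counting, NOGF counting, contrast
computation, LASSO screening, PGLS model averaging — can be exercised and
validated end-to-end without any external database.

The generative model:

* a Yule (pure-birth) tree with ``n_species`` tips;
* every predictor (per-category gene counts, genome size, total genes,
  duplicated genes, body mass, mass-specific metabolic rate) evolves as an
  independent Brownian motion on the tree, exponentiated and rounded where
  the trait is a positive count (Kleiber-style M^-1/4 scaling links
  metabolic rate to body mass);
* the square-root of the climate envelope is ``base + beta_star * (planted
  category count) + Brownian noise``, so the planted category is the only
  NOGF with a causal effect;
* species niche clouds in 19-dimensional climate space share two dominant
  latent axes (variance split chosen so the pooled PCA concentrates ~98%/
  ~1.5% on PC1/PC2) with per-species spread proportional to latent niche
  breadth, making grid occupancy scale with breadth squared;
* homology-hit tables contain planted duplicate pairs plus threshold-boundary
  decoys (E exactly at the cutoff, coverage exactly at the cutoff) and self
  hits, so the strict filter is exercised.

All generators are pure functions of (config, seed): a single master seed
fans out to per-component substreams, so any stage can be regenerated
independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .envelope import BIOCLIM_COLUMNS
from .trees import PhyloTree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyData",
    "simulate_tree",
    "simulate_bm",
    "simulate_traits",
    "simulate_niche_samples",
    "simulate_hit_table",
    "simulate_habitat_classes",
    "simulate_gene_category_map",
    "generate_study",
    "write_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults define the standard design.

    ``beta_star`` is the causal effect of the planted category's gene count
    on the square-root envelope.  With the default count spread (base 100
    genes, log-scale Brownian s.d. 0.15 per unit branch length) the planted
    signal contributes about half the contrast-level variance of the
    response, i.e. a contrast R^2 near 0.5 — a realistically strong, not
    overwhelming, comparative signal.
    """

    n_species: int = 32
    n_categories: int = 384
    planted_category: str = "Exosome-like"
    beta_star: float = 0.05
    base_sqrt_env: float = 2.0
    noise_rate: float = 0.42        # Brownian variance rate of response noise
    birth_rate: float = 1.0

    # gene-count scales (log-normal around a per-category base size)
    base_category_size: float = 20.0
    category_size_log_sd: float = 1.0
    min_category_size: float = 8.0  # tiny categories quantize to spiky contrasts
    planted_base_size: float = 100.0
    count_log_sd: float = 0.15      # log-scale Brownian s.d. of counts

    # niche clouds in climate space
    rows_per_species: int = 1000
    center_sd: float = 10.0         # species-center spread along latent axis 1
    pc2_share: float = 1.5 / 98.1   # axis-2 : axis-1 variance ratio (~98%/1.5%)
    cloud_pc1_per_breadth: float = 0.03
    cloud_pc2_per_breadth: float = 0.08
    ambient_sd: float = 0.05        # isotropic noise in the other 17 directions

    # duplicated genes
    base_dup_pairs: float = 200.0
    dup_log_sd: float = 0.3

    # habitat classes
    n_classes: int = 12
    class_cells: int = 200

    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    tree_newick: str
    beta_star: float
    planted_category: str
    breadth: pd.Series            # latent sqrt-envelope per species
    envelope_target: pd.Series    # latent occupied-cell target per species
    expected_n_d: pd.Series
    planted_counts: pd.Series

    def to_json(self) -> str:
        return json.dumps(
            {
                "tree_newick": self.tree_newick,
                "beta_star": self.beta_star,
                "planted_category": self.planted_category,
                "breadth": self.breadth.round(6).to_dict(),
                "envelope_target": self.envelope_target.to_dict(),
                "expected_n_d": self.expected_n_d.to_dict(),
                "planted_counts": self.planted_counts.to_dict(),
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class StudyData:
    """A complete in-memory synthetic study."""

    tree: PhyloTree
    traits: pd.DataFrame          # species, envelope target, G, N_g, N_d, M, B_c, NOGF_*
    climate: pd.DataFrame         # species, bio1..bio19
    class_counts: pd.DataFrame    # species, class, count
    hits: pd.DataFrame            # species, qseqid, sseqid, evalue, qcov
    gene_map: pd.DataFrame        # species, gene, category
    catalogue: tuple[str, ...]
    truth: GroundTruth


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Tree and Brownian traits
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self):
        self.children: list[_Node] = []
        self.length = 0.0
        self.label: str | None = None

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def simulate_tree(n: int, birth_rate: float = 1.0,
                  seed: int | np.random.Generator = 0) -> PhyloTree:
    """Yule (pure-birth) tree with ``n`` tips and positive branch lengths.

    Lineages split at rate ``birth_rate`` each; after the (n-1)-th
    speciation all pendant branches are extended by one further exponential
    waiting time so every branch length is strictly positive.  Deterministic
    for a given seed.
    """
    if n < 2:
        raise ValueError("a tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    root = _Node()
    a, b = _Node(), _Node()
    root.children = [a, b]
    active: list[tuple[_Node, float]] = [(a, 0.0), (b, 0.0)]  # (node, birth time)
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born
        c1, c2 = _Node(), _Node()
        node.children = [c1, c2]
        active.append((c1, t))
        active.append((c2, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    order = rng.permutation(len(active))
    for rank, i in enumerate(order):
        node, born = active[i]
        node.length = t_end - born
        node.label = f"t{rank + 1}"
    newick = "(" + ",".join(c.newick() for c in root.children) + ");"
    return PhyloTree.from_newick(newick)


def simulate_bm(
    tree: PhyloTree,
    rates: float | np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Brownian motion(s) on the tree; one column per rate, rows are tips.

    Each column starts at 0 at the root and accumulates independent normal
    increments with variance ``rate * branch length``.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if (rates < 0).any():
        raise ValueError("rates must be nonnegative")
    dtree = tree.dendropy_tree
    values: dict[int, np.ndarray] = {id(dtree.seed_node): np.zeros(len(rates))}
    out: dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            parent = values[id(node.parent_node)]
            step = rng.normal(size=len(rates)) * np.sqrt(rates * node.edge.length)
            values[id(node)] = parent + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.DataFrame.from_dict(out, orient="index").loc[tree.tip_labels]


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Species trait table plus the planted ground truth.

    Per-category gene counts, genome size, total genes, duplicate pairs,
    body mass and metabolic rate each follow an independent Brownian motion
    (exponentiated to a positive scale, rounded where integer).  The latent
    square-root envelope is ``base + beta_star * planted count + BM noise``.
    """
    cats = _catalogue(config)
    if config.planted_category not in cats:
        raise ValueError(f"planted category {config.planted_category!r} "
                         "not in the catalogue")
    species = tree.tip_labels
    k = len(cats)

    # category base sizes (shared across species), planted one fixed larger
    base = np.maximum(
        config.min_category_size,
        config.base_category_size
        * np.exp(rng.normal(0.0, config.category_size_log_sd, size=k)),
    )
    base[cats.index(config.planted_category)] = config.planted_base_size

    z = simulate_bm(tree, np.ones(k), rng)               # unit-rate BM per category
    counts = np.maximum(1, np.rint(base * np.exp(config.count_log_sd * z))).astype(int)
    nogf = pd.DataFrame(counts.to_numpy() if isinstance(counts, pd.DataFrame)
                        else counts, index=species,
                        columns=[f"NOGF_{c}" for c in cats])

    aux = simulate_bm(tree, np.ones(5), rng)             # G, N_g, dup, M, B_c noise
    G = (2.5e9 * np.exp(0.05 * aux[0])).round().astype(int)
    N_g = np.maximum(5000, (2.0e4 * np.exp(0.10 * aux[1])).round()).astype(int)
    dup_pairs = np.maximum(
        1, (config.base_dup_pairs * np.exp(config.dup_log_sd * aux[2])).round()
    ).astype(int)
    N_d = np.minimum(2 * dup_pairs, N_g)
    M = 1000.0 * np.exp(1.5 * aux[3])                    # body mass, g
    B_c = 0.01 * (M / 1000.0) ** -0.25 * np.exp(0.2 * aux[4])  # W / g

    planted = nogf[f"NOGF_{config.planted_category}"]
    noise = simulate_bm(tree, config.noise_rate, rng)[0]
    sqrt_env = config.base_sqrt_env + config.beta_star * planted + noise
    sqrt_env = sqrt_env.clip(lower=1.0)
    env_target = np.maximum(1, np.rint(sqrt_env**2)).astype(int)

    traits = pd.DataFrame(
        {"G": G, "N_g": N_g, "N_d": N_d, "M": M, "B_c": B_c,
         "envelope": env_target},
        index=pd.Index(species, name="species"),
    ).join(nogf)
    truth = GroundTruth(
        tree_newick=tree.to_newick(),
        beta_star=config.beta_star,
        planted_category=config.planted_category,
        breadth=sqrt_env.rename("breadth"),
        envelope_target=env_target.rename("envelope_target"),
        expected_n_d=pd.Series(N_d, index=species, name="expected_n_d"),
        planted_counts=planted.rename("planted_counts"),
    )
    return traits, truth


def _catalogue(config: SimulationConfig) -> list[str]:
    cats = [config.planted_category]
    cats += [f"Category_{i:03d}" for i in range(1, config.n_categories)]
    return cats


# ---------------------------------------------------------------------------
# Niche clouds in climate space
# ---------------------------------------------------------------------------

def simulate_niche_samples(
    breadths: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-species climate samples whose grid occupancy tracks niche breadth.

    All species share two orthonormal latent axes in 19-dimensional climate
    space; species centers spread along them with an axis-variance split of
    ``1 : pc2_share`` so that a pooled PCA reproduces the highly anisotropic
    variance structure of real bioclim data.  Within-species spread along
    both axes is proportional to the species' breadth, so the number of
    occupied grid cells grows roughly with breadth squared — i.e. the
    square-root envelope is roughly proportional to breadth.
    """
    if (breadths <= 0).any():
        bad = list(breadths.index[breadths <= 0])
        raise ValueError(f"nonpositive niche breadth for species: {bad}")
    d = len(BIOCLIM_COLUMNS)
    basis, _ = np.linalg.qr(rng.normal(size=(d, 2)))
    u1, u2 = basis[:, 0], basis[:, 1]
    offset = rng.normal(100.0, 50.0, size=d)    # arbitrary bioclim-like baseline

    m = config.rows_per_species
    frames = []
    for sp, b in breadths.items():
        c1 = rng.normal(0.0, config.center_sd)
        c2 = rng.normal(0.0, config.center_sd * np.sqrt(config.pc2_share))
        z1 = rng.normal(c1, config.cloud_pc1_per_breadth * b, size=m)
        z2 = rng.normal(c2, config.cloud_pc2_per_breadth * b, size=m)
        rows = (offset
                + np.outer(z1, u1)
                + np.outer(z2, u2)
                + rng.normal(0.0, config.ambient_sd, size=(m, d)))
        frame = pd.DataFrame(rows, columns=list(BIOCLIM_COLUMNS))
        frame.insert(0, "species", sp)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Homology hits, habitat classes, gene-category maps
# ---------------------------------------------------------------------------

def simulate_hit_table(
    n_genes: int,
    n_dup_pairs: int,
    rng: np.random.Generator,
    species: str = "sp1",
    e_max: float = 1e-5,
    cov_min_pct: float = 30.0,
) -> tuple[pd.DataFrame, int]:
    """Homology hits with planted duplicate pairs, boundary decoys, self hits.

    The first ``2 * n_dup_pairs`` genes form passing duplicate pairs; decoy
    hits among the remaining genes fail exactly one threshold (E-value at or
    above the cutoff, or coverage at or below the cutoff), and every gene
    gets a self hit.  Returns the table and the expected duplicated-gene
    count (``2 * n_dup_pairs``).
    """
    if 2 * n_dup_pairs > n_genes:
        raise ValueError("need at least 2 genes per duplicate pair")
    genes = [f"{species}_g{i:05d}" for i in range(n_genes)]
    rows: list[tuple[str, str, str, float, float]] = []
    for p in range(n_dup_pairs):
        q, s = genes[2 * p], genes[2 * p + 1]
        e = 10.0 ** rng.uniform(-30.0, np.log10(e_max) - 1.0)
        cov = rng.uniform(cov_min_pct + 5.0, 100.0)
        rows.append((species, q, s, e, cov))
    spare = genes[2 * n_dup_pairs:]
    for i in range(0, max(0, len(spare) - 1), 2):
        q, s = spare[i], spare[i + 1]
        kind = i // 2 % 3
        if kind == 0:      # boundary E-value: exactly at the cutoff -> excluded
            rows.append((species, q, s, e_max, 80.0))
        elif kind == 1:    # boundary coverage: exactly at the cutoff -> excluded
            rows.append((species, q, s, 1e-10, cov_min_pct))
        else:              # clearly failing both margins
            rows.append((species, q, s, 1e-3, 10.0))
    for g in genes:
        rows.append((species, g, g, 0.0, 100.0))
    df = pd.DataFrame(rows, columns=["species", "qseqid", "sseqid", "evalue", "qcov"])
    return df, 2 * n_dup_pairs


def simulate_habitat_classes(
    breadths: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Occupied-cell counts per climate class; evenness grows with breadth."""
    records = []
    for sp, b in breadths.items():
        j = np.arange(config.n_classes)
        probs = np.exp(-j / max(b / 2.0, 0.25))
        probs /= probs.sum()
        counts = rng.multinomial(config.class_cells, probs)
        for cls, cnt in zip(j, counts):
            if cnt > 0:
                records.append((sp, f"class_{cls:02d}", int(cnt)))
    return pd.DataFrame(records, columns=["species", "class", "count"])


def simulate_gene_category_map(
    nogf: pd.DataFrame,
    n_genes: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gene -> category records realizing the given per-species NOGF counts.

    Per species, categories are assigned blocks of a random permutation of
    the gene pool; consecutive blocks overlap slightly so some genes carry
    multiple categories.  Distinct-gene counts per category equal the NOGF
    table exactly.
    """
    frames = []
    cats = [c.removeprefix("NOGF_") for c in nogf.columns]
    for sp in nogf.index:
        pool = rng.permutation(int(n_genes.loc[sp]))
        counts = nogf.loc[sp].to_numpy(dtype=int)
        if counts.max() > len(pool):
            raise ValueError(f"a category outnumbers the gene pool for {sp}")
        genes_col: list[str] = []
        cats_col: list[str] = []
        start = 0
        for cat, cnt in zip(cats, counts):
            if start + cnt > len(pool):
                start = 0  # wrap, reusing early genes (extra multi-category genes)
            block = pool[start : start + cnt]
            genes_col.extend(f"{sp}_g{g:05d}" for g in block)
            cats_col.extend([cat] * cnt)
            # step back ~10% so adjacent categories share a few genes
            start += max(1, int(cnt * 0.9))
        frame = pd.DataFrame({"gene": genes_col, "category": cats_col})
        frame.insert(0, "species", sp)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------

def generate_study(config: SimulationConfig | None = None) -> StudyData:
    """Generate a full in-memory study from one master seed."""
    config = config or SimulationConfig()
    rng_tree, rng_traits, rng_niche, rng_hits, rng_cls, rng_map = _substreams(
        config.seed, 6
    )
    tree = simulate_tree(config.n_species, config.birth_rate, rng_tree)
    traits, truth = simulate_traits(tree, config, rng_traits)
    climate = simulate_niche_samples(truth.breadth, config, rng_niche)
    hit_frames = []
    for sp in tree.tip_labels:
        pairs = int(traits.loc[sp, "N_d"]) // 2
        df, _ = simulate_hit_table(2 * pairs + 60, pairs, rng_hits, species=sp)
        hit_frames.append(df)
    hits = pd.concat(hit_frames, ignore_index=True)
    classes = simulate_habitat_classes(truth.breadth, config, rng_cls)
    nogf_cols = [c for c in traits.columns if c.startswith("NOGF_")]
    gene_map = simulate_gene_category_map(
        traits[nogf_cols], traits["N_g"], rng_map
    )
    return StudyData(
        tree=tree,
        traits=traits,
        climate=climate,
        class_counts=classes,
        hits=hits,
        gene_map=gene_map,
        catalogue=tuple(_catalogue(config)),
        truth=truth,
    )


def write_study(config: SimulationConfig, out_dir: str | Path) -> StudyData:
    """Generate a study and write every input file the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = generate_study(config)
    (out / "tree.nwk").write_text(study.tree.to_newick() + "\n")
    study.traits.reset_index().to_csv(out / "traits.tsv", sep="\t", index=False)
    study.climate.to_csv(out / "climate.tsv", sep="\t", index=False)
    study.class_counts.to_csv(out / "habitat_classes.tsv", sep="\t", index=False)
    study.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    study.gene_map.to_csv(out / "gene_categories.tsv", sep="\t", index=False)
    (out / "catalogue.txt").write_text("\n".join(study.catalogue) + "\n")
    (out / "ground_truth.json").write_text(study.truth.to_json() + "\n")
    return study
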