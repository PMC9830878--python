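"""Synthetic two-species SDX-like datasets with known ground truth.

The generator emulates the structure the pipeline consumes: two species
sharing a branching xylem lineage (a ray branch organizer -> precursor ->
ray parenchyma, and a fusiform branch organizer -> early -> intermediate ->
vessel, with a libriform-fiber side branch), NB-distributed UMI counts with
gene-wise dispersion and log-normal library sizes, a many-to-one
gene -> ortholog-group map per species (1-3 copies, Dirichlet-split
expression), co-registered 2D embeddings along the branch curves, and
LCM-like bulk TPM profiles of the three terminal cell types.

A divergence knob ``epsilon`` in [0, 1] re-randomizes that fraction of the
fusiform-program ortholog groups in species B (nested sets, so growing
``epsilon`` only adds divergence) and displaces species B's fusiform cells
in the shared embedding proportionally.

Randomness discipline: every component (programs, per-species counts,
embedding, LCM noise) draws from its own child of ``SeedSequence(seed)``, so
e.g. enlarging the gene panel does not perturb the embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io import (
    CellMatrix,
    LabeledEmbedding,
    LcmProfile,
    OrthoGroupMap,
    write_count_matrix,
    write_embedding,
    write_lcm_profile,
    write_ortholog_groups,
)
from .normalize import log_transform, normalize_counts

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "TwoSpeciesDataset",
    "CLUSTERS",
    "CLUSTER_MODULES",
    "simulate_two_species",
    "simulate_embedding_pair",
    "write_dataset",
]

#: the 8 lineage states: (name, branch, pseudotime interval on that branch)
CLUSTERS: list[tuple[str, str, tuple[float, float]]] = [
    ("FuO", "fusiform", (0.00, 0.25)),   # fusiform organizer
    ("FuEP", "fusiform", (0.25, 0.50)),  # fusiform early precursor
    ("FuIP", "fusiform", (0.50, 0.75)),  # fusiform intermediate precursor
    ("V", "fusiform", (0.75, 1.00)),     # vessel element
    ("F", "fiber", (0.60, 1.00)),        # libriform fiber (side branch)
    ("RO", "ray", (0.00, 0.33)),         # ray organizer
    ("RP", "ray", (0.33, 0.66)),         # ray precursor
    ("R", "ray", (0.66, 1.00)),          # ray parenchyma
]

CLUSTER_MODULES: dict[str, int] = {name: i + 1 for i, (name, _, _) in enumerate(CLUSTERS)}
FUSIFORM_CLUSTERS = ("FuO", "FuEP", "FuIP", "V", "F")
TERMINAL_LCM = {"F": "libriform_fiber", "V": "vessel_element", "R": "ray_parenchyma"}


@dataclass
class SimConfig:
    """Study conditions of the synthetic two-species experiment."""

    seed: int = 0
    n_cells_per_cluster: int = 100
    n_orthogroups: int = 600
    n_markers_per_cluster: int = 25
    marker_fold: float = 8.0
    dispersion_range: tuple[float, float] = (0.05, 0.3)
    library_size: float = 2000.0         # log-normal median of per-cell totals
    library_sigma: float = 0.4
    epsilon: float = 0.0                 # fusiform divergence knob in [0, 1]
    embedding_noise: float = 0.35
    lcm_replicates: int = 3
    lcm_noise: float = 0.15
    species: tuple[str, str] = ("ptr", "egr")

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.n_cells_per_cluster < 5:
            raise ValueError("need >= 5 cells per cluster (DEG eligibility rule)")
        if self.n_orthogroups < 8 * self.n_markers_per_cluster:
            raise ValueError("not enough ortholog groups for the marker programs")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    correspondence: dict[str, str]               # cluster A -> cluster B (bijection)
    marker_groups: dict[str, list[str]]          # cluster -> marker ortholog groups
    marker_genes: dict[str, dict[str, list[str]]]  # species -> cluster -> gene ids
    lcm_programs: dict[str, list[str]]           # LCM cell type -> species-A genes
    module_of: dict[str, int]                    # cluster -> module 1..8
    rerandomized_groups: list[str]               # groups diverged in species B
    epsilon: float

    def __post_init__(self) -> None:
        vals = list(self.correspondence.values())
        if len(set(vals)) != len(vals):
            raise ValueError("cluster correspondence must be a bijection")


@dataclass
class TwoSpeciesDataset:
    """Everything the pipeline consumes, plus the truth."""

    matrices: dict[str, CellMatrix]
    ortho_map: OrthoGroupMap
    embedding: LabeledEmbedding                  # integrated 2D, both species
    pcs: dict[str, LabeledEmbedding]             # per species, d = 10
    clusters: dict[str, np.ndarray]
    pseudotime: dict[str, np.ndarray]
    branch: dict[str, np.ndarray]
    lcm: LcmProfile
    truth: SyntheticTruth
    config: SimConfig = field(repr=False, default_factory=SimConfig)


# ---------------------------------------------------------------------------
# branch geometry
# ---------------------------------------------------------------------------

def _branch_xy(branch: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Smooth 2D curves for the three branches, joined near the origin."""
    xy = np.zeros((len(t), 2))
    fus = branch == "fusiform"
    ray = branch == "ray"
    fib = branch == "fiber"
    xy[fus, 0] = 6.0 * t[fus]
    xy[fus, 1] = -1.5 * np.sin(np.pi * t[fus])
    xy[ray, 0] = -5.0 * t[ray]
    xy[ray, 1] = 2.0 * t[ray] + 1.0 * t[ray] ** 2
    # fiber departs from the fusiform curve at t = 0.6
    t0 = 0.6
    base = np.array([6.0 * t0, -1.5 * np.sin(np.pi * t0)])
    xy[fib] = base + np.outer(t[fib] - t0, [2.0, 4.0])
    return xy


# ---------------------------------------------------------------------------
# programs
# ---------------------------------------------------------------------------

def _pulse(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth bump centered on [lo, hi] (logistic-ramp product)."""
    width = max(hi - lo, 1e-6)
    k = 12.0 / width
    return 1.0 / (1.0 + np.exp(-k * (t - lo))) / (1.0 + np.exp(k * (t - hi)))


def _cluster_multiplier(
    cluster_name: str, branch: np.ndarray, t: np.ndarray, fold: float
) -> np.ndarray:
    name, br, (lo, hi) = next(c for c in CLUSTERS if c[0] == cluster_name)
    mult = np.ones(len(t))
    on = branch == br
    if br == "fusiform":  # fusiform programs also leak onto the fiber side branch base
        on = on | ((branch == "fiber") & (t <= 0.6))
    mult[on] += (fold - 1.0) * _pulse(t[on], lo, hi)
    return mult


def _sample_cells(rng: np.random.Generator, n_per_cluster: int):
    names, branches, ts = [], [], []
    for name, br, (lo, hi) in CLUSTERS:
        u = rng.uniform(lo, hi, size=n_per_cluster)
        names.extend([name] * n_per_cluster)
        branches.extend([br] * n_per_cluster)
        ts.append(u)
    return (np.asarray(names, dtype=object), np.asarray(branches, dtype=object),
            np.concatenate(ts))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion phi) samples; phi ~ 0 falls back to Poisson."""
    counts = np.empty(mu.shape, dtype=np.int64)
    tiny = phi < 1e-8
    if tiny.any():
        counts[:, tiny] = rng.poisson(mu[:, tiny])
    if (~tiny).any():
        p = phi[~tiny]
        lam = rng.gamma(1.0 / p, p * mu[:, ~tiny])
        counts[:, ~tiny] = rng.poisson(lam)
    return counts


def simulate_two_species(cfg: SimConfig) -> TwoSpeciesDataset:
    """Generate the full two-species dataset with planted ground truth."""
    root = np.random.SeedSequence(cfg.seed)
    ss_prog, ss_a, ss_b, ss_emb, ss_lcm, ss_div = root.spawn(6)
    rng_prog = np.random.default_rng(ss_prog)
    rng_div = np.random.default_rng(ss_div)

    G = cfg.n_orthogroups
    og_ids = np.asarray([f"OG{i:04d}" for i in range(G)], dtype=object)
    base = rng_prog.lognormal(mean=0.0, sigma=1.0, size=G)
    dispersion_og = rng_prog.uniform(*cfg.dispersion_range, size=G)

    # marker assignment: first 8 * n_markers groups, in cluster blocks.
    # Marker groups draw their base level from a higher-expression regime:
    # cell-type markers are well-detected genes, which is what makes them
    # usable as markers at threshold-based cutoffs.
    marker_groups: dict[str, list[str]] = {}
    og_cluster = np.full(G, "", dtype=object)  # "" = background
    pos = 0
    for name, _, _ in CLUSTERS:
        sel = slice(pos, pos + cfg.n_markers_per_cluster)
        marker_groups[name] = list(og_ids[sel])
        og_cluster[sel] = name
        base[sel] = rng_prog.lognormal(mean=1.0, sigma=0.5,
                                       size=cfg.n_markers_per_cluster)
        pos += cfg.n_markers_per_cluster

    # divergence: nested fraction of the fusiform-program groups re-randomized in B
    fus_groups = [g for c in FUSIFORM_CLUSTERS for g in marker_groups[c]]
    n_div = int(round(cfg.epsilon * len(fus_groups)))
    rerandomized = sorted(fus_groups)[:n_div]
    rerand_target: dict[str, str] = {}
    all_names = [c[0] for c in CLUSTERS]
    for g in sorted(fus_groups):  # draw targets for every candidate: stable across eps
        current = og_cluster[np.where(og_ids == g)[0][0]]
        choices = [c for c in all_names if c != current]
        rerand_target[g] = choices[rng_div.integers(len(choices))]

    # gene copies per species
    species = list(cfg.species)
    gene_ids: dict[str, np.ndarray] = {}
    gene_og: dict[str, np.ndarray] = {}
    gene_share: dict[str, np.ndarray] = {}
    groups_map: dict[str, set[tuple[str, str]]] = {g: set() for g in og_ids}
    for s in species:
        ids, ogs, shares = [], [], []
        counter = 0
        for i, g in enumerate(og_ids):
            k = int(rng_prog.integers(1, 4))
            w = rng_prog.dirichlet(np.full(k, 5.0))
            for j in range(k):
                gid = f"{s}_g{counter:05d}"
                counter += 1
                ids.append(gid)
                ogs.append(i)
                shares.append(w[j])
                groups_map[g].add((s, gid))
        gene_ids[s] = np.asarray(ids, dtype=object)
        gene_og[s] = np.asarray(ogs)
        gene_share[s] = np.asarray(shares)
    ortho_map = OrthoGroupMap(groups_map)

    # cells, counts, embeddings
    matrices: dict[str, CellMatrix] = {}
    clusters: dict[str, np.ndarray] = {}
    pseudotime: dict[str, np.ndarray] = {}
    branch_of: dict[str, np.ndarray] = {}
    pcs: dict[str, LabeledEmbedding] = {}
    marker_genes: dict[str, dict[str, list[str]]] = {}
    emb_parts = []
    rng_emb = np.random.default_rng(ss_emb)

    for s, ss_cells in zip(species, (ss_a, ss_b)):
        rng = np.random.default_rng(ss_cells)
        names, branches, t = _sample_cells(rng, cfg.n_cells_per_cluster)
        n = len(t)

        # per-OG multiplier field for this species
        og_of_cluster = og_cluster.copy()
        if s == species[1]:
            for g in rerandomized:
                og_of_cluster[np.where(og_ids == g)[0][0]] = rerand_target[g]
        M = np.ones((n, G))
        for name in all_names:
            cols = np.where(og_of_cluster == name)[0]
            if len(cols):
                M[:, cols] = _cluster_multiplier(name, branches, t, cfg.marker_fold)[:, None]

        W = M[:, gene_og[s]] * (base[gene_og[s]] * gene_share[s])[None, :]
        p = W / W.sum(axis=1, keepdims=True)
        lib = rng.lognormal(np.log(cfg.library_size), cfg.library_sigma, size=n)
        mu = lib[:, None] * p
        counts = _nb_counts(rng, mu, dispersion_og[gene_og[s]])
        cell_ids = np.asarray([f"{s}_c{i:04d}" for i in range(n)], dtype=object)
        matrices[s] = CellMatrix(sp.csr_matrix(counts), cell_ids, gene_ids[s], species=s)
        clusters[s] = names
        pseudotime[s] = t
        branch_of[s] = branches
        marker_genes[s] = {
            c: [g for g, og in zip(gene_ids[s], gene_og[s]) if og_cluster[og] == c]
            for c in all_names
        }

        # shared 2D embedding: curves + noise; species B fusiform displaced with eps
        xy = _branch_xy(branches, t)
        xy = xy + rng_emb.normal(0.0, cfg.embedding_noise, size=xy.shape)
        if s == species[1] and cfg.epsilon > 0:
            moved = np.isin(branches, ("fusiform", "fiber"))
            xy[moved] += cfg.epsilon * np.array([1.5, 3.0])
        emb_parts.append((cell_ids, xy, np.full(n, s, dtype=object), names))

        # top-10-PC coordinates from the counts themselves
        logn = log_transform(normalize_counts(matrices[s])).dense()
        n_pc = min(10, n - 1, logn.shape[1])
        coords = PCA(n_components=n_pc, svd_solver="full", random_state=0).fit_transform(logn)
        pcs[s] = LabeledEmbedding(cell_ids, coords, np.full(n, s, dtype=object), names)

    embedding = LabeledEmbedding(
        np.concatenate([p[0] for p in emb_parts]),
        np.vstack([p[1] for p in emb_parts]),
        np.concatenate([p[2] for p in emb_parts]),
        np.concatenate([p[3] for p in emb_parts]),
    )

    # LCM bulk profiles of the terminal cell types (species A gene space)
    rng_lcm = np.random.default_rng(ss_lcm)
    s0 = species[0]
    nm0 = normalize_counts(matrices[s0], scale_factor=1e6).dense()  # TPM-like scale
    reps: dict[str, np.ndarray] = {}
    for cl, ct in TERMINAL_LCM.items():
        mask = clusters[s0] == cl
        profile = nm0[mask].mean(axis=0)
        noise = rng_lcm.lognormal(0.0, cfg.lcm_noise,
                                  size=(len(profile), cfg.lcm_replicates))
        reps[ct] = profile[:, None] * noise
    lcm = LcmProfile(gene_ids[s0], reps)

    truth = SyntheticTruth(
        correspondence={c: c for c in all_names},
        marker_groups=marker_groups,
        marker_genes=marker_genes,
        lcm_programs={ct: marker_genes[s0][cl] for cl, ct in TERMINAL_LCM.items()},
        module_of=dict(CLUSTER_MODULES),
        rerandomized_groups=list(rerandomized),
        epsilon=cfg.epsilon,
    )
    return TwoSpeciesDataset(
        matrices=matrices, ortho_map=ortho_map, embedding=embedding, pcs=pcs,
        clusters=clusters, pseudotime=pseudotime, branch=branch_of,
        lcm=lcm, truth=truth, config=cfg,
    )


def simulate_embedding_pair(
    n: int,
    separation: float,
    interdigitation: float = 0.0,
    seed: int = 0,
    n_components: int = 1,
) -> LabeledEmbedding:
    """Two labeled 2D point clouds with controlled separation (units of blob sd).

    Each species draws ``n`` points from a shared unit-sd Gaussian (or a
    ``n_components``-component mixture); species B is shifted by
    ``separation`` along x.  ``interdigitation`` in [0, 1] is the fraction of
    species-B points drawn from the *unshifted* distribution (extra mixing).
    """
    if n < 10:
        raise ValueError("need n >= 10 per species")
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [4.0, 1.0], [2.0, 4.0]])[:n_components]

    def draw(k: int, shift: float) -> np.ndarray:
        comp = rng.integers(len(centers), size=k)
        return centers[comp] + rng.normal(size=(k, 2)) + np.array([shift, 0.0])

    a = draw(n, 0.0)
    n_mix = int(round(interdigitation * n))
    b = np.vstack([draw(n - n_mix, separation), draw(n_mix, 0.0)]) if n_mix \
        else draw(n, separation)
    ids = np.asarray([f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
                     dtype=object)
    return LabeledEmbedding(
        ids, np.vstack([a, b]),
        np.asarray(["A"] * n + ["B"] * n, dtype=object),
        np.zeros(2 * n, dtype=object),
    )


def write_dataset(ds: TwoSpeciesDataset, outdir: str | Path) -> None:
    """Write every artifact in the pipeline's input formats plus a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s, m in ds.matrices.items():
        write_count_matrix(m, out / f"matrix_{s}")
        pd.DataFrame({
            "cell_id": m.cell_ids, "cluster": ds.clusters[s],
            "lineage": ds.branch[s], "t": ds.pseudotime[s],
        }).to_csv(out / f"cells_{s}.tsv", sep="\t", index=False)
        write_embedding(ds.pcs[s], out / f"pcs_{s}.tsv")
    write_ortholog_groups(ds.ortho_map, out / "groups.txt")
    write_embedding(ds.embedding, out / "embedding.tsv")
    write_lcm_profile(ds.lcm, out / "lcm_tpm.tsv")
    truth = {
        "correspondence": ds.truth.correspondence,
        "marker_groups": ds.truth.marker_groups,
        "marker_genes": ds.truth.marker_genes,
        "lcm_programs": ds.truth.lcm_programs,
        "module_of": ds.truth.module_of,
        "rerandomized_groups": ds.truth.rerandomized_groups,
        "epsilon": ds.truth.epsilon,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
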