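"""Clustered negative-binomial scRNA-seq count simulation.

Generates gene x cell count matrices with known cell-group labels so every
benchmark in the package runs without downloads. The generative model is the
standard scRNA-seq simulation skeleton (gamma baseline, multiplicative group
effects, log-normal library sizes, gamma-Poisson counts):

1. baseline relative expression lambda_g ~ Gamma(shape=2, scale=1);
2. per group k, a seeded subset (``de_frac`` of genes) is differentially
   expressed with multiplier 2^(+-lfc), sign by fair coin per (group, gene);
3. cells are assigned to groups by ``group_props``; each cell's library
   size L_c ~ LogNormal(log(lib_size_mu), lib_size_sigma), so ``lib_size_mu``
   is the median total count per cell;
4. expected counts mu_gc = L_c * lambda_g * fc_gk / sum_g(lambda_g * fc_gk)
   (expected totals equal L_c exactly);
5. counts ~ NB(mean mu, dispersion phi) via the gamma-Poisson mixture
   (variance mu + phi mu^2; phi -> 0 recovers Poisson).

No dropout-inflation term: sparsity is controlled through library size
alone, which is what distinguishes the dense "plate-like" and sparse
"droplet-like" members of :func:`simulate_pair`.

Random streams are drawn in a fixed, documented order (baseline, DE gene
choice per group, DE signs per group, group assignment, library sizes,
counts) from a single ``numpy.random.default_rng(seed)``, so output is
bit-reproducible across platforms for a given numpy generation algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .sc_data import SCDataset

__all__ = ["SimConfig", "simulate_dataset", "simulate_pair"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the clustered NB count simulation.

    Defaults describe a small plate-like experiment: 200 genes, 120 cells in
    3 balanced groups, 10% of genes DE per group at |log2 FC| = 2, biological
    dispersion 0.1, median library size 5000 with 25% log-normal spread.
    """

    n_genes: int = 200
    n_cells: int = 120
    n_groups: int = 3
    group_props: Optional[tuple[float, ...]] = None  # default: balanced
    de_frac: float = 0.1
    lfc: float = 2.0
    dispersion: float = 0.1
    lib_size_mu: float = 5000.0
    lib_size_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if self.n_groups < 2:
            raise ValueError("n_groups must be at least 2")
        props = self.group_props
        if props is None:
            props = tuple([1.0 / self.n_groups] * self.n_groups)
        else:
            props = tuple(float(p) for p in props)
            if len(props) != self.n_groups:
                raise ValueError("group_props length must equal n_groups")
            if any(p <= 0 for p in props):
                raise ValueError("group_props must be positive")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("group_props must sum to 1")
        object.__setattr__(self, "group_props", props)
        if not (0.0 < self.de_frac <= 1.0):
            raise ValueError("de_frac must be in (0, 1]")
        if self.lfc < 0:
            raise ValueError("lfc must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.lib_size_mu <= 0 or self.lib_size_sigma < 0:
            raise ValueError("library size parameters out of range")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance mu + phi mu^2."""
    shape = 1.0 / phi
    lam = rng.gamma(shape=shape, scale=mu * phi)
    return rng.poisson(lam).astype(float)


def group_fold_changes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Draw the groups x genes fold-change matrix.

    Per group, ``round(de_frac * n_genes)`` genes get a 2^(+-lfc)
    multiplier, sign by fair coin; all other entries are 1. Consumes the DE
    portion of the simulation's random stream.
    """
    n_de = int(round(cfg.de_frac * cfg.n_genes))
    fold = np.ones((cfg.n_groups, cfg.n_genes))
    for grp in range(cfg.n_groups):
        de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        fold[grp, de_idx] = 2.0 ** (signs * cfg.lfc)
    return fold


def simulate_dataset(cfg: SimConfig, name: str = "sim") -> SCDataset:
    """Draw one clustered count dataset with ground-truth labels.

    Fully reproducible from ``cfg.seed``; the number of DE genes per group
    is ``round(de_frac * n_genes)``.
    """
    rng = np.random.default_rng(cfg.seed)
    g, c, k = cfg.n_genes, cfg.n_cells, cfg.n_groups

    baseline = rng.gamma(shape=2.0, scale=1.0, size=g)
    baseline = np.maximum(baseline, 1e-8)

    fold = group_fold_changes(rng, cfg)

    groups = rng.choice(k, size=c, p=np.asarray(cfg.group_props))
    lib = rng.lognormal(mean=np.log(cfg.lib_size_mu),
                        sigma=cfg.lib_size_sigma, size=c)

    group_means = baseline[None, :] * fold              # k x g
    group_props_expr = group_means / group_means.sum(axis=1, keepdims=True)
    mu = group_props_expr[groups, :].T * lib[None, :]   # g x c

    counts = _nb_counts(rng, mu, cfg.dispersion)

    gene_ids = tuple(f"gene_{i + 1}" for i in range(g))
    cell_ids = tuple(f"cell_{j + 1}" for j in range(c))
    labels = tuple(f"group{grp + 1}" for grp in groups)
    return SCDataset(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                     labels=labels, name=name)


def simulate_pair(cfg: SimConfig,
                  depth_ratio: float = 10.0) -> tuple[SCDataset, SCDataset]:
    """Simulate a dense "plate-like" and a sparse "droplet-like" dataset.

    Both share the group structure and parameters of ``cfg``; the droplet
    variant has median library size ``lib_size_mu / depth_ratio``, hence a
    higher fraction of zero entries. The pair is reproducible from
    ``cfg.seed`` (the droplet dataset uses a derived seed).
    """
    if depth_ratio <= 1:
        raise ValueError("depth_ratio must exceed 1")
    plate = simulate_dataset(cfg, name="plate_like")
    droplet_cfg = replace(cfg, lib_size_mu=cfg.lib_size_mu / depth_ratio,
                          seed=cfg.seed + 1)
    droplet = simulate_dataset(droplet_cfg, name="droplet_like")
    return plate, droplet
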