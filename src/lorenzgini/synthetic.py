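"""Synthetic expression data with known ground truth.

Emulates the statistical regime of multi-class tumour expression studies:
a handful of informative genes whose class-conditional means are shifted
by a chosen effect size, buried among thousands of class-independent noise
genes, with optional correlated blocks of redundant informative genes
(shared latent factor) and strongly unbalanced class sizes.  Every stage
of the package can therefore be tested without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import BayesNetModel
from .data import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate", "generate_worked_example_model"]


@dataclass
class SyntheticSpec:
    """Generator settings.

    Defaults mirror the recovery benchmark used throughout the test suite:
    4 classes of unbalanced sizes 60/60/50/30, 1000 genes of which 20 are
    informative with a 2-SD between-class shift and unit within-class SD.
    ``n_correlated_blocks`` groups the informative genes into blocks that
    share both their class-mean pattern and a latent noise factor at
    ``block_correlation``, emulating redundant high-ranking genes.
    """

    n_classes: int = 4
    class_sizes: tuple = (60, 60, 50, 30)
    n_genes: int = 1000
    n_informative: int = 20
    effect_size: float = 2.0
    within_sd: float = 1.0
    n_correlated_blocks: int = 0
    block_correlation: float = 0.0
    log_normal: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes length must equal n_classes")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must all be >= 1")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError("need 0 <= n_informative <= n_genes")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block correlation must be in [0, 1)")
        if self.n_correlated_blocks > max(self.n_informative, 0):
            raise ValueError(
                "more correlated blocks than informative genes")
        if self.within_sd <= 0:
            raise ValueError("within-class SD must be positive")


def generate(spec: SyntheticSpec):
    """Draw a matrix from the spec; deterministic given ``spec.seed``.

    Returns ``(ExpressionMatrix, truth)`` where truth is a dict with the
    informative gene ids and the genes x classes table of true class means.
    Informative genes get class means at ``effect_size * within_sd`` times
    a centered random permutation of class levels; noise genes are
    class-independent Gaussians.  Genes are shuffled so informative ids
    occupy random rows.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.class_sizes)
    class_names = [f"C{i + 1}" for i in range(spec.n_classes)]
    labels = [class_names[c]
              for c, size in enumerate(spec.class_sizes) for _ in range(size)]
    label_idx = np.array([class_names.index(l) for l in labels])

    values = np.empty((spec.n_genes, n))
    class_means = np.zeros((spec.n_genes, spec.n_classes))

    # block membership for the informative genes (block id per gene, -1 none)
    block_of = np.full(spec.n_informative, -1, dtype=int)
    if spec.n_correlated_blocks > 0:
        chunks = np.array_split(np.arange(spec.n_informative),
                                spec.n_correlated_blocks)
        for b, chunk in enumerate(chunks):
            block_of[chunk] = b
    block_pattern = {}
    block_latent = {}
    rho = spec.block_correlation

    for g in range(spec.n_informative):
        b = block_of[g]
        if b >= 0 and b in block_pattern:
            levels = block_pattern[b]
        else:
            levels = rng.permutation(spec.n_classes).astype(float)
            levels -= levels.mean()
            if b >= 0:
                block_pattern[b] = levels
        mu = spec.effect_size * spec.within_sd * levels
        class_means[g] = mu
        if b >= 0 and rho > 0.0:
            if b not in block_latent:
                block_latent[b] = rng.standard_normal(n)
            eps = (np.sqrt(rho) * block_latent[b]
                   + np.sqrt(1.0 - rho) * rng.standard_normal(n))
        else:
            eps = rng.standard_normal(n)
        values[g] = mu[label_idx] + spec.within_sd * eps

    for g in range(spec.n_informative, spec.n_genes):
        values[g] = spec.within_sd * rng.standard_normal(n)

    if spec.log_normal:
        values = np.exp(values)
        class_means = np.exp(class_means + 0.5 * spec.within_sd ** 2)

    order = rng.permutation(spec.n_genes)
    values = values[order]
    class_means = class_means[order]
    width = len(str(spec.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}_at" for i in range(spec.n_genes)]
    informative = sorted(
        gene_ids[int(np.flatnonzero(order == g)[0])]
        for g in range(spec.n_informative))
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]

    matrix = ExpressionMatrix(gene_ids, sample_ids, values, labels,
                              class_names)
    truth = {
        "informative_genes": informative,
        "class_means": pd.DataFrame(class_means, index=gene_ids,
                                    columns=class_names),
    }
    return matrix, truth


# Printed per-gene conditional probabilities P(gene = 0 | class = normal)
# for the nine-marker, all-zero worked instance, and the printed prior.
_WORKED_GENES = ("JAG1", "MET", "CDH5", "ABCC3", "DSP",
                 "ABCD3", "PECAM1", "MAPRE2", "PDF5")
_WORKED_FACTORS_NORMAL = (0.95, 0.92, 0.03, 0.92, 0.95,
                          0.03, 0.08, 0.03, 0.03)
_WORKED_PRIOR_NORMAL = 0.09
_WORKED_CLASSES = ("normal", "adenocarcinoma", "squamous", "carcinoid")
# published per-class joints for the all-zero instance
_WORKED_JOINTS = {"adenocarcinoma": 0.0, "squamous": 0.3615e-4,
                  "carcinoid": 0.2647e-10}


def generate_worked_example_model() -> BayesNetModel:
    """Nine-gene, four-class naive-structure reference model.

    The normal-class CPT entries for the all-zero instance and the normal
    prior are the published values; all other entries are a synthetic
    reconstruction: the remaining prior mass 0.91 is split by the study's
    class sizes (139/21/20), the adenocarcinoma branch carries one zero
    factor, and the squamous/carcinoid branches use uniform per-gene
    factors equal to the ninth root of (published joint / prior), so the
    model reproduces all four published per-class joint probabilities on
    the all-zero instance.
    """
    genes = list(_WORKED_GENES)
    classes = list(_WORKED_CLASSES)
    rest = 1.0 - _WORKED_PRIOR_NORMAL
    priors = np.array([
        _WORKED_PRIOR_NORMAL,
        rest * 139 / 180,
        rest * 21 / 180,
        rest * 20 / 180,
    ])
    factors = {classes[0]: np.array(_WORKED_FACTORS_NORMAL)}
    for cls in ("squamous", "carcinoid"):
        j = classes.index(cls)
        per_gene = (_WORKED_JOINTS[cls] / priors[j]) ** (1.0 / 9.0)
        factors[cls] = np.full(9, per_gene)
    adeno = np.full(9, 0.5)
    adeno[0] = 0.0  # forces the published zero joint
    factors["adenocarcinoma"] = adeno

    cpts = {}
    for i, g in enumerate(genes):
        p0 = np.array([factors[c][i] for c in classes])
        cpts[g] = np.stack([p0, 1.0 - p0], axis=1)  # (class, value)
    return BayesNetModel(
        class_set=classes, gene_ids=genes, arities=[2] * 9,
        parents={g: [] for g in genes}, class_priors=priors, cpts=cpts,
        smoothing=0.0)
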