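"""Synthetic expression matrices with planted co-expression modules.

The generator emulates the structure the hybrid network method assumes in
real tumour expression data: groups of genes driven by a shared latent
signal (detectable by Pearson correlation when the dependence is linear,
only by mutual information when it is not) embedded in a background of
independent genes.

* A *linear* module draws one standard-normal latent factor per module and
  sets each member to ``sign * factor + noise``; signs are random so the
  module mixes positively and negatively co-regulated genes.
* A *nonlinear* module draws a latent ``u ~ Uniform(-1, 1)``; half the
  members follow ``u`` and the other half a symmetric function of ``u``
  (``u**2`` by default, ``cos(pi*u)`` optionally).  Across the two halves
  the population Pearson correlation is exactly zero while the mutual
  information stays high — the cleanest case where MI rescues an edge that
  correlation alone would miss.
* Background genes are independent standard normals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .ingest import ExpressionMatrix

__all__ = ["PlantedTruth", "generate_expression"]

_NONLINEAR_FAMILIES = ("square", "cosine")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels for a generated matrix.

    ``module_assignments`` maps every gene id to a module label or
    ``"background"``; ``module_kinds`` maps module labels to ``"linear"`` or
    ``"nonlinear"``; ``generator_params`` records the call that produced it.
    """

    module_assignments: dict[str, str]
    module_kinds: dict[str, str]
    generator_params: dict

    def members(self, label: str) -> set[str]:
        return {g for g, lab in self.module_assignments.items() if lab == label}

    def module_labels(self) -> list[str]:
        return list(self.module_kinds)


def generate_expression(
    n_genes: int,
    n_samples: int,
    linear_modules: list[int] | tuple[int, ...] = (),
    nonlinear_modules: list[int] | tuple[int, ...] = (),
    noise_sd: float = 0.2,
    seed: int = 0,
    nonlinear_family: str = "square",
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a genes x samples matrix with planted modules.

    Parameters
    ----------
    n_genes, n_samples
        Matrix dimensions; module sizes must sum to at most ``n_genes`` and
        ``n_samples`` must be at least 30 (below that neither measure is
        reliably estimable).
    linear_modules, nonlinear_modules
        Sizes of the planted modules, in gene order.
    noise_sd
        Standard deviation of the additive Gaussian noise on module members.
        Within a linear module the population |correlation| between members
        is 1 / (1 + noise_sd**2).
    seed
        Seeds a ``numpy.random.default_rng``; the output is reproducible
        bit-for-bit.
    nonlinear_family
        ``"square"`` (y = u**2) or ``"cosine"`` (y = cos(pi*u)) for the
        second half of each nonlinear module.
    """
    linear_modules = tuple(int(s) for s in linear_modules)
    nonlinear_modules = tuple(int(s) for s in nonlinear_modules)
    if any(s < 2 for s in linear_modules + nonlinear_modules):
        raise ValidationError("module sizes must be >= 2")
    total = sum(linear_modules) + sum(nonlinear_modules)
    if total > n_genes:
        raise ValidationError(f"module sizes sum to {total} > n_genes = {n_genes}")
    if n_samples < 30:
        raise ValidationError("need n_samples >= 30")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if nonlinear_family not in _NONLINEAR_FAMILIES:
        raise ValidationError(f"nonlinear_family must be one of {_NONLINEAR_FAMILIES}")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    values = np.empty((n_genes, n_samples))
    assignments: dict[str, str] = {}
    kinds: dict[str, str] = {}

    row = 0
    for k, size in enumerate(linear_modules, start=1):
        label = f"lin{k}"
        kinds[label] = "linear"
        factor = rng.standard_normal(n_samples)
        signs = rng.choice([-1.0, 1.0], size=size)
        for s in signs:
            values[row] = s * factor + noise_sd * rng.standard_normal(n_samples)
            assignments[gene_ids[row]] = label
            row += 1
    for k, size in enumerate(nonlinear_modules, start=1):
        label = f"nl{k}"
        kinds[label] = "nonlinear"
        u = rng.uniform(-1.0, 1.0, size=n_samples)
        if nonlinear_family == "square":
            v = u**2
        else:
            v = np.cos(np.pi * u)
        half = size // 2
        for g in range(size):
            signal = u if g < half else v
            values[row] = signal + noise_sd * rng.standard_normal(n_samples)
            assignments[gene_ids[row]] = label
            row += 1
    n_background = n_genes - row
    if n_background:
        values[row:] = rng.standard_normal((n_background, n_samples))
        for g in gene_ids[row:]:
            assignments[g] = "background"

    matrix = ExpressionMatrix(tuple(gene_ids), tuple(f"S{j + 1:04d}" for j in range(n_samples)), values)
    truth = PlantedTruth(
        module_assignments=assignments,
        module_kinds=kinds,
        generator_params={
            "n_genes": n_genes,
            "n_samples": n_samples,
            "linear_modules": linear_modules,
            "nonlinear_modules": nonlinear_modules,
            "noise_sd": noise_sd,
            "seed": seed,
            "nonlinear_family": nonlinear_family,
        },
    )
    return matrix, truth
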