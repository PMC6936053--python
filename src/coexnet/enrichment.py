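"""Over-representation analysis of modules against gene-set collections.

Standard one-sided hypergeometric test: given a background universe of N
genes, a gene set hitting K of them, and a module of m genes overlapping
the set in k, the p-value is P(X >= k) for X ~ Hypergeom(N, K, m).
False-discovery rates are Benjamini-Hochberg, adjusted across all sets
tested for the same module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import CoexnetWarning, ValidationError
from .ingest import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeometric_enrich", "enrichment_table"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap statistics of one module against one gene set."""

    module_id: str
    set_name: str
    overlap: int          # k
    module_size: int      # m
    set_size: int         # K, after intersecting with the background
    background_size: int  # N
    p_value: float
    fdr: float


def hypergeometric_enrich(
    module_genes: set[str] | frozenset[str],
    collection: GeneSetCollection,
    background: set[str] | list[str],
    module_id: str = "M1",
) -> list[EnrichmentResult]:
    """Test a module against every set in a collection.

    Sets are intersected with the background before testing; sets with no
    background overlap are skipped with a warning.  Results are sorted by
    p-value ascending (ties by set name).
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene universe is empty")
    module = set(module_genes)
    if not module <= background:
        missing = sorted(module - background)
        raise ValidationError(f"module genes outside background: {missing[:5]}")

    N, m = len(background), len(module)
    tested: list[tuple[str, int, int, float]] = []
    for name in collection.names():
        members = set(collection.members(name)) & background
        if not members:
            warnings.warn(
                f"gene set {name!r} has no overlap with the background; skipped",
                CoexnetWarning,
                stacklevel=2,
            )
            continue
        K = len(members)
        k = len(module & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        tested.append((name, k, K, min(p, 1.0)))

    if not tested:
        return []
    fdrs = stats.false_discovery_control([t[3] for t in tested], method="bh")
    results = [
        EnrichmentResult(
            module_id=module_id,
            set_name=name,
            overlap=k,
            module_size=m,
            set_size=K,
            background_size=N,
            p_value=p,
            fdr=float(min(q, 1.0)),
        )
        for (name, k, K, p), q in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results: set name, p-value, FDR, overlap and sizes."""
    return pd.DataFrame(
        [
            {
                "module_id": r.module_id,
                "set_name": r.set_name,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "overlap": r.overlap,
                "module_size": r.module_size,
                "set_size": r.set_size,
                "background_size": r.background_size,
            }
            for r in results
        ],
        columns=[
            "module_id",
            "set_name",
            "p_value",
            "fdr",
            "overlap",
            "module_size",
            "set_size",
            "background_size",
        ],
    )
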