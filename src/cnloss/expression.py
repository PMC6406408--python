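"""CPM computation, expression filtering and log-CPM transformation.

Two CPM variants are used deliberately: the *filtering* CPM is offset-free
(count / library size x 1e6), while the modelling transform adds the
standard half-count offset, log2((count + 0.5) / (libsize + 1) x 1e6), so
zero counts stay finite.  Library sizes are computed once on the unfiltered
matrix and frozen; gene filtering must not change the scale of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A real-valued genes x samples matrix tagged with its scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    lib_sizes: np.ndarray
    scale: str  # "cpm" | "log2cpm"

    def __post_init__(self) -> None:
        if self.scale not in ("cpm", "log2cpm"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with ids")


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: value[g, j] = counts[g, j] / lib_size[j] * 1e6."""
    zero = np.flatnonzero(counts.lib_sizes == 0)
    if zero.size:
        raise ValueError(
            f"zero library size for sample(s) {[counts.sample_ids[j] for j in zero]}")
    values = counts.counts / counts.lib_sizes[np.newaxis, :] * 1e6
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids),
                            values, counts.lib_sizes.copy(), "cpm")


def filter_genes(counts: CountMatrix, cpm_threshold: float = 5.0,
                 min_samples: int = 5) -> CountMatrix:
    """Keep genes with CPM strictly above ``cpm_threshold`` in at least
    ``min_samples`` samples.  Library sizes are retained, not recomputed."""
    expr = cpm(counts)
    keep = (expr.values > cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        logger.warning("expression filter removed every gene "
                       "(threshold %g in >= %d samples)",
                       cpm_threshold, min_samples)
    return counts.subset_genes(keep)


def log_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Offset log2-CPM: log2((count + 0.5) / (lib_size + 1) * 1e6)."""
    values = np.log2((counts.counts + 0.5)
                     / (counts.lib_sizes[np.newaxis, :] + 1.0) * 1e6)
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids),
                            values, counts.lib_sizes.copy(), "log2cpm")
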