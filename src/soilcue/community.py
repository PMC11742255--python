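"""OTU-table handling: rarefaction, alpha diversity, prevalence filtering.

Tables are held as a taxa × samples integer count matrix (taxa as rows, the
convention of most amplicon toolchains) with a domain label (bacteria or
fungi). Rarefaction subsamples every sample without replacement to a common
read depth so that richness and Shannon diversity are comparable across
samples; prevalence filtering removes rare OTUs before network inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Read depths the study rarefied to, per domain.
DEFAULT_RAREFACTION_DEPTHS = {"bacteria": 20981, "fungi": 8542}

#: Prevalence fractions below which OTUs are excluded before network inference.
DEFAULT_PREVALENCE_FRACTIONS = {"bacteria": 0.8, "fungi": 0.5}


@dataclass
class OtuTable:
    """A taxa × samples count matrix for one domain (bacteria or fungi)."""

    counts: pd.DataFrame  # index: taxon ids, columns: sample ids
    domain: str = "bacteria"

    def __post_init__(self) -> None:
        if self.domain not in {"bacteria", "fungi"}:
            raise ValueError(f"domain must be 'bacteria' or 'fungi', got {self.domain!r}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("taxon and sample ids must be unique")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "OtuTable":
        return OtuTable(self.counts[list(sample_ids)].copy(), self.domain)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("taxon_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, domain: str) -> "OtuTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, domain)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample, without replacement, to exactly ``depth`` reads.

    Deterministic at a fixed seed. Raises if any sample has fewer than
    ``depth`` reads, naming the offending samples.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    sums = table.counts.sum(axis=0)
    shallow = sums[sums < depth]
    if len(shallow):
        raise ValueError(
            f"rarefaction depth {depth} exceeds read count of samples: "
            f"{dict(shallow)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.values)
    for j, col in enumerate(table.counts.values.T):
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    rare = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(rare, table.domain)


def richness(column: pd.Series | np.ndarray) -> int:
    """Observed OTU richness: number of taxa with a nonzero count."""
    col = np.asarray(column)
    if col.sum() <= 0:
        raise ValueError("richness undefined for an all-zero sample")
    return int((col > 0).sum())


def shannon(column: pd.Series | np.ndarray) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ (natural log, nats)."""
    col = np.asarray(column, dtype=float)
    total = col.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero sample")
    p = col[col > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness and Shannon index for one rarefied table."""
    rows = [
        {
            "sample_id": s,
            "domain": table.domain,
            "richness": richness(table.counts[s]),
            "shannon": shannon(table.counts[s]),
        }
        for s in table.sample_ids
    ]
    return pd.DataFrame(rows)


def prevalence_filter(table: OtuTable, min_prevalence_fraction: float) -> OtuTable:
    """Keep taxa present (count > 0) in at least the given fraction of samples.

    The boundary is inclusive: a taxon present in exactly 80% of samples
    survives a 0.8 threshold (taxa occurring in *less than* the threshold
    fraction are excluded).
    """
    if not 0 < min_prevalence_fraction <= 1:
        raise ValueError("min_prevalence_fraction must be in (0, 1]")
    prevalence = (table.counts > 0).sum(axis=1) / table.n_samples
    keep = prevalence >= min_prevalence_fraction
    if not keep.any():
        logger.warning(
            "prevalence filter at %.2f removed all %d %s taxa",
            min_prevalence_fraction,
            table.n_taxa,
            table.domain,
        )
    return OtuTable(table.counts.loc[keep].copy(), table.domain)
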