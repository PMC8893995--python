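"""Bootstrap resampling of an observation table.

Each replicate draws ``replicate_size`` rows uniformly with replacement
from the original table; the concatenation of all replicates is the
bootstrap pseudopopulation ("mega file") that downstream models are fit
to.  Per-replicate column means are retained so the dispersion of the
sample mean can be read off directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConfigurationError, EmptyDataError, ObservationTable

logger = logging.getLogger(__name__)

__all__ = ["BootstrapConfig", "BootstrapResult", "resample", "bootstrap_mean_dispersion"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling plan: number of replicates, seed, and rows per replicate.

    ``replicate_size=None`` means each replicate has the size of the
    original sample.
    """

    n_replicates: int = 1000
    seed: int = 0
    replicate_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.replicate_size is not None and self.replicate_size < 1:
            raise ConfigurationError("replicate_size must be >= 1")


@dataclass(frozen=True)
class BootstrapResult:
    """Pseudopopulation plus per-replicate bookkeeping.

    ``indices`` has shape (n_replicates, replicate_size) and records which
    original row each resampled row copies; ``replicate_index`` tags every
    mega-table row with its replicate.  ``replicate_stats`` holds the mean
    of each numeric column per replicate.
    """

    mega_table: ObservationTable
    replicate_index: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)
    replicate_stats: pd.DataFrame = field(repr=False)

    @property
    def n_replicates(self) -> int:
        return self.indices.shape[0]

    @property
    def replicate_size(self) -> int:
        return self.indices.shape[1]

    def distinct_row_fractions(self) -> np.ndarray:
        """Fraction of distinct original rows appearing in each replicate."""
        m = self.indices.max() + 1 if self.indices.size else 0
        return np.array(
            [len(np.unique(rep)) / self.replicate_size for rep in self.indices]
        )

    def to_csv(self, path) -> None:
        """Export the mega table with a leading replicate-index column."""
        out = self.mega_table.data.copy()
        out.insert(0, "replicate", self.replicate_index)
        out.to_csv(path, index=False)


def resample(table: ObservationTable, config: BootstrapConfig) -> BootstrapResult:
    """Draw the bootstrap pseudopopulation from ``table``.

    Deterministic under ``config.seed``; every mega-table row is an exact
    copy of some original row.
    """
    m = len(table)
    if m == 0:
        raise EmptyDataError("cannot bootstrap an empty table")
    size = config.replicate_size if config.replicate_size is not None else m
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, m, size=(config.n_replicates, size))

    mega_df = table.data.iloc[idx.ravel()].reset_index(drop=True)
    mega = ObservationTable(specs=table.specs, data=mega_df)
    rep_index = np.repeat(np.arange(config.n_replicates), size)

    numeric = table.data.columns
    stats = (
        mega_df.assign(_rep=rep_index)
        .groupby("_rep")[list(numeric)]
        .mean()
        .rename_axis("replicate")
    )
    logger.info(
        "bootstrap: %d replicates x %d rows from %d originals (seed %d)",
        config.n_replicates, size, m, config.seed,
    )
    return BootstrapResult(
        mega_table=mega, replicate_index=rep_index, indices=idx, replicate_stats=stats
    )


def bootstrap_mean_dispersion(result: BootstrapResult, column: str) -> tuple[float, float]:
    """Mean and standard deviation of the per-replicate means of ``column``.

    With a single replicate the SD is reported as 0 with a warning.
    """
    if column not in result.replicate_stats.columns:
        raise ConfigurationError(f"unknown column {column!r}")
    means = result.replicate_stats[column].to_numpy()
    if len(means) == 1:
        warnings.warn("single replicate: dispersion of replicate means reported as 0")
        return float(means[0]), 0.0
    return float(means.mean()), float(means.std(ddof=1))
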