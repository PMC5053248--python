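"""In-memory containers for observed reports and upstream marginal draws.

Counts are stored as dense arrays over the full index grid together with
boolean presence masks at the report-block level: a block is one
(origin, destination, year, reporter) combination, which is either reported
with full age–sex detail, reported with a sex split only, or missing.  The two
forms are mutually exclusive per block ("a report is not used twice").

Array axis conventions used throughout the package::

    age–sex counts   z[k, f, t, a, s]   k: reporter (0=S sending, 1=R receiving)
    sex-only counts  z1[k, f, t, s]     f: flow index (see StudyDimensions.flows)
    block masks      mask[k, f, t]      t: year index, a: age index, s: sex (0=F)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dims import RECEIVING, SENDING, StudyDimensions
from .errors import ConfigError, DataError


@dataclass
class ReportedFlowData:
    """Observed migration reports for one study system.

    ``z_agesex`` holds full age–sex counts, ``z_sexonly`` the sex-split-only
    counts; each is valid only where the corresponding mask is true.
    """

    dims: StudyDimensions
    z_agesex: np.ndarray  # (2, F, T, A, 2) int64
    mask_agesex: np.ndarray  # (2, F, T) bool
    z_sexonly: np.ndarray  # (2, F, T, 2) int64
    mask_sexonly: np.ndarray  # (2, F, T) bool

    @classmethod
    def empty(cls, dims: StudyDimensions) -> "ReportedFlowData":
        F, T, A = dims.n_flows, dims.n_years, dims.n_ages
        return cls(
            dims=dims,
            z_agesex=np.zeros((2, F, T, A, 2), dtype=np.int64),
            mask_agesex=np.zeros((2, F, T), dtype=bool),
            z_sexonly=np.zeros((2, F, T, 2), dtype=np.int64),
            mask_sexonly=np.zeros((2, F, T), dtype=bool),
        )

    # ------------------------------------------------------------------
    @property
    def report_mask(self) -> np.ndarray:
        """Blocks carrying any report (either form), shape ``(2, F, T)``."""
        return self.mask_agesex | self.mask_sexonly

    def n_observed_blocks(self) -> int:
        return int(self.report_mask.sum())

    def validate(self) -> None:
        """Check shapes, integrality, mask disjointness and one-sidedness of
        rest-of-world flows; raise :class:`DataError` on violation."""
        d = self.dims
        F, T, A = d.n_flows, d.n_years, d.n_ages
        if self.z_agesex.shape != (2, F, T, A, 2):
            raise DataError(f"z_agesex has shape {self.z_agesex.shape}")
        if self.z_sexonly.shape != (2, F, T, 2):
            raise DataError(f"z_sexonly has shape {self.z_sexonly.shape}")
        if self.mask_agesex.shape != (2, F, T) or self.mask_sexonly.shape != (2, F, T):
            raise DataError("mask shape mismatch")
        if not np.issubdtype(self.z_agesex.dtype, np.integer) or not np.issubdtype(
            self.z_sexonly.dtype, np.integer
        ):
            raise DataError("counts must be integer")
        if (self.z_agesex[self.mask_agesex] < 0).any() or (
            self.z_sexonly[self.mask_sexonly] < 0
        ).any():
            raise DataError("negative counts")
        if (self.mask_agesex & self.mask_sexonly).any():
            raise DataError("a block reports both age-sex and sex-only counts")
        if d.has_rest_of_world:
            o_idx, d_idx = d.flow_arrays()
            from_row = o_idx == 0  # flows out of rest of world: receiving side only
            to_row = d_idx == 0  # flows into rest of world: sending side only
            if self.report_mask[SENDING][from_row].any():
                raise DataError("sending report for a flow originating in rest-of-world")
            if self.report_mask[RECEIVING][to_row].any():
                raise DataError("receiving report for a flow into rest-of-world")


@dataclass
class ODMarginalDraws:
    """Posterior draws of total origin–destination–year flows from an upstream
    model, consumed as plain numbers (persons/year)."""

    dims: StudyDimensions
    values: np.ndarray  # (n_draws, F, T) positive floats

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (
            self.dims.n_flows,
            self.dims.n_years,
        ):
            raise ConfigError(
                f"marginal draws have shape {self.values.shape}, expected "
                f"(n_draws, {self.dims.n_flows}, {self.dims.n_years})"
            )
        if not (self.values > 0).all():
            raise DataError("marginal flow draws must be strictly positive")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]
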