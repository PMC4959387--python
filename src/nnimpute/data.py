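"""Numeric case-by-attribute tables with an explicit missingness mask.

The container deliberately keeps three things together that imputation code
needs in lockstep: the value matrix, the observed/missing mask, and the role
of each attribute (at most one ``outcome``, any number of ``imputable`` or
``auxiliary`` columns).  Missing entries are stored as NaN *and* flagged in
the mask; the mask is authoritative.

When missingness is injected synthetically (see :mod:`nnimpute.synthetic`)
the pre-masking values are retained in ``truth`` so that imputation error can
be scored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLE_OUTCOME = "outcome"
ROLE_IMPUTABLE = "imputable"
ROLE_AUXILIARY = "auxiliary"
_VALID_ROLES = {ROLE_OUTCOME, ROLE_IMPUTABLE, ROLE_AUXILIARY}

#: strings interpreted as missing cells when reading CSV
NA_STRINGS = ["", "NA"]


@dataclass
class DataMatrix:
    """A numeric table of cases (rows) by attributes (columns).

    Parameters
    ----------
    values
        Float matrix; NaN where unobserved.
    mask
        Boolean matrix, ``True`` where observed.  Same shape as ``values``.
    attr_names
        Unique attribute identifiers, one per column.
    roles
        Per-attribute role tag: ``outcome``, ``imputable`` or ``auxiliary``.
        At most one attribute may be the outcome.
    truth
        Optional full value matrix before any synthetic masking, used to
        score imputation accuracy.  ``None`` for real incomplete data.
    original_mask
        After imputation, the mask the dataset had *before* filling, kept as
        provenance; ``None`` otherwise.
    """

    values: np.ndarray
    mask: np.ndarray
    attr_names: list[str]
    roles: list[str] = field(default=None)  # type: ignore[assignment]
    truth: np.ndarray | None = None
    original_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("values and mask must have identical shape")
        self.attr_names = list(self.attr_names)
        if len(self.attr_names) != self.values.shape[1]:
            raise ValueError("one attribute name per column required")
        if len(set(self.attr_names)) != len(self.attr_names):
            raise ValueError("attribute names must be unique")
        if self.roles is None:
            self.roles = [ROLE_AUXILIARY] * len(self.attr_names)
        self.roles = list(self.roles)
        if len(self.roles) != len(self.attr_names):
            raise ValueError("one role per attribute required")
        bad = set(self.roles) - _VALID_ROLES
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if self.roles.count(ROLE_OUTCOME) > 1:
            raise ValueError("at most one outcome attribute allowed")

    # -- basic geometry ---------------------------------------------------

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_attrs(self) -> int:
        return self.values.shape[1]

    def index(self, name: str) -> int:
        """Column index of attribute ``name``."""
        try:
            return self.attr_names.index(name)
        except ValueError:
            raise KeyError(f"unknown attribute {name!r}") from None

    @property
    def outcome_index(self) -> int | None:
        return self.roles.index(ROLE_OUTCOME) if ROLE_OUTCOME in self.roles else None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index(name)]

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def complete_rows(self) -> np.ndarray:
        """Boolean selector of rows with no missing entries."""
        return self.mask.all(axis=1)

    # -- copies and views -------------------------------------------------

    def copy(self) -> "DataMatrix":
        return DataMatrix(
            self.values.copy(),
            self.mask.copy(),
            list(self.attr_names),
            list(self.roles),
            None if self.truth is None else self.truth.copy(),
            None if self.original_mask is None else self.original_mask.copy(),
        )

    def take_rows(self, idx: np.ndarray) -> "DataMatrix":
        idx = np.asarray(idx)
        return DataMatrix(
            self.values[idx],
            self.mask[idx],
            list(self.attr_names),
            list(self.roles),
            None if self.truth is None else self.truth[idx],
            None if self.original_mask is None else self.original_mask[idx],
        )

    # -- pandas / CSV interface -------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[~self.mask] = np.nan
        return pd.DataFrame(vals, columns=self.attr_names)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str | None = None,
        imputable: list[str] | None = None,
    ) -> "DataMatrix":
        """Build from a numeric DataFrame; NaN cells become missing.

        ``outcome`` names the single outcome column; ``imputable`` lists the
        columns eligible for imputation scoring (default: every non-outcome
        column is auxiliary until tagged).
        """
        values = df.to_numpy(dtype=float)
        mask = ~np.isnan(values)
        names = [str(c) for c in df.columns]
        roles = []
        for name in names:
            if outcome is not None and name == outcome:
                roles.append(ROLE_OUTCOME)
            elif imputable is not None and name in imputable:
                roles.append(ROLE_IMPUTABLE)
            else:
                roles.append(ROLE_AUXILIARY)
        if outcome is not None and outcome not in names:
            raise KeyError(f"outcome column {outcome!r} not in table")
        return cls(values, mask, names, roles)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        outcome: str | None = None,
        imputable: list[str] | None = None,
    ) -> "DataMatrix":
        """Read a CSV with a header row; empty cells or literal ``NA`` are missing."""
        df = pd.read_csv(path, na_values=NA_STRINGS, keep_default_na=False)
        return cls.from_dataframe(df, outcome=outcome, imputable=imputable)

    def write_csv(self, path: str | Path) -> None:
        """Write CSV; missing cells are emitted as empty fields (mask round-trips)."""
        self.to_dataframe().to_csv(path, index=False, na_rep="")
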