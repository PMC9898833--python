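"""Patient-by-variable cohort container and CSV round-tripping.

A :class:`Cohort` holds the observed feature matrix (``NaN`` marks a missing
cell), the binary outcome, per-variable metadata, and — for synthetic cohorts —
the complete ground-truth matrix used by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Recognised variable kinds.  ``ordinal`` appears after L/N/H discretization.
KINDS = ("continuous", "discrete", "diagnosis", "ordinal")

META_COLUMNS = ("kind", "ref_low", "ref_high", "synonym_group", "impute")


def _empty_meta() -> pd.DataFrame:
    return pd.DataFrame(columns=list(META_COLUMNS)).rename_axis("name")


@dataclass
class Cohort:
    """Observed matrix + missingness mask + outcome + variable metadata.

    Parameters
    ----------
    data:
        n x m observed matrix; ``NaN`` marks missing cells.
    outcome:
        Binary (0/1) outcome, aligned with ``data`` rows.
    meta:
        Per-variable metadata indexed by variable name with columns
        ``kind`` (one of :data:`KINDS`), ``ref_low``/``ref_high`` (reference
        range for continuous labs), ``synonym_group`` and ``impute`` (whether
        the variable is a target for imputation; identifiers such as age and
        gender are flagged ``False``).
    complete:
        Optional ground-truth matrix without missing entries (synthetic
        cohorts only).
    """

    data: pd.DataFrame
    outcome: pd.Series
    meta: pd.DataFrame = field(default_factory=_empty_meta)
    complete: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.outcome = pd.Series(np.asarray(self.outcome, dtype=int),
                                 index=self.data.index, name="outcome")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome values must be binary 0/1")
        if len(self.outcome) != len(self.data):
            raise ValueError("outcome length does not match data rows")
        if "impute" not in self.meta.columns:
            self.meta = self.meta.assign(impute=True)
        missing_meta = [v for v in self.data.columns if v not in self.meta.index]
        if missing_meta:
            raise ValueError(f"variables without metadata: {missing_meta}")
        bad_kind = [v for v in self.data.columns
                    if self.meta.loc[v, "kind"] not in KINDS]
        if bad_kind:
            raise ValueError(f"unknown variable kind for: {bad_kind}")
        if self.complete is not None:
            if self.complete.isna().any().any():
                raise ValueError("complete matrix must have no missing entries")
            if list(self.complete.columns) != list(self.data.columns):
                raise ValueError("complete matrix columns differ from data")

    # ------------------------------------------------------------------ views
    @property
    def mask(self) -> pd.DataFrame:
        """Boolean n x m frame, True where a cell is missing."""
        return self.data.isna()

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def variables_of_kind(self, *kinds: str) -> list[str]:
        return [v for v in self.data.columns if self.meta.loc[v, "kind"] in kinds]

    def missing_fraction(self) -> pd.Series:
        """Per-variable fraction of missing cells."""
        return self.data.isna().mean()

    # ------------------------------------------------------------ derivations
    def subset_variables(self, names: Sequence[str]) -> "Cohort":
        unknown = [v for v in names if v not in self.data.columns]
        if unknown:
            raise KeyError(f"unknown variables: {unknown}")
        names = list(names)
        return Cohort(
            data=self.data[names].copy(),
            outcome=self.outcome.copy(),
            meta=self.meta.loc[names].copy(),
            complete=None if self.complete is None else self.complete[names].copy(),
        )

    def subset_rows(self, index: Iterable[int]) -> "Cohort":
        idx = np.asarray(list(index))
        return Cohort(
            data=self.data.iloc[idx].reset_index(drop=True),
            outcome=self.outcome.iloc[idx].reset_index(drop=True),
            meta=self.meta.copy(),
            complete=None if self.complete is None
            else self.complete.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "Cohort":
        return Cohort(
            data=self.data.copy(),
            outcome=self.outcome.copy(),
            meta=self.meta.copy(),
            complete=None if self.complete is None else self.complete.copy(),
        )

    # -------------------------------------------------------------------- IO
    def to_csv(self, cohort_path: str | Path, meta_path: str | Path | None = None,
               mask_path: str | Path | None = None) -> None:
        """Write cohort (features + ``outcome`` column), metadata, and mask.

        Missing cells are written as empty fields.
        """
        out = self.data.copy()
        out["outcome"] = self.outcome.values
        out.to_csv(cohort_path, index=False)
        if meta_path is not None:
            self.meta.reset_index().to_csv(meta_path, index=False)
        if mask_path is not None:
            self.mask.astype(int).to_csv(mask_path, index=False)

    @classmethod
    def from_csv(cls, cohort_path: str | Path,
                 meta_path: str | Path | None = None) -> "Cohort":
        frame = pd.read_csv(cohort_path)
        if "outcome" not in frame.columns:
            raise ValueError("cohort CSV must contain an 'outcome' column")
        outcome = frame.pop("outcome")
        if meta_path is not None:
            meta = pd.read_csv(meta_path).set_index("name")
        else:
            meta = pd.DataFrame(
                {"kind": "continuous", "ref_low": np.nan, "ref_high": np.nan,
                 "synonym_group": "", "impute": True},
                index=pd.Index(frame.columns, name="name"),
            )
        if "impute" in meta.columns:
            meta["impute"] = meta["impute"].astype(bool)
        return cls(data=frame, outcome=outcome, meta=meta)


def make_meta(names: Sequence[str], kinds: Sequence[str],
              ref_ranges: dict[str, tuple[float, float]] | None = None,
              synonym_groups: dict[str, str] | None = None,
              impute: dict[str, bool] | None = None) -> pd.DataFrame:
    """Assemble a metadata frame from per-variable attributes."""
    ref_ranges = ref_ranges or {}
    synonym_groups = synonym_groups or {}
    impute = impute or {}
    rows = []
    for name, kind in zip(names, kinds, strict=True):
        low, high = ref_ranges.get(name, (np.nan, np.nan))
        rows.append({
            "name": name, "kind": kind, "ref_low": low, "ref_high": high,
            "synonym_group": synonym_groups.get(name, ""),
            "impute": impute.get(name, True),
        })
    return pd.DataFrame(rows).set_index("name")
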