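"""Variable screening: synonym merging, missingness and prevalence filters,
and L/N/H discretization of continuous labs against reference ranges.

Screening order follows the study protocol: merge free-text diagnosis
synonyms first, then filter; filters never modify cell values, only column
membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

#: ordinal codes for the L/N/H mapping of a lab value against its reference
#: range (below / within / above); ordered L < N < H.
L, N, H = 0, 1, 2


@dataclass
class ScreenReport:
    """Outcome of a screening pass over a set of variables."""

    kept: list[str] = field(default_factory=list)
    #: (variable, reason in {"missingness", "prevalence"}, offending value)
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    #: (original name, unified name) for every synonym rename
    merge_log: list[tuple[str, str]] = field(default_factory=list)

    def apply(self, cohort: Cohort) -> Cohort:
        """Project the cohort onto kept variables (others pass through)."""
        screened = set(self.kept) | {d[0] for d in self.dropped}
        keep = [v for v in cohort.variables
                if v not in screened or v in self.kept]
        return cohort.subset_variables(keep)


def merge_synonyms(cohort: Cohort, mapping: dict[str, str]
                   ) -> tuple[Cohort, ScreenReport]:
    """Combine synonym diagnosis columns by logical OR.

    ``mapping`` is many-to-one (original -> unified name).  Only binary
    diagnosis variables may be merged; a missing cell counts as absence of
    the diagnosis when OR-ing, which mirrors how free-text diagnoses are
    recorded (no record = not diagnosed).
    """
    report = ScreenReport()
    if not mapping:
        return cohort.copy(), report
    unknown = [v for v in mapping if v not in cohort.variables]
    if unknown:
        raise KeyError(f"synonym mapping references unknown variables: {unknown}")
    non_dx = [v for v in mapping if cohort.meta.loc[v, "kind"] != "diagnosis"]
    if non_dx:
        raise ValueError(f"only diagnosis variables may be merged: {non_dx}")

    groups: dict[str, list[str]] = {}
    for orig, unified in mapping.items():
        groups.setdefault(unified, []).append(orig)

    data = cohort.data.copy()
    meta = cohort.meta.copy()
    complete = None if cohort.complete is None else cohort.complete.copy()
    for unified, originals in groups.items():
        merged = (data[originals].fillna(0.0) > 0).any(axis=1).astype(float)
        data = data.drop(columns=originals)
        first = originals[0]
        meta_row = meta.loc[[first]].rename(index={first: unified})
        meta_row.loc[unified, "synonym_group"] = unified
        meta = pd.concat([meta.drop(index=originals), meta_row])
        data[unified] = merged
        if complete is not None:
            cm = (complete[originals] > 0).any(axis=1).astype(float)
            complete = complete.drop(columns=originals)
            complete[unified] = cm
        for orig in originals:
            report.merge_log.append((orig, unified))

    meta = meta.loc[data.columns]
    merged_cohort = Cohort(data=data, outcome=cohort.outcome.copy(),
                           meta=meta, complete=complete)
    return merged_cohort, report


def filter_missingness(cohort: Cohort, threshold: float = 0.8) -> ScreenReport:
    """Drop any variable whose missing fraction is >= ``threshold``.

    The boundary drops: a variable missing in exactly 80% of rows is
    filtered out under the default threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    report = ScreenReport()
    fractions = cohort.missing_fraction()
    for name in cohort.variables:
        frac = float(fractions[name])
        if frac >= threshold:
            report.dropped.append((name, "missingness", frac))
        else:
            report.kept.append(name)
    return report


def filter_prevalence(cohort: Cohort, threshold: float = 0.05,
                      per_class: bool = True,
                      variables: list[str] | None = None) -> ScreenReport:
    """Keep diagnosis variables whose prevalence is strictly above ``threshold``.

    With ``per_class`` (the default) prevalence is computed separately within
    each outcome class and a variable survives if it exceeds the threshold in
    either class — so a diagnosis common among the rare positives is retained
    even if globally rare.  A missing diagnosis cell counts as absence.
    """
    if variables is None:
        variables = cohort.variables_of_kind("diagnosis")
    report = ScreenReport()
    y = cohort.outcome.to_numpy()
    for name in variables:
        col = cohort.data[name].fillna(0.0).to_numpy()
        uniq = set(np.unique(col))
        if not uniq <= {0.0, 1.0}:
            raise ValueError(f"prevalence filter requires binary variable: {name}")
        if per_class:
            prevs = [col[y == c].mean() for c in (0, 1) if (y == c).any()]
            prev = max(prevs)
        else:
            prev = col.mean()
        if prev > threshold:
            report.kept.append(name)
        else:
            report.dropped.append((name, "prevalence", float(prev)))
    return report


def discretize_lnh(cohort: Cohort,
                   variables: list[str] | None = None) -> Cohort:
    """Map continuous lab values to ordinal L/N/H codes (0/1/2).

    ``value < ref_low`` -> L; ``ref_low <= value <= ref_high`` -> N (bounds
    inclusive); ``value > ref_high`` -> H.  Missing cells stay missing.
    Converted variables get kind ``ordinal``, so re-applying the operation
    is rejected by the kind check.
    """
    if variables is None:
        variables = cohort.variables_of_kind("continuous")
    out = cohort.copy()
    for name in variables:
        if out.meta.loc[name, "kind"] != "continuous":
            raise ValueError(f"{name} is not continuous (kind="
                             f"{out.meta.loc[name, 'kind']})")
        low = out.meta.loc[name, "ref_low"]
        high = out.meta.loc[name, "ref_high"]
        if pd.isna(low) or pd.isna(high):
            raise ValueError(f"variable '{name}' has no reference range")
        values = out.data[name]
        codes = pd.Series(np.full(len(values), np.nan), index=values.index)
        codes[values < low] = L
        codes[(values >= low) & (values <= high)] = N
        codes[values > high] = H
        out.data[name] = codes
        out.meta.loc[name, "kind"] = "ordinal"
        if out.complete is not None:
            cvals = out.complete[name]
            ccodes = pd.Series(np.full(len(cvals), np.nan), index=cvals.index)
            ccodes[cvals < low] = L
            ccodes[(cvals >= low) & (cvals <= high)] = N
            ccodes[cvals > high] = H
            out.complete[name] = ccodes
    return out
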