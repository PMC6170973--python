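"""Reading, writing and filtering of allergen-component IgE panels.

A *panel* is a subjects x components matrix of component-specific IgE
measurements on the ISAC standardized unit (ISU) scale, one panel per
follow-up age.  Panels are binarized at a positivity cutoff (0.30 ISU by
default), components are called *active* at an age when at least
``min_positive`` subjects respond, and subjects with at least one positive
response to an active component are the *responders* analysed at that age.

Missing data are whole-subject: a subject either has a complete row or an
all-NaN row (absent at that follow-up).  Activity counts only ever use
present subjects, so denominators vary by age.
"""

from __future__ import annotations

import csv
import decimal
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantPanel",
    "BinaryPanel",
    "ActivityTimeline",
    "ComponentMeta",
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "read_component_meta",
    "binarize_panel",
    "active_components",
    "responder_subjects",
    "build_activity_timeline",
    "classify_dropout_cause",
    "percent",
    "compare_groups",
]

POSITIVITY_THRESHOLD_ISU = 0.30
MIN_POSITIVE_DEFAULT = 3

ACTIVE = "active"
INACTIVE = "inactive"
NEVER_ACTIVE = "never-active"

RESOLUTION = "resolution"
ATTRITION = "attrition"
UNDETERMINED = "undetermined"


class PanelFormatError(ValueError):
    """Raised for malformed panel files (with line numbers where possible)."""


def _check_axes(subject_ids: Sequence[str], component_ids: Sequence[str]) -> None:
    for name, ids in (("subject", subject_ids), ("component", component_ids)):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise PanelFormatError(f"duplicate {name} ID: {x!r}")
            seen.add(x)


@dataclass
class QuantPanel:
    """Continuous IgE panel at one age.

    ``data`` is subjects (rows) x components (columns), in ISU.  Rows that
    are entirely NaN encode subjects absent at this age; partial missingness
    is rejected.
    """

    age_label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(list(self.data.index), list(self.data.columns))
        values = self.data.to_numpy(dtype=float)
        row_nan = np.isnan(values).any(axis=1)
        row_all_nan = np.isnan(values).all(axis=1)
        partial = row_nan & ~row_all_nan
        if partial.any():
            bad = self.data.index[partial][0]
            raise PanelFormatError(
                f"subject {bad!r}: partially missing row (missingness must be whole-row)"
            )
        if values.size and not np.isnan(values).all():
            if np.nanmin(values) < 0:
                raise PanelFormatError("negative ISU value in panel")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def component_ids(self) -> list[str]:
        return list(self.data.columns)

    def present_subjects(self) -> list[str]:
        mask = ~self.data.isna().all(axis=1)
        return list(self.data.index[mask])


@dataclass
class BinaryPanel:
    """Binarized panel: 1 = positive (ISU >= threshold), 0 = negative.

    Absent subjects keep their all-NaN rows, so the dtype is float.
    """

    age_label: str
    data: pd.DataFrame
    threshold_used: float

    def __post_init__(self) -> None:
        if not self.threshold_used > 0:
            raise ValueError("threshold_used must be > 0")
        _check_axes(list(self.data.index), list(self.data.columns))
        values = self.data.to_numpy(dtype=float)
        present = ~np.isnan(values)
        if not np.isin(values[present], (0.0, 1.0)).all():
            raise ValueError("BinaryPanel values must be 0/1 (or whole-row NaN)")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def component_ids(self) -> list[str]:
        return list(self.data.columns)

    def present_subjects(self) -> list[str]:
        mask = ~self.data.isna().all(axis=1)
        return list(self.data.index[mask])

    def restrict(self, subjects: Iterable[str], components: Iterable[str]) -> "BinaryPanel":
        sub = self.data.loc[list(subjects), list(components)]
        return BinaryPanel(self.age_label, sub, self.threshold_used)


@dataclass
class ComponentMeta:
    """Per-component annotation: source organism and protein family."""

    table: pd.DataFrame  # index = component_id; columns: source, family

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise PanelFormatError(f"duplicate component ID in metadata: {dup!r}")

    def source_of(self, component_id: str) -> str:
        return str(self.table.loc[component_id, "source"])


@dataclass
class ActivityTimeline:
    """Per-component activity status across ages, with drop-out annotations.

    ``status`` is a components x ages frame with values in
    {active, inactive, never-active}.  ``dropouts`` records every
    active -> inactive transition between consecutive measured ages
    (a component may re-activate later) with a cause in
    {resolution, attrition, undetermined} once classified.
    """

    ages: list[str]
    status: pd.DataFrame
    first_active_age: pd.Series  # NaN-free for ever-active; <NA> otherwise
    dropouts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["component", "age", "cause"])
    )

    def ever_active(self) -> list[str]:
        mask = (self.status == ACTIVE).any(axis=1)
        return list(self.status.index[mask])


# ---------------------------------------------------------------------------
# file I/O


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_panel(path: str | Path, age_label: str) -> QuantPanel:
    """Read a delimited-text panel (header of component names, first column
    subject ID) into a :class:`QuantPanel`.

    Comma- or tab-delimited, auto-detected from the header line.  Rows with
    the wrong field count or non-numeric cells are reported with their
    1-based line numbers.  Blank cells are allowed only for whole-row-missing
    subjects.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise PanelFormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    header = rows[0]
    if len(header) < 2:
        raise PanelFormatError(f"{path}: header must contain a subject-ID column and components")
    components = [c.strip() for c in header[1:]]
    n_fields = len(header)
    subject_ids: list[str] = []
    values: list[list[float]] = []
    errors: list[str] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) != n_fields:
            errors.append(f"line {lineno}: expected {n_fields} fields, found {len(row)}")
            continue
        subject_ids.append(row[0].strip())
        parsed: list[float] = []
        for j, cell in enumerate(row[1:], start=1):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                parsed.append(np.nan)
                continue
            try:
                v = float(cell)
            except ValueError:
                errors.append(f"line {lineno}: non-numeric cell {cell!r} (column {header[j]!r})")
                v = np.nan
            else:
                if v < 0:
                    raise PanelFormatError(
                        f"{path}: line {lineno}: negative ISU {v} (column {header[j]!r})"
                    )
            parsed.append(v)
        values.append(parsed)
    if errors:
        raise PanelFormatError(f"{path}: malformed rows:\n  " + "\n  ".join(errors))
    frame = pd.DataFrame(values, index=subject_ids, columns=components, dtype=float)
    return QuantPanel(age_label=age_label, data=frame)


def _format_cell(v: float) -> str:
    if np.isnan(v):
        return ""
    # shortest repr that parses back to exactly v: "%g" would round
    # threshold-adjacent values across the positivity boundary
    v = float(v)
    return repr(v) if v != int(v) else format(v, "g")


def write_panel(panel: QuantPanel | BinaryPanel, path: str | Path, delimiter: str = ",") -> None:
    """Write a panel in the same delimited-text layout :func:`read_panel` reads."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["subject_id", *panel.component_ids])
        values = panel.data.to_numpy(dtype=float)
        for sid, row in zip(panel.subject_ids, values):
            w.writerow([sid, *(_format_cell(v) for v in row)])


def read_component_meta(path: str | Path) -> ComponentMeta:
    """Read component metadata (component_id, source, family) from delimited text."""
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.read_text() else ""
    delim = _sniff_delimiter(first)
    table = pd.read_csv(path, sep=delim, dtype=str).set_index("component_id")
    return ComponentMeta(table=table)


# ---------------------------------------------------------------------------
# filtering


def binarize_panel(
    panel: QuantPanel, threshold: float = POSITIVITY_THRESHOLD_ISU
) -> BinaryPanel:
    """Threshold a continuous panel: positive iff ISU >= threshold (inclusive).

    Absent subjects (all-NaN rows) stay absent.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    values = panel.data.to_numpy(dtype=float)
    out = np.where(np.isnan(values), np.nan, (values >= threshold).astype(float))
    frame = pd.DataFrame(out, index=panel.data.index, columns=panel.data.columns)
    return BinaryPanel(age_label=panel.age_label, data=frame, threshold_used=threshold)


def active_components(
    panel: BinaryPanel, min_positive: int = MIN_POSITIVE_DEFAULT
) -> list[str]:
    """Components with >= ``min_positive`` positive responders at this age.

    Order-preserving (panel column order); counts use present subjects only.
    """
    sums = panel.data.sum(axis=0, skipna=True)
    return [c for c in panel.component_ids if sums[c] >= min_positive]


def responder_subjects(panel: BinaryPanel, active: Sequence[str]) -> list[str]:
    """Subjects with >= 1 positive response among the active components.

    The complement (present, all-negative subjects) is the candidate
    "nonsensitized" group at this age.
    """
    active = list(active)
    unknown = set(active) - set(panel.component_ids)
    if unknown:
        raise ValueError(f"active components not in panel: {sorted(unknown)}")
    if not active:
        warnings.warn("empty active set: no responders", stacklevel=2)
        return []
    sub = panel.data[active]
    mask = (sub == 1).any(axis=1)
    return list(panel.data.index[mask])


def build_activity_timeline(
    panels: Sequence[BinaryPanel], min_positive: int = MIN_POSITIVE_DEFAULT
) -> ActivityTimeline:
    """Track per-component activity across ages and record drop-out events.

    A drop-out is any active -> inactive transition between consecutive
    measured ages; components may re-activate afterwards.  With fewer than
    two panels no drop-outs can be annotated.
    """
    ages = [p.age_label for p in panels]
    if len(set(ages)) != len(ages):
        raise ValueError("panel age labels must be unique")
    universe: list[str] = []
    for p in panels:
        for c in p.component_ids:
            if c not in universe:
                universe.append(c)

    active_by_age: dict[str, set[str]] = {}
    for p in panels:
        active_by_age[p.age_label] = set(active_components(p, min_positive))

    status = pd.DataFrame(INACTIVE, index=universe, columns=ages, dtype=object)
    for age in ages:
        for c in active_by_age[age]:
            status.loc[c, age] = ACTIVE

    first_active: dict[str, object] = {}
    for c in universe:
        actives = [age for age in ages if status.loc[c, age] == ACTIVE]
        if actives:
            first_active[c] = actives[0]
        else:
            first_active[c] = pd.NA
            status.loc[c, :] = NEVER_ACTIVE

    records = []
    for c in universe:
        if first_active[c] is pd.NA:
            continue
        for prev_age, age in zip(ages, ages[1:]):
            if status.loc[c, prev_age] == ACTIVE and status.loc[c, age] == INACTIVE:
                records.append({"component": c, "age": age, "cause": UNDETERMINED})
    dropouts = pd.DataFrame(records, columns=["component", "age", "cause"])
    return ActivityTimeline(
        ages=ages,
        status=status,
        first_active_age=pd.Series(first_active, dtype=object),
        dropouts=dropouts,
    )


def classify_dropout_cause(
    timeline: ActivityTimeline, panels: Sequence[BinaryPanel]
) -> ActivityTimeline:
    """Attribute each drop-out to resolved sensitization vs subject attrition.

    For a component dropping out at age t, the subjects positive to it at the
    preceding measured age are traced to age t:

    * all present and now negative      -> resolution
    * all absent from the age-t panel   -> attrition
    * anything else (mixed, or a previously positive subject still positive
      while the component fell below the activity rule) -> undetermined
    """
    by_age = {p.age_label: p for p in panels}
    ages = timeline.ages
    causes = []
    for rec in timeline.dropouts.itertuples(index=False):
        c, age = rec.component, rec.age
        prev_age = ages[ages.index(age) - 1]
        prev_panel, cur_panel = by_age[prev_age], by_age[age]
        prev_col = prev_panel.data[c]
        prev_positive = [s for s in prev_panel.data.index if prev_col.get(s) == 1]
        cur_present = set(cur_panel.present_subjects())
        present = [s for s in prev_positive if s in cur_present]
        if not prev_positive:
            causes.append(UNDETERMINED)
        elif not present:
            causes.append(ATTRITION)
        elif len(present) == len(prev_positive) and all(
            cur_panel.data.loc[s, c] == 0 for s in present
        ):
            causes.append(RESOLUTION)
        else:
            causes.append(UNDETERMINED)
    dropouts = timeline.dropouts.copy()
    dropouts["cause"] = causes
    return ActivityTimeline(
        ages=timeline.ages,
        status=timeline.status,
        first_active_age=timeline.first_active_age,
        dropouts=dropouts,
    )


# ---------------------------------------------------------------------------
# demographics utilities


def percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, round-half-up to 2 decimals (printed-table style)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    value = decimal.Decimal(100) * decimal.Decimal(numerator) / decimal.Decimal(denominator)
    return float(value.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def compare_groups(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Included-vs-excluded 2x2 comparison: (statistic, p).

    Chi-square with continuity correction by default; Fisher's exact test
    (statistic = odds ratio) when any expected count is below 5.  A zero
    row or column margin yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table: p set to 1", stacklevel=2)
        return 0.0, 1.0
    expected = stats.contingency.expected_freq(t)
    if (expected < 5).any():
        res = stats.fisher_exact(t)
        return float(res.statistic), float(res.pvalue)
    res = stats.chi2_contingency(t, correction=True)
    return float(res.statistic), float(res.pvalue)
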