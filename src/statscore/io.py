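"""Reading and writing of the plain-text interchange formats.

All experiment data travel as three tab-separated files plus one JSON file:

``counts.tsv``
    First column ``gene`` (unique ids), remaining columns one per sample,
    integer counts, header row.
``lengths.tsv``
    Two columns ``gene`` and ``length`` (bases).
``samples.tsv``
    Columns ``sample``, ``condition``, ``role`` (control|reference|query) and
    ``reference_stat`` (may be empty for non-reference conditions).
``truth.json``
    Ground-truth serialization of a simulation (see :mod:`statscore.simdata`).

The in-memory container is :class:`CountMatrix`, which couples the count
table with the sample sheet and validates their mutual consistency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParseError, ValidationError

ROLES = ("control", "reference", "query")

SAMPLE_SHEET_COLUMNS = ["sample", "condition", "role", "reference_stat"]


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus per-sample condition metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
    samples
        DataFrame indexed by sample id with columns ``condition``, ``role``
        and ``reference_stat`` (``None``/NaN allowed for the latter).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    _condition_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValidationError(
                "counts columns and sample sheet disagree; "
                f"mismatched samples: {sorted(missing)[:5] or 'order differs'}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        controls = self.samples.loc[self.samples["role"] == "control", "condition"]
        if controls.nunique() != 1:
            raise ValidationError(
                f"exactly one control condition required, found {controls.nunique()}"
            )
        # a condition must not straddle roles
        role_counts = self.samples.groupby("condition")["role"].nunique()
        if (role_counts > 1).any():
            bad = role_counts[role_counts > 1].index.tolist()
            raise ValidationError(f"conditions with conflicting roles: {bad}")

    # -- convenience accessors ----------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def control_condition(self) -> str:
        return self.samples.loc[self.samples["role"] == "control", "condition"].iloc[0]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        out = list(self.samples.index[self.samples["condition"] == condition])
        if not out:
            raise ValidationError(f"unknown condition: {condition!r}")
        return out

    def condition_role(self, condition: str) -> str:
        return self.samples.loc[self.samples["condition"] == condition, "role"].iloc[0]

    def reference_conditions_of(self, stat: str) -> list[str]:
        mask = (self.samples["role"] == "reference") & (
            self.samples["reference_stat"] == stat
        )
        return list(dict.fromkeys(self.samples.loc[mask, "condition"]))


# -- parsing helpers ---------------------------------------------------------

def _read_table(path: Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{what} file not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {n_fields}"
                )
            rows.append((lineno, fields))
    return header, rows


def read_counts(path: Path) -> pd.DataFrame:
    """Read a counts TSV into a gene x sample integer DataFrame."""
    header, rows = _read_table(path, "counts")
    genes, data = [], []
    for lineno, fields in rows:
        genes.append(fields[0])
        try:
            data.append([int(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer count ({exc})")
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=header[1:])
    return df.astype(np.int64)


def read_lengths(path: Path) -> pd.Series:
    """Read a two-column gene-length TSV into a Series (bases)."""
    header, rows = _read_table(path, "lengths")
    if len(header) != 2:
        raise ParseError(f"{path}: expected 2 columns, found {len(header)}")
    genes, lengths = [], []
    for lineno, fields in rows:
        genes.append(fields[0])
        try:
            lengths.append(int(fields[1]))
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-integer length {fields[1]!r}")
    return pd.Series(lengths, index=pd.Index(genes, name="gene"), name="length")


def read_sample_sheet(path: Path) -> pd.DataFrame:
    """Read samples.tsv; returns a DataFrame indexed by sample id."""
    header, rows = _read_table(path, "sample sheet")
    if header != SAMPLE_SHEET_COLUMNS:
        raise ParseError(
            f"{path}: expected columns {SAMPLE_SHEET_COLUMNS}, found {header}"
        )
    recs = []
    for lineno, fields in rows:
        sample, condition, role, ref_stat = fields
        if role not in ROLES:
            raise ParseError(f"{path}: line {lineno}: unknown role {role!r}")
        recs.append((sample, condition, role, ref_stat or None))
    df = pd.DataFrame(recs, columns=SAMPLE_SHEET_COLUMNS).set_index("sample")
    if not df.index.is_unique:
        raise ParseError(f"{path}: duplicate sample ids")
    return df


def read_count_matrix(counts_path: Path, samples_path: Path) -> CountMatrix:
    """Read counts + sample sheet and cross-validate them."""
    counts = read_counts(counts_path)
    samples = read_sample_sheet(samples_path)
    missing = set(samples.index) - set(counts.columns)
    if missing:
        raise ValidationError(
            f"sample sheet lists samples absent from counts: {sorted(missing)}"
        )
    extra = set(counts.columns) - set(samples.index)
    if extra:
        raise ValidationError(
            f"counts contain samples absent from sample sheet: {sorted(extra)}"
        )
    return CountMatrix(counts[list(samples.index)], samples)


# -- writing ------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def write_lengths(lengths: pd.Series, path: Path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene")


def write_sample_sheet(samples: pd.DataFrame, path: Path) -> None:
    out = samples.copy()
    out["reference_stat"] = out["reference_stat"].fillna("")
    out.to_csv(path, sep="\t", index_label="sample")


def write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)


def check_nonzero_columns(counts: pd.DataFrame) -> None:
    """Reject samples with zero total counts (no library)."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise DegenerateInputError(f"samples with zero total counts: {zero}")
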