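"""Containers and on-disk formats for methylation cohorts.

The package works with three tabular artifacts, all plain TSV (UTF-8,
tab-separated, ``.`` decimal, no quoting):

* a probe-by-sample **methylation matrix** whose first header cell names the
  probe-id column and whose remaining header cells are sample ids; a comment
  line ``#value_space=beta|M`` records whether values are beta proportions in
  [0, 1] or M-values (log2 of the methylated/unmethylated odds);
* a **sample sheet** with columns ``sample_id``, ``group`` (``tumor`` or
  ``normal``) and ``batch``;
* a **DMP table** of per-probe differential-methylation records.

Missing values (empty cells or ``NA``) are rejected rather than imputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, MergeError, PackagingError, ValidationError

BETA = "beta"
M = "M"
GROUPS = ("tumor", "normal")

#: per-cohort (tumor, normal) counts of the five discovery GEO series
GEO_COHORTS = {
    "GSE32861": (59, 59),
    "GSE32866": (28, 27),
    "GSE62948": (28, 28),
    "GSE63384": (35, 35),
    "GSE83845": (39, 0),
}


@dataclass
class MethylationMatrix:
    """A probe × sample grid of methylation values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
    value_space
        Either ``"beta"`` (proportions in [0, 1]) or ``"M"`` (logit2 scale).
    """

    values: pd.DataFrame
    value_space: str = BETA

    def __post_init__(self) -> None:
        if self.value_space not in (BETA, M):
            raise ValidationError(f"unknown value space {self.value_space!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("matrix values must be numeric")
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("matrix contains non-finite or missing values")
        if self.value_space == BETA and arr.size:
            if arr.min() < 0.0 or arr.max() > 1.0:
                bad = np.unravel_index(
                    np.argmax((arr < 0.0) | (arr > 1.0)), arr.shape
                )
                raise ValidationError(
                    "beta value outside [0, 1] at probe "
                    f"{self.values.index[bad[0]]!r}, sample "
                    f"{self.values.columns[bad[1]]!r}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Sequence[str]) -> "MethylationMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise ValidationError(f"probes not present in matrix: {missing}")
        return MethylationMatrix(self.values.loc[list(probes)].copy(), self.value_space)


@dataclass
class SampleSheet:
    """Per-sample class and batch labels."""

    table: pd.DataFrame  # columns: sample_id, group, batch

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "batch"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"sample sheet must have columns {sorted(required)}"
            )
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = self.table.set_index("sample_id")["group"]
        return lookup.loc[list(sample_ids)].to_numpy()

    def batches_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = self.table.set_index("sample_id")["batch"]
        return lookup.loc[list(sample_ids)].to_numpy()


@dataclass
class CohortManifest:
    """Tumor/normal counts per cohort plus their totals."""

    per_cohort: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cohort", "n_tumor", "n_normal"])
    )

    @property
    def n_tumor(self) -> int:
        return int(self.per_cohort["n_tumor"].sum())

    @property
    def n_normal(self) -> int:
        return int(self.per_cohort["n_normal"].sum())

    @property
    def n_all(self) -> int:
        return self.n_tumor + self.n_normal


def geo_manifest() -> CohortManifest:
    """Manifest of the five discovery GEO cohorts (27k array, tumor vs normal)."""
    rows = [
        {"cohort": name, "n_tumor": t, "n_normal": n}
        for name, (t, n) in GEO_COHORTS.items()
    ]
    return CohortManifest(pd.DataFrame(rows))


def manifest_from_sheet(sheet: SampleSheet) -> CohortManifest:
    """Tumor/normal counts per batch (= cohort after a merge)."""
    counts = (
        sheet.table.groupby("batch")["group"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(GROUPS), fill_value=0)
    )
    rows = [
        {"cohort": b, "n_tumor": int(r["tumor"]), "n_normal": int(r["normal"])}
        for b, r in counts.iterrows()
    ]
    return CohortManifest(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# matrix TSV round trip


def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#value_space={matrix.value_space}\n")
        matrix.values.to_csv(
            fh, sep="\t", index_label="probe_id", float_format="%.6f", lineterminator="\n"
        )


def read_matrix(path: str | Path) -> MethylationMatrix:
    path = Path(path)
    value_space = BETA
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if line.startswith("#value_space="):
                value_space = line.split("=", 1)[1].strip()
        else:
            break
    body = "\n".join(lines[body_start:])
    try:
        frame = pd.read_csv(
            io.StringIO(body), sep="\t", index_col=0, keep_default_na=False, dtype=str
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse matrix file {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate probe id {dup!r} in {path}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in {path}")
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            i = int(np.argmax(converted.isna().to_numpy()))
            raise FormatError(
                f"non-numeric cell {frame[col].iloc[i]!r} at row {frame.index[i]!r}, "
                f"column {col!r} in {path}"
            )
        numeric[col] = converted
    return MethylationMatrix(numeric, value_space)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(frame)


# ---------------------------------------------------------------------------
# cohort merging


def merge_datasets(
    matrices: Sequence[MethylationMatrix],
    sheets: Sequence[SampleSheet],
    cohort_names: Sequence[str] | None = None,
) -> tuple[MethylationMatrix, SampleSheet]:
    """Combine cohorts by their common probes.

    Probe set is the intersection of all cohorts, in the first cohort's order;
    columns are concatenated with sample ids prefixed ``<cohort>:`` and each
    sample's batch set to its cohort name.
    """
    if len(matrices) < 2:
        raise MergeError("need at least two cohorts to merge")
    if len(matrices) != len(sheets):
        raise MergeError("one sample sheet per matrix required")
    spaces = {m.value_space for m in matrices}
    if len(spaces) > 1:
        raise MergeError(f"cohorts mix value spaces {sorted(spaces)}")
    if cohort_names is None:
        cohort_names = [f"cohort{i}" for i in range(len(matrices))]
    if len(set(cohort_names)) != len(cohort_names):
        raise MergeError("cohort names must be unique")

    common = list(matrices[0].values.index)
    for m in matrices[1:]:
        present = set(m.values.index)
        common = [p for p in common if p in present]
    if not common:
        raise MergeError("no probes common to all cohorts")

    blocks, sheet_rows = [], []
    seen: set[str] = set()
    for name, mat, sh in zip(cohort_names, matrices, sheets):
        block = mat.values.loc[common].copy()
        renamed = [f"{name}:{s}" for s in block.columns]
        clash = seen.intersection(renamed)
        if clash:
            raise MergeError(f"duplicate sample id after prefixing: {sorted(clash)[0]!r}")
        seen.update(renamed)
        block.columns = renamed
        blocks.append(block)
        tab = sh.table.copy()
        tab["sample_id"] = [f"{name}:{s}" for s in tab["sample_id"]]
        tab["batch"] = name
        sheet_rows.append(tab)
    merged = pd.concat(blocks, axis=1)
    sheet = pd.concat(sheet_rows, ignore_index=True)
    # keep only samples that actually have matrix columns, in column order
    sheet = sheet.set_index("sample_id").loc[list(merged.columns)].reset_index()
    return MethylationMatrix(merged, matrices[0].value_space), SampleSheet(sheet)


# ---------------------------------------------------------------------------
# DMP tables

DMP_COLUMNS = ["probe_id", "symbol", "logFC", "t", "p", "adj_p", "direction"]


def write_dmp_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in DMP_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan if col in ("t", "p") else ""
    out[DMP_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_dmp_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    for col in ("logFC", "t", "p", "adj_p"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame


def load_published_dmps() -> pd.DataFrame:
    """The 62 published discovery-cohort DMPs (probe, gene symbol, logFC, adjusted p).

    Values are carried verbatim from the printed table; Unicode minus signs are
    normalised to ASCII hyphens in the packaged TSV. Direction is derived from
    the sign of logFC.
    """
    try:
        ref = resources.files("methpanel").joinpath("data/published_dmps.tsv")
        text = ref.read_text(encoding="utf-8")
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise PackagingError("packaged DMP fixture is missing") from exc
    frame = pd.read_csv(
        io.StringIO(text.replace("−", "-")),
        sep="\t",
        keep_default_na=False,
        dtype={"probe_id": str, "symbol": str},
    )
    if list(frame.columns) != ["probe_id", "symbol", "logFC", "adj_p"] or len(frame) != 62:
        raise PackagingError("packaged DMP fixture is corrupt")
    frame["logFC"] = pd.to_numeric(frame["logFC"])
    frame["adj_p"] = pd.to_numeric(frame["adj_p"])
    frame["direction"] = np.where(frame["logFC"] > 0, "hyper", "hypo")
    return frame
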