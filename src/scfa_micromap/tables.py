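"""Core tabular containers and TSV readers/writers.

The pipeline works on two aligned objects: an :class:`AbundanceTable`
(samples x features, taxa or KEGG orthogroups) and a :class:`CohortMetadata`
(per-sample clinical group, covariates and quantitative endophenotypes:
SCFA concentrations, colonic transit time, stool bile acids).  Both wrap a
pandas DataFrame; samples are always rows, features/traits always columns.

All on-disk formats are plain TSV (UTF-8, "." decimal); CSV is accepted via
an explicit flag.  Missing trait values are encoded as empty cells or "NA"
and are dropped per endpoint downstream, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

GROUPS = ("HV", "IBS-C", "IBS-D")
SCFA_COLUMNS = ("acetate", "butyrate", "propionate")

_ROW_SUM_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Nonnegative sample-by-feature matrix with identifier bookkeeping.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and feature
        identifiers as columns.  Values must be nonnegative reals.
    kind
        ``"counts"`` for raw counts, ``"relative"`` for row-closed relative
        abundances (each row must sum to 1 within 1e-9).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise FormatError(f"unknown table kind {self.kind!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("empty abundance table")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate feature identifier {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value {values[i, j]} at sample "
                f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
            )
        if self.kind == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if bad.any():
                i = int(np.argmax(bad))
                raise FormatError(
                    f"relative-abundance row {self.data.index[i]!r} sums to "
                    f"{sums[i]!r}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_relative(self) -> "AbundanceTable":
        """Row-normalize to relative abundances (closure)."""
        values = self.data.to_numpy(dtype=float)
        sums = values.sum(axis=1)
        if (sums <= 0).any():
            i = int(np.argmax(sums <= 0))
            raise FormatError(f"all-zero sample row {self.data.index[i]!r}")
        closed = pd.DataFrame(
            values / sums[:, None], index=self.data.index, columns=self.data.columns
        )
        return AbundanceTable(closed, kind="relative")

    def select_features(
        self, feature_ids: Sequence[str], *, reclose: bool = False
    ) -> "AbundanceTable":
        """Column subset preserving the requested order.

        A feature subset of a relative table no longer sums to 1, so the
        subset comes back as plain nonnegative data (``kind="counts"``)
        unless ``reclose`` renormalizes rows to 1.
        """
        sub = AbundanceTable(self.data.loc[:, list(feature_ids)], kind="counts")
        return sub.to_relative() if reclose else sub

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], kind=self.kind)


@dataclass
class CohortMetadata:
    """Per-sample clinical group, covariates and quantitative traits.

    ``data`` holds one row per sample with a ``group`` column (values from
    ``GROUPS``) plus any numeric covariate/trait columns.  The derived
    ``acetate_butyrate_ratio`` is added automatically when acetate and
    butyrate are present and the ratio column is absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise FormatError("metadata requires a 'group' column")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        unknown = set(self.data["group"].dropna()) - set(GROUPS)
        if unknown:
            raise FormatError(f"unknown clinical group labels {sorted(unknown)}")
        if (
            "acetate" in self.data.columns
            and "butyrate" in self.data.columns
            and "acetate_butyrate_ratio" not in self.data.columns
        ):
            but = self.data["butyrate"].astype(float)
            ratio = self.data["acetate"].astype(float) / but.where(but > 0)
            self.data = self.data.assign(acetate_butyrate_ratio=ratio)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    def groups_present(self) -> list[str]:
        return [g for g in GROUPS if (self.data["group"] == g).any()]

    def trait(self, trait_id: str) -> pd.Series:
        if trait_id not in self.data.columns:
            raise KeyError(f"trait {trait_id!r} not in metadata")
        return self.data[trait_id].astype(float)

    def complete_for(self, columns: Iterable[str]) -> list[str]:
        """Sample ids with no missing value in ``columns`` (per-endpoint
        exclusion of missing data)."""
        cols = list(columns)
        mask = self.data[cols].notna().all(axis=1)
        return [str(s) for s in self.data.index[mask]]

    def select_samples(self, sample_ids: Sequence[str]) -> "CohortMetadata":
        return CohortMetadata(self.data.loc[list(sample_ids)].copy())


@dataclass(frozen=True)
class GMMDefinition:
    """One gut-metabolic module: a named, curated set of KEGG orthogroups."""

    module_id: str
    description: str
    ko_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ko_ids:
            raise FormatError(f"module {self.module_id!r} has an empty KO set")


# ---------------------------------------------------------------------------
# readers


def _read_frame(path: str | Path, csv: bool) -> pd.DataFrame:
    sep = "," if csv else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    # pandas silently renames duplicate header fields; catch them first.
    if len(header) != len(set(header)):
        dup = next(h for h in header if header.count(h) > 1)
        raise FormatError(f"duplicate feature identifier {dup!r} in {path}")
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_abundance_table(
    path: str | Path,
    kind: str = "counts",
    *,
    csv: bool = False,
    normalize: bool = False,
    allow_transpose: bool = False,
) -> AbundanceTable:
    """Read a TSV abundance table (samples as rows, features as columns).

    With ``allow_transpose`` the table is flipped when it has more rows than
    columns, i.e. when it ships features-as-rows.  ``normalize`` row-closes
    counts into relative abundances after reading.
    """
    frame = _read_frame(path, csv)
    if frame.size == 0:
        raise FormatError(f"empty table at {path}")
    if not frame.map(lambda v: isinstance(v, (int, float, np.number))).all().all():
        raise FormatError(f"non-numeric cell in {path}")
    if allow_transpose and frame.shape[0] > frame.shape[1]:
        frame = frame.T
    table = AbundanceTable(frame.astype(float), kind=kind)
    if normalize:
        table = table.to_relative()
    return table


def read_metadata(path: str | Path, *, csv: bool = False) -> CohortMetadata:
    return CohortMetadata(_read_frame(path, csv))


def read_gmm_definitions(path: str | Path) -> list[GMMDefinition]:
    """Read a gut-metabolic-module definition TSV.

    Columns: ``module_id``, ``description``, ``ko_ids`` (comma-separated
    KEGG orthogroup identifiers such as ``K00925``).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"module_id", "description", "ko_ids"}
    if not required.issubset(frame.columns):
        raise FormatError(f"GMM file needs columns {sorted(required)}")
    if frame["module_id"].duplicated().any():
        dup = frame["module_id"][frame["module_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate module identifier {dup!r}")
    modules = []
    for _, row in frame.iterrows():
        kos = frozenset(k.strip() for k in str(row["ko_ids"]).split(",") if k.strip())
        modules.append(GMMDefinition(row["module_id"], str(row["description"]), kos))
    return modules


# ---------------------------------------------------------------------------
# alignment


def align_samples(
    table: AbundanceTable,
    meta: CohortMetadata,
    *,
    required_traits: Sequence[str] = (),
) -> tuple[AbundanceTable, CohortMetadata, dict]:
    """Restrict both objects to the shared sample set, in table order.

    Samples missing any of ``required_traits`` are dropped (per-endpoint
    exclusion); the returned log dict records how many.
    """
    shared = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not shared:
        raise AlignmentError("no shared sample identifiers between table and metadata")
    n_missing = 0
    if required_traits:
        complete = set(meta.complete_for(required_traits))
        kept = [s for s in shared if s in complete]
        n_missing = len(shared) - len(kept)
        shared = kept
    if not shared:
        raise AlignmentError(
            f"all shared samples missing a required trait {list(required_traits)}"
        )
    log = {"n_shared": len(shared), "n_dropped_missing_trait": n_missing}
    return table.select_samples(shared), meta.select_samples(shared), log


# ---------------------------------------------------------------------------
# writers


def write_table(frame: pd.DataFrame, path: str | Path, *, index_label: str = "sample_id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def write_result_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict:
    """Write each named result DataFrame as ``<name>.tsv`` under ``out_dir``.

    Returns a manifest mapping file name -> data row count; the manifest is
    also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    for name, frame in results.items():
        fn = f"{name}.tsv"
        frame.to_csv(out / fn, sep="\t", index=False)
        manifest[fn] = int(frame.shape[0])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
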