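"""Compositional preprocessing: closure, ALR transform, abundance filters.

Relative-abundance rows live on the simplex, so ordinary linear statistics
do not apply directly.  The pipeline maps compositions to unconstrained
real space with the additive log-ratio (ALR) transform — the log of each
part over a fixed reference part — after replacing zeros with a small
pseudocount.  Before any per-taxon modelling, taxa are restricted to the
"high abundant" set: relative abundance >= 0.1% in at least 2 specimens of
at least one clinical group.  A simple fold-change screen on group mean
abundances complements the model-based comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .tables import AbundanceTable, CohortMetadata


@dataclass
class ALRTable:
    """Additive log-ratio transformed abundances.

    ``data`` holds ln((x_ij + pc) / (x_iref + pc)); the reference feature's
    column is removed.
    """

    data: pd.DataFrame
    reference_id: str
    pseudocount: float

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class FilterReport:
    """Kept/dropped feature bookkeeping for the high-abundance filter."""

    kept_features: list[str]
    dropped_features: dict[str, str]  # feature -> reason code

    def counts(self) -> dict[str, int]:
        reasons = pd.Series(list(self.dropped_features.values()))
        out = {"kept": len(self.kept_features)}
        out.update({k: int(v) for k, v in reasons.value_counts().items()})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, "kept", "") for f in self.kept_features]
        rows += [(f, "dropped", r) for f, r in self.dropped_features.items()]
        return pd.DataFrame(rows, columns=["feature_id", "status", "reason"])


def default_alr_reference(table: AbundanceTable) -> str:
    """Reference part for the ALR: the feature with the highest minimum
    relative abundance across samples (the most uniformly present part,
    keeping the denominator away from zero).  Ties break on the larger
    mean, then lexicographically."""
    values = table.values
    mins = values.min(axis=0)
    means = values.mean(axis=0)
    order = sorted(
        range(values.shape[1]),
        key=lambda j: (-mins[j], -means[j], table.feature_ids[j]),
    )
    return table.feature_ids[order[0]]


def default_pseudocount(table: AbundanceTable) -> float:
    """Half the smallest nonzero relative abundance (0 if no zeros present,
    in which case no replacement is needed)."""
    values = table.values
    if (values > 0).all():
        return 0.0
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise DomainError("table is all zeros")
    return float(nonzero.min()) / 2.0


def alr_transform(
    table: AbundanceTable,
    reference_id: str | None = None,
    pseudocount: float | None = None,
) -> ALRTable:
    """ALR-transform a relative-abundance table.

    value[i, j] = ln((x_ij + pc) / (x_iref + pc)); the reference column is
    dropped.  ``pseudocount`` must be positive when zeros are present.
    """
    if reference_id is None:
        reference_id = default_alr_reference(table)
    if reference_id not in table.data.columns:
        raise KeyError(f"ALR reference {reference_id!r} not in table")
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    if pseudocount < 0:
        raise DomainError("pseudocount must be >= 0")
    values = table.values + pseudocount
    if (values <= 0).any():
        raise DomainError("zeros present; a positive pseudocount is required")
    ref = values[:, table.data.columns.get_loc(reference_id)]
    logratio = np.log(values / ref[:, None])
    frame = pd.DataFrame(logratio, index=table.data.index, columns=table.data.columns)
    frame = frame.drop(columns=[reference_id])
    return ALRTable(frame, reference_id=reference_id, pseudocount=float(pseudocount))


def alr_inverse(alr: ALRTable) -> pd.DataFrame:
    """Map ALR rows back to the simplex (softmax with a zero appended for
    the reference part).  Recovers the pseudocounted, re-closed composition."""
    logs = np.concatenate(
        [alr.values, np.zeros((alr.values.shape[0], 1))], axis=1
    )
    logs -= logs.max(axis=1, keepdims=True)
    expd = np.exp(logs)
    comp = expd / expd.sum(axis=1, keepdims=True)
    cols = alr.feature_ids + [alr.reference_id]
    return pd.DataFrame(comp, index=alr.data.index, columns=cols)


def filter_high_abundant(
    table: AbundanceTable,
    meta: CohortMetadata,
    abundance_min: float = 0.001,
    min_prevalent_samples: int = 2,
) -> tuple[AbundanceTable, FilterReport]:
    """Keep "high abundant" taxa: relative abundance >= ``abundance_min``
    in >= ``min_prevalent_samples`` specimens within >= 1 clinical group.

    Dropped features get a reason code: ``low_abundance`` when no sample
    anywhere reaches the threshold, ``low_prevalence`` when some do but no
    single group holds enough of them.
    """
    groups = meta.groups_present()
    if not groups:
        raise ConfigError("no clinical groups defined in metadata")
    values = table.values
    group_labels = meta.group.to_numpy()
    kept: list[str] = []
    dropped: dict[str, str] = {}
    hits = values >= abundance_min
    for j, fid in enumerate(table.feature_ids):
        per_group = [int(hits[group_labels == g, j].sum()) for g in groups]
        if max(per_group) >= min_prevalent_samples:
            kept.append(fid)
        elif not hits[:, j].any():
            dropped[fid] = "low_abundance"
        else:
            dropped[fid] = "low_prevalence"
    return table.select_features(kept), FilterReport(kept, dropped)


def fold_change_screen(
    table: AbundanceTable,
    meta: CohortMetadata,
    fold_min: float = 3.0,
    pseudocount: float = 0.0,
    *,
    geometric: bool = False,
) -> pd.DataFrame:
    """Screen for taxa with >= ``fold_min``-fold differences in group mean
    relative abundance, over every ordered pair of clinical groups.

    Folds are ratios of group arithmetic means (geometric means optional);
    ``pseudocount`` stabilizes zero denominators.  Returns a DataFrame with
    columns feature_id, group_a, group_b, mean_a, mean_b, fold for the
    pairs whose fold reaches the threshold.
    """
    groups = meta.groups_present()
    if len(groups) < 2:
        raise ConfigError("fold-change screen needs >= 2 groups")
    labels = meta.group.to_numpy()
    values = table.values
    means = {}
    for g in groups:
        sub = values[labels == g]
        if geometric:
            means[g] = np.exp(np.log(sub + pseudocount).mean(axis=0)) - pseudocount
        else:
            means[g] = sub.mean(axis=0)
    rows = []
    for ga in groups:
        for gb in groups:
            if ga == gb:
                continue
            num = means[ga] + pseudocount
            den = means[gb] + pseudocount
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = np.where(den > 0, num / den, np.inf)
            fold = np.where((num == 0) & (den == 0), np.nan, fold)
            for j, fid in enumerate(table.feature_ids):
                if np.isfinite(fold[j]) and fold[j] >= fold_min or np.isinf(fold[j]):
                    rows.append(
                        (fid, ga, gb, means[ga][j], means[gb][j], float(fold[j]))
                    )
    return pd.DataFrame(
        rows, columns=["feature_id", "group_a", "group_b", "mean_a", "mean_b", "fold"]
    )
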