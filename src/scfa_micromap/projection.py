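"""Biplot projection-score ranking of taxa against individual SCFAs.

In the constrained biplot (first two constrained axes, species-focused
scaling), each SCFA is an arrow and each taxon a point (its species-score
vector).  A taxon is associated with an SCFA when it scatters along that
arrow's axis — within a 60-degree cone centered on the axis line, in both
the positive and the negative direction — and its association strength is
the signed scalar projection of the species score onto the arrow's unit
vector.  Projections smaller than 0.5 in magnitude are discarded; the
survivors are ranked by |projection|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import alr_transform, filter_high_abundant
from .errors import DomainError
from .ordination import OrdinationResult, pcca
from .tables import AbundanceTable, CohortMetadata

logger = logging.getLogger(__name__)


@dataclass
class ProjectionRanking:
    """Retained taxa for one SCFA (one clinical group or overall cohort)."""

    scfa_id: str
    group_id: str
    entries: pd.DataFrame  # feature_id, projection_score, angle_deg (sorted)
    cone_deg: float
    score_min: float
    plane_axes: tuple[int, int] | tuple[int]

    @property
    def retained_ids(self) -> list[str]:
        return [str(f) for f in self.entries["feature_id"]]

    @property
    def n_retained(self) -> int:
        return int(self.entries.shape[0])


def project_taxa(
    ordination: OrdinationResult,
    scfa_id: str,
    cone_deg: float = 60.0,
    score_min: float = 0.5,
    *,
    group_id: str = "all",
) -> ProjectionRanking:
    """Project species scores onto one SCFA arrow and apply the cone and
    score thresholds.

    The angle is measured to the arrow's axis *line* (the minimum of the
    angles to +u and -u), so anti-parallel taxa are retained with a
    negative score.  Retention requires angle <= cone_deg/2 and
    |projection| >= score_min; ties in |projection| break lexicographically
    on the feature identifier.
    """
    if scfa_id not in ordination.biplot_scores.index:
        raise KeyError(f"constraint {scfa_id!r} not in the ordination")
    n_axes = ordination.n_axes
    if n_axes >= 2:
        plane: tuple[int, ...] = (0, 1)
    elif n_axes == 1:
        plane = (0,)
    else:
        raise DomainError("ordination has no constrained axes")
    arrow = ordination.biplot_scores.loc[scfa_id].to_numpy()[list(plane)]
    norm = float(np.linalg.norm(arrow))
    if norm <= 1e-12:
        raise DomainError(f"degenerate (zero-length) arrow for {scfa_id!r}")
    u = arrow / norm
    V = ordination.species_scores.to_numpy()[:, list(plane)]
    proj = V @ u
    vnorm = np.linalg.norm(V, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(proj) / np.where(vnorm > 0, vnorm, np.nan)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angle = np.where(vnorm > 0, angle, 90.0)  # zero vector: excluded

    if len(plane) == 1:
        # One constrained axis: the cone degenerates to the sign test and
        # only the |projection| threshold applies.
        retain = np.abs(proj) >= score_min
        angle = np.zeros_like(angle)
    else:
        retain = (angle <= cone_deg / 2.0) & (np.abs(proj) >= score_min)

    frame = pd.DataFrame(
        {
            "feature_id": ordination.species_scores.index,
            "projection_score": proj,
            "angle_deg": angle,
        }
    )[retain]
    frame = frame.sort_values(
        by=["projection_score", "feature_id"],
        key=lambda s: -s.abs() if s.name == "projection_score" else s,
    ).reset_index(drop=True)
    return ProjectionRanking(
        scfa_id=scfa_id,
        group_id=group_id,
        entries=frame,
        cone_deg=cone_deg,
        score_min=score_min,
        plane_axes=tuple(plane),
    )


def rank_by_group(
    table: AbundanceTable,
    meta: CohortMetadata,
    constraints: list[str],
    conditions: list[str] = ("transit",),
    cone_deg: float = 60.0,
    score_min: float = 0.5,
    *,
    abundance_min: float = 0.001,
    min_prevalent_samples: int = 2,
    min_group_samples: int = 4,
    per_scfa: bool = False,
) -> dict[str, list[ProjectionRanking]]:
    """Run filter -> pCCA -> projection independently per clinical group
    and for the overall cohort ("all").

    ``constraints`` and ``conditions`` name metadata columns (the SCFA set
    and transit).  Groups with fewer than ``min_group_samples`` complete
    samples are skipped with a warning.  With ``per_scfa`` each SCFA gets
    its own single-constraint model instead of one joint model.
    """
    rel = table if table.kind == "relative" else table.to_relative()
    needed = list(constraints) + list(conditions)
    out: dict[str, list[ProjectionRanking]] = {}
    units = ["all"] + meta.groups_present()
    for unit in units:
        if unit == "all":
            ids = meta.sample_ids
        else:
            ids = [s for s, g in zip(meta.sample_ids, meta.group) if g == unit]
        complete = set(meta.complete_for(needed))
        ids = [s for s in ids if s in complete]
        if len(ids) < min_group_samples:
            logger.warning("group %s has %d usable samples; skipped", unit, len(ids))
            continue
        sub = rel.select_samples(ids).to_relative()
        sub_meta = meta.select_samples(ids)
        filtered, _ = filter_high_abundant(
            sub, sub_meta, abundance_min, min_prevalent_samples
        )
        closed = filtered.to_relative()
        rankings: list[ProjectionRanking] = []
        if per_scfa:
            for s in constraints:
                ordination = pcca(
                    closed,
                    sub_meta.data[[s]].astype(float),
                    sub_meta.data[list(conditions)].astype(float)
                    if conditions
                    else None,
                )
                rankings.append(
                    project_taxa(ordination, s, cone_deg, score_min, group_id=unit)
                )
        else:
            ordination = pcca(
                closed,
                sub_meta.data[list(constraints)].astype(float),
                sub_meta.data[list(conditions)].astype(float) if conditions else None,
            )
            for s in constraints:
                rankings.append(
                    project_taxa(ordination, s, cone_deg, score_min, group_id=unit)
                )
        out[unit] = rankings
    return out
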