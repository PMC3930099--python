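"""Template matching of component spatial maps by goodness of fit.

Each candidate component map is Z-scored over the analysis mask and scored
against a binary network template as

    GOF = mean(Z inside template) - mean(Z outside template),

both means restricted to the analysis mask.  Components are ranked by GOF
per template; a top-ranked component is skipped (and the next taken)
whenever it fits an artifact/exclusion template — e.g. a CSF/ventricle
mask — better than the target network template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpatialMap",
    "TemplateMask",
    "GOFRanking",
    "gof_score",
    "rank_and_select",
]


@dataclass(frozen=True)
class SpatialMap:
    """A component loading map with an optional analysis (in-brain) mask."""

    values: np.ndarray
    analysis_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.analysis_mask is not None:
            m = np.asarray(self.analysis_mask, dtype=bool)
            if m.shape != v.shape:
                raise ValueError("analysis mask grid does not match map grid")
            object.__setattr__(self, "analysis_mask", m)
        if not np.all(np.isfinite(self.in_mask_values())):
            raise ValueError("non-finite map values within the analysis mask")

    def in_mask_values(self) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        if self.analysis_mask is None:
            return v.ravel()
        return v[self.analysis_mask]


@dataclass(frozen=True)
class TemplateMask:
    indicator: np.ndarray
    name: str = "template"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "indicator", np.asarray(self.indicator).astype(bool)
        )


@dataclass(frozen=True)
class GOFRanking:
    """Descending GOF ranking of components for one template."""

    template: str
    order: np.ndarray  # component indices, best first
    scores: np.ndarray  # matching sorted scores (descending)
    selected: int  # index of the selected component
    notes: tuple[str, ...] = field(default_factory=tuple)


def gof_score(
    spatial_map: SpatialMap | np.ndarray,
    template: TemplateMask | np.ndarray,
    ddof: int = 0,
) -> float:
    """Goodness of fit of a map to a binary template.

    The map is Z-scored (population variance by default, ``ddof=0``) over
    the analysis-mask voxels; the score is the mean Z inside the template
    minus the mean Z outside it.  Positive affine rescaling of the map
    leaves the score unchanged; an all-constant map has no Z-score and is
    an error.
    """
    if not isinstance(spatial_map, SpatialMap):
        spatial_map = SpatialMap(np.asarray(spatial_map))
    if not isinstance(template, TemplateMask):
        template = TemplateMask(np.asarray(template))
    if template.indicator.shape != spatial_map.values.shape:
        raise ValueError("template grid does not match map grid")
    mask = (
        spatial_map.analysis_mask
        if spatial_map.analysis_mask is not None
        else np.ones(spatial_map.values.shape, dtype=bool)
    )
    inside = template.indicator & mask
    outside = ~template.indicator & mask
    if not inside.any() or not outside.any():
        raise ValueError(
            f"template {template.name!r} degenerate within the analysis mask"
        )
    vals = spatial_map.values[mask]
    std = vals.std(ddof=ddof)
    if std == 0.0:
        raise ValueError("all-constant map: Z-score (and GOF) undefined")
    z = (spatial_map.values - vals.mean()) / std
    return float(z[inside].mean() - z[outside].mean())


def rank_and_select(
    maps: Sequence[SpatialMap | np.ndarray] | np.ndarray,
    template: TemplateMask,
    exclusion_templates: Sequence[TemplateMask] = (),
) -> GOFRanking:
    """Rank components by GOF against a template and select one.

    Components are sorted by descending GOF (ties broken toward the lower
    component index, logged).  Walking down the ranking, a component is
    skipped — with a note naming the offending artifact template — whenever
    its GOF with any exclusion template exceeds its GOF with the target;
    the first surviving component is selected.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 candidate maps to rank")
    scores = np.array([gof_score(m, template) for m in maps])
    order = np.lexsort((np.arange(len(maps)), -scores))
    notes: list[str] = []
    tied = len(np.unique(np.round(scores, 12))) < len(scores)
    if tied:
        notes.append("tied scores broken toward the lower component index")
    selected = -1
    for idx in order:
        excluded = False
        for excl in exclusion_templates:
            if gof_score(maps[idx], excl) > scores[idx]:
                notes.append(
                    f"component {idx} skipped: better fit to exclusion "
                    f"template {excl.name!r} than to {template.name!r}"
                )
                excluded = True
                break
        if not excluded:
            selected = int(idx)
            break
    if selected < 0:
        raise ValueError("all components excluded by artifact templates")
    return GOFRanking(
        template=template.name,
        order=order,
        scores=scores[order],
        selected=selected,
        notes=tuple(notes),
    )
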