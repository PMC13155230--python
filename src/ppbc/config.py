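"""Generator configuration for the synthetic cohort / ROI marker simulator.

The defaults encode the study conditions the pipeline is designed for: 336
parous women (plus 268 nulliparas) profiled on tissue-microarray regions of
interest (ROIs, up to 8 per woman, in practice 1-4), with log2 protein marker
panels of 53 (keratin-rich, epithelial) or 48 (keratin-poor, stromal) markers,
per-year time-since-last-birth (TSLB) effects on selected markers, a per-woman
random intercept inducing within-woman ROI correlation, and a low-rank factor
structure inducing inter-marker correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "GeneratorConfig",
    "TSLB_CATEGORIES",
    "TSLB_BIN_EDGES",
    "NULLIPAROUS_CATEGORY",
    "default_marker_names",
    "default_factor_loadings",
    "tslb_to_category",
]

#: Ordered parous TSLB categories. The published labels overlap at their
#: boundaries ("0-3", "3-5", "6-10", "11-21"); the binning rule adopted here is
#: [0, 3], (3, 5], (5, 10], (10, 21] (years).
TSLB_CATEGORIES: tuple[str, ...] = ("0-3", "3-5", "6-10", "11-21")
TSLB_BIN_EDGES: tuple[float, ...] = (0.0, 3.0, 5.0, 10.0, 21.0)
NULLIPAROUS_CATEGORY = "nulliparous"

#: Markers printed in the study's association tables; the panel is padded with
#: generic names up to the requested size.
_NAMED_MARKERS: tuple[str, ...] = (
    "PR", "PTEN", "CD20", "CTLA4", "Fibronectin", "Pan-AKT", "NF1", "GZMB",
    "SMA", "Bcl2", "BCL6", "CD44", "Cleaved Caspase 9", "PARP", "PD_1",
    "Phospho-AKT1-S473", "Tim_3", "IDO1", "STING1", "B2M", "CD45RO", "CD8",
    "B7_H3", "PD_L1", "CD68", "CD45", "Ki67", "p53",
)


def default_marker_names(p: int) -> list[str]:
    """Marker panel of size ``p``: published names first, generic padding after."""
    names = list(_NAMED_MARKERS[:p])
    names += [f"marker_{i + 1}" for i in range(len(names), p)]
    return names


#: Published per-year log2 effect magnitudes used as generator defaults.
DEFAULT_TSLB_EFFECTS: dict[str, float] = {
    "PR": 0.06,
    "PTEN": 0.04,
    "Fibronectin": 0.05,
    "CD20": -0.04,
    "CTLA4": -0.07,
}


def default_factor_loadings(p: int, k: int = 3) -> np.ndarray:
    """A deterministic p×k loading matrix giving a realistic correlation range.

    Markers are assigned cyclically to ``k`` blocks. Within a block the first
    members load strongly (1.3) and later members moderately (0.6) on the block
    factor; every fourth marker additionally loads -0.5 on the next factor so
    that the pairwise residual correlations span roughly -0.4 to 0.9, the
    spread seen in epithelial marker panels.
    """
    lam = np.zeros((p, k))
    for m in range(p):
        j = m % k
        lam[m, j] = 1.3 if m < 2 * k else 0.6
        if m % 4 == 3:
            lam[m, (j + 1) % k] = -0.5
    return lam


def tslb_to_category(tslb: float, edges: Sequence[float] = TSLB_BIN_EDGES) -> str:
    """Deterministic binning of continuous TSLB (years) into the ordinal scale."""
    if tslb < edges[0] or tslb > edges[-1]:
        raise ValueError(f"TSLB {tslb} outside supported range {edges[0]}-{edges[-1]}")
    idx = int(np.searchsorted(edges[1:-1], tslb, side="left"))
    return TSLB_CATEGORIES[idx]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator, with study-scale defaults.

    Parameters
    ----------
    n_parous, n_nulliparous
        Cohort sizes (women).
    p_markers
        Panel size; 53 mimics the keratin-rich panel, 48 the keratin-poor one.
    tslb_cat_probs
        Target proportions of the four parous TSLB categories.
    roi_count_probs
        Distribution of ROIs per woman over counts 1..4.
    tslb_effects
        Per-marker slope in log2 units per year of TSLB; markers absent from
        the map have slope 0. Defaults are the published per-year magnitudes
        for the markers that carried signal (PR +0.06, PTEN +0.04,
        Fibronectin +0.05, CD20 -0.04, CTLA4 -0.07).
    subtype_shifts
        Mean offsets (log2) keyed ``(subtype, marker)``.
    woman_sd
        SD of the per-woman random intercept shared by all markers (log2).
    noise_sd
        SD of ROI/marker-level residual noise (log2).
    factor_loadings
        p×k loadings of per-woman latent factors; ``None`` selects
        :func:`default_factor_loadings`; pass an all-zero matrix for
        uncorrelated markers.
    confounded
        When true, breastfeeding and number of children shift the TSLB mean so
        that confounder selection has signal to find.
    expr_loadings / expr_noise_sd / n_extra_genes
        One-factor ("exhaustion" axis) structure of the bulk expression
        generator used for signature-scoring tests.
    """

    n_parous: int = 336
    n_nulliparous: int = 268
    p_markers: int = 53
    tslb_cat_probs: tuple[float, ...] = (0.402, 0.289, 0.238, 0.071)
    # ROI repeat distribution from the reference cohort's printed counts
    # (63, 119, 143, 11 women with 1..4 ROIs of 336); the rounded printed
    # percentages sum to 100.1% and would fail the simplex invariant.
    roi_count_probs: tuple[float, ...] = (63 / 336, 119 / 336, 143 / 336, 11 / 336)
    #: ``None`` selects :data:`DEFAULT_TSLB_EFFECTS` restricted to the panel;
    #: an explicit map must name only panel markers.
    tslb_effects: dict[str, float] | None = None
    subtype_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    marker_mean: float = 8.0
    woman_sd: float = 0.3
    noise_sd: float = 0.5
    factor_loadings: np.ndarray | None = None
    marker_names: list[str] | None = None
    confounded: bool = False
    confound_breastfed_delta: float = -1.5
    confound_children_delta: float = 0.8
    expr_loadings: dict[str, float] = field(default_factory=dict)
    expr_noise_sd: float = 1.0
    n_extra_genes: int = 20
    seed: int = 20260109

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for name in ("tslb_cat_probs", "roi_count_probs"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if probs.ndim != 1 or (probs < 0).any():
                raise ValueError(f"{name} must be a nonnegative vector")
            if abs(probs.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {probs.sum()!r})")
        if self.woman_sd < 0:
            raise ValueError("woman_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_parous < 0 or self.n_nulliparous < 0 or self.p_markers <= 0:
            raise ValueError("cohort and panel sizes must be positive")

    # -- derived ----------------------------------------------------------
    def resolved_marker_names(self) -> list[str]:
        names = self.marker_names or default_marker_names(self.p_markers)
        if len(names) != self.p_markers:
            raise ValueError(
                f"marker_names has {len(names)} entries, p_markers={self.p_markers}"
            )
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        return list(names)

    def resolved_effects(self) -> dict[str, float]:
        markers = set(self.resolved_marker_names())
        if self.tslb_effects is None:
            return {m: v for m, v in DEFAULT_TSLB_EFFECTS.items()
                    if m in markers}
        unknown = set(self.tslb_effects) - markers
        if unknown:
            raise ValueError(
                f"tslb_effects refer to markers absent from the panel: "
                f"{sorted(unknown)}"
            )
        return dict(self.tslb_effects)

    def resolved_loadings(self) -> np.ndarray:
        lam = (
            default_factor_loadings(self.p_markers)
            if self.factor_loadings is None
            else np.asarray(self.factor_loadings, dtype=float)
        )
        if lam.shape[0] != self.p_markers:
            raise ValueError("factor_loadings rows must equal p_markers")
        return lam

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("factor_loadings"), np.ndarray):
            d["factor_loadings"] = d["factor_loadings"].tolist()
        d["subtype_shifts"] = {f"{s}|{m}": v for (s, m), v in self.subtype_shifts.items()}
        return d
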