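"""Synthetic cohort and marker-matrix generators.

Every downstream stage of the pipeline (descriptive tests, confounder
selection, cluster-robust marker screens, sliced inverse regression, signature
scoring) is exercised on data from these generators, which reproduce the
statistical structure the analysis assumes: a parous cohort with a skewed
time-since-last-birth (TSLB) distribution, repeated regions of interest (ROIs)
per woman, per-year TSLB effects on a subset of log2 markers, a per-woman
random intercept, and correlated markers via latent factors.

Generation starts at log2 marker summaries; no image-level counts or cell
segmentation are simulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    GeneratorConfig,
    NULLIPAROUS_CATEGORY,
    TSLB_BIN_EDGES,
    TSLB_CATEGORIES,
    tslb_to_category,
)

__all__ = [
    "generate_cohort",
    "generate_roi_markers",
    "generate_expression_matrix",
    "SUBTYPES",
]

#: Molecular subtype labels with marginal frequencies of the reference cohort
#: (104 luminal A, 148 luminal B, 26 HER2, 37 TNBC, 21 missing of 336).
SUBTYPES = ("luminal A", "luminal B", "HER2", "TNBC", "missing")
_SUBTYPE_PROBS = np.array([104, 148, 26, 37, 21], dtype=float) / 336.0

_MENOPAUSE_LEVELS = ("no", "not sure", "yes")
_MENOPAUSE_PROBS = np.array([189, 107, 26], dtype=float) / 322.0
_CHILDREN_LEVELS = (1, 2, 3, 4)
_CHILDREN_PROBS = np.array([92, 161, 55, 13], dtype=float) / 321.0
_BREASTFED_P = 228 / 324  # breastfed among non-missing
_FAM_HX_P = 54 / 336


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table: one row per woman, parous women first.

    Columns: ``woman_id, age_dx, parous, tslb, tslb_cat, n_children,
    breastfed, menopause, fam_hx, bmi, subtype``. Parous TSLB is drawn by
    sampling a category with the configured target proportions and then a
    uniform value within the category's bin, so empirical category proportions
    converge to the targets. Nulliparas have ``tslb`` missing and
    ``tslb_cat = "nulliparous"``. Covariates are drawn independently with the
    reference cohort's marginal frequencies unless ``config.confounded`` is
    set, in which case breastfeeding and number of children shift the TSLB
    mean (signal for the confounder-selection stage).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_parous + config.n_nulliparous
    parous = np.zeros(n, dtype=bool)
    parous[: config.n_parous] = True

    age = np.clip(rng.normal(36.6, 3.06, size=n), 25.0, 40.0)
    n_children = rng.choice(_CHILDREN_LEVELS, size=n, p=_CHILDREN_PROBS)
    breastfed = rng.random(n) < _BREASTFED_P
    menopause = rng.choice(_MENOPAUSE_LEVELS, size=n, p=_MENOPAUSE_PROBS)
    fam_hx = rng.random(n) < _FAM_HX_P
    bmi = np.clip(rng.normal(23.5, 3.5, size=n), 16.6, 47.5)
    subtype = rng.choice(SUBTYPES, size=n, p=_SUBTYPE_PROBS)

    # nulliparas have no children / breastfeeding history
    n_children = np.where(parous, n_children, 0)
    breastfed = np.where(parous, breastfed, False)

    tslb = np.full(n, np.nan)
    cat_idx = rng.choice(len(TSLB_CATEGORIES), size=config.n_parous,
                         p=np.asarray(config.tslb_cat_probs))
    lo = np.asarray(TSLB_BIN_EDGES[:-1])[cat_idx]
    hi = np.asarray(TSLB_BIN_EDGES[1:])[cat_idx]
    tslb[: config.n_parous] = lo + rng.random(config.n_parous) * (hi - lo)

    if config.confounded:
        shift = np.where(breastfed[: config.n_parous],
                         config.confound_breastfed_delta, 0.0)
        shift = shift + config.confound_children_delta * (
            n_children[: config.n_parous] - 2
        )
        tslb[: config.n_parous] = np.clip(
            tslb[: config.n_parous] + shift, 0.0, TSLB_BIN_EDGES[-1]
        )

    tslb_cat = np.array(
        [tslb_to_category(t) if p else NULLIPAROUS_CATEGORY
         for t, p in zip(tslb, parous)],
        dtype=object,
    )

    cohort = pd.DataFrame(
        {
            "woman_id": [f"W{i:05d}" for i in range(n)],
            "age_dx": age,
            "parous": parous,
            "tslb": tslb,
            "tslb_cat": pd.Categorical(
                tslb_cat, categories=list(TSLB_CATEGORIES) + [NULLIPAROUS_CATEGORY],
                ordered=True,
            ),
            "n_children": n_children,
            "breastfed": breastfed,
            "menopause": pd.Categorical(menopause, categories=_MENOPAUSE_LEVELS),
            "fam_hx": fam_hx,
            "bmi": bmi,
            "subtype": pd.Categorical(subtype, categories=SUBTYPES),
        }
    )
    return cohort


def generate_roi_markers(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    seed: int | None = None,
    segment: str = "keratin_rich",
) -> pd.DataFrame:
    """Draw an ROI-level log2 marker matrix for a cohort.

    For woman ``i``, ROI ``r``, marker ``m``:

    ``y = mu + shift(subtype_i, m) + slope_m * TSLB_i + (Lambda @ b_i)_m
    + a_i + eps``

    with per-woman factor scores ``b_i ~ N(0, I_k)`` (inter-marker
    correlation), per-woman intercept ``a_i ~ N(0, woman_sd^2)`` shared by all
    markers (within-woman ROI correlation), and ``eps ~ N(0, noise_sd^2)``
    i.i.d. Nulliparas contribute no slope term. The ROI count per woman is
    drawn from ``config.roi_count_probs`` over 1..4.

    Returns a frame with ``roi_id, woman_id, segment`` followed by one column
    per marker; no missing values (a failed-QC row would be dropped entirely).
    """
    config.validate()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    markers = config.resolved_marker_names()
    effects = config.resolved_effects()
    lam = config.resolved_loadings()
    p, k = lam.shape

    slopes = np.array([effects.get(m, 0.0) for m in markers])
    shifts = np.zeros((len(cohort), p))
    for (sub, m), v in config.subtype_shifts.items():
        if m not in markers:
            raise ValueError(f"subtype_shifts refer to unknown marker {m!r}")
        shifts[np.asarray(cohort["subtype"] == sub), markers.index(m)] = v

    n_women = len(cohort)
    roi_counts = rng.choice(
        np.arange(1, len(config.roi_count_probs) + 1),
        size=n_women,
        p=np.asarray(config.roi_count_probs),
    )
    a = rng.normal(0.0, config.woman_sd, size=n_women)
    b = rng.standard_normal((n_women, k))
    tslb = cohort["tslb"].to_numpy(dtype=float)
    tslb_term = np.where(np.isnan(tslb), 0.0, tslb)[:, None] * slopes[None, :]

    woman_mean = config.marker_mean + shifts + tslb_term + (b @ lam.T) + a[:, None]

    rows = np.repeat(np.arange(n_women), roi_counts)
    n_roi = len(rows)
    values = woman_mean[rows] + rng.normal(0.0, config.noise_sd, size=(n_roi, p))

    out = pd.DataFrame(values, columns=markers)
    out.insert(0, "segment", segment)
    out.insert(0, "woman_id", cohort["woman_id"].to_numpy()[rows])
    out.insert(0, "roi_id", [f"R{i:06d}" for i in range(n_roi)])
    return out


def generate_expression_matrix(
    n_samples: int,
    signature,
    config: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample × gene log2 expression with a latent exhaustion factor.

    Gene ``g`` of sample ``i`` is ``mu + loading_g * u_i + eps`` with
    ``u_i ~ N(0,1)`` and ``eps ~ N(0, expr_noise_sd^2)``; loadings default to
    0 except where ``config.expr_loadings`` sets them, so true correlations
    between the score and individual genes are configurable (and zero in the
    null configuration). ``config.n_extra_genes`` non-signature genes are
    appended. Used as a controlled input for signature scoring.
    """
    genes = list(signature.genes)
    if not genes:
        raise ValueError("signature has no genes")
    unknown = set(config.expr_loadings) - set(genes)
    genes = genes + [f"gene_{i + 1}" for i in range(config.n_extra_genes)]
    if unknown - set(genes):
        raise ValueError(f"expr_loadings refer to unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_003
    )
    loadings = np.array([config.expr_loadings.get(g, 0.0) for g in genes])
    u = rng.standard_normal(n_samples)
    x = (
        8.0
        + u[:, None] * loadings[None, :]
        + rng.normal(0.0, config.expr_noise_sd, size=(n_samples, len(genes)))
    )
    return pd.DataFrame(
        x, columns=genes, index=[f"S{i:04d}" for i in range(n_samples)]
    )
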