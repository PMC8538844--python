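"""Four-way TMM label assignment from telomerase and ALT activity z-scores.

A sample's label is determined by thresholding its two cohort-standardized
enrichment scores at tau (default 0, i.e. a within-cohort median-like split):

* ``TEL+ALT`` — both activities at or above tau,
* ``TEL``     — telomerase only,
* ``ALT``     — ALT only,
* ``NDTMM``   — neither (non-defined maintenance mechanism).

The boundary is inclusive (``>= tau``) so every finite score pair maps to
exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentMatrix

__all__ = [
    "TMM_LABELS",
    "ClassifierParams",
    "classify_sample",
    "classify_cohorts",
    "tmm_frequencies",
]

#: Canonical label order used throughout the package.
TMM_LABELS = ("TEL+ALT", "ALT", "TEL", "NDTMM")


@dataclass
class ClassifierParams:
    """tau: activity threshold applied to cohort z-scores (finite)."""

    tau: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau):
            raise ValueError(f"tau must be finite, got {self.tau}")


def classify_sample(z_tel: float, z_alt: float, tau: float = 0.0) -> str:
    """Label one sample from its two activity z-scores (inclusive >= tau)."""
    if not (np.isfinite(z_tel) and np.isfinite(z_alt)):
        raise ValueError(f"non-finite z-scores: ({z_tel}, {z_alt})")
    tel = z_tel >= tau
    alt = z_alt >= tau
    if tel and alt:
        return "TEL+ALT"
    if tel:
        return "TEL"
    if alt:
        return "ALT"
    return "NDTMM"


def classify_cohorts(
    em: EnrichmentMatrix,
    tel_set_name: str,
    alt_set_name: str,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Label every sample in a cohort-z-scored enrichment matrix.

    Returns a DataFrame with columns sample_id, cohort, z_tel, z_alt, label.
    Raw-scale input is rejected: the classification rule is defined on
    relative (within-cohort standardized) activities only.
    """
    params = params or ClassifierParams()
    if em.scale != "cohort_z":
        raise ValueError(
            f"classifier requires cohort_z-scaled scores, got {em.scale!r}"
        )
    for name in (tel_set_name, alt_set_name):
        if name not in em.set_names:
            raise KeyError(f"set {name!r} not in enrichment matrix")
    z_tel = em.scores.loc[tel_set_name]
    z_alt = em.scores.loc[alt_set_name]
    rows = []
    for sample in em.sample_ids:
        zt = float(z_tel[sample])
        za = float(z_alt[sample])
        rows.append(
            {
                "sample_id": sample,
                "cohort": em.cohort_of[sample],
                "z_tel": zt,
                "z_alt": za,
                "label": classify_sample(zt, za, params.tau),
            }
        )
    return pd.DataFrame(rows)


def tmm_frequencies(labels: pd.DataFrame, by: str = "overall") -> pd.DataFrame:
    """Label proportions, overall or per cohort.

    Returns a tidy DataFrame with columns stratum, label, count, proportion;
    proportions within each stratum sum to 1.
    """
    if labels.empty:
        raise ValueError("empty label table")
    if by not in ("overall", "cohort"):
        raise ValueError(f"by must be 'overall' or 'cohort', got {by!r}")
    if by == "overall":
        groups = {"overall": labels}
    else:
        groups = {c: g for c, g in labels.groupby("cohort")}
    rows = []
    for stratum, g in groups.items():
        if g.empty:
            raise ValueError(f"empty stratum {stratum!r}")
        counts = g["label"].value_counts()
        total = int(counts.sum())
        for label in TMM_LABELS:
            c = int(counts.get(label, 0))
            rows.append(
                {
                    "stratum": stratum,
                    "label": label,
                    "count": c,
                    "proportion": c / total,
                }
            )
    return pd.DataFrame(rows)
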