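"""Two-group linear discriminant analysis in (PADR, SI) morphospace.

The discriminant is trained on lineage-labelled specimens from a single
biozone (Zone M3 in the reference analysis) and used to score specimens
from other zones.  With equal priors and a pooled within-group covariance
S, the discriminant direction is w = S^-1 (mu2 - mu1) and the score

    z(x) = w . x + c

is zero at the midpoint of the two group means.  The z = 0 locus is a
straight line in morphospace, perpendicular to w; specimens are assigned
to a lineage by the sign of z.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .morphometrics import MorphospacePoint

UNASSIGNED = "unassigned"


@dataclass
class DiscriminantModel:
    """Fitted 2-D linear discriminant.

    ``group_labels`` is ordered (negative-score label, positive-score
    label); scores are negative on the group-1 side of the boundary.
    """

    weights: np.ndarray            # shape (2,), over (padr, si)
    intercept: float
    group_labels: tuple[str, str]
    means: np.ndarray              # shape (2, 2): per-group (padr, si) means
    pooled_cov: np.ndarray         # shape (2, 2)
    n_per_group: tuple[int, int]


@dataclass
class BoundaryLine:
    """The z = 0 locus as A*padr + B*si + C = 0, with unit normal (A, B)."""

    coefficients: tuple[float, float, float]

    @property
    def normal(self) -> np.ndarray:
        a, b, _ = self.coefficients
        return np.array([a, b])


def _as_matrix(points: Sequence[MorphospacePoint]) -> np.ndarray:
    return np.array([[p.padr, p.si] for p in points], dtype=float)


def fit_lda(
    points_group1: Sequence[MorphospacePoint],
    points_group2: Sequence[MorphospacePoint],
    labels: Optional[tuple[str, str]] = None,
) -> DiscriminantModel:
    """Fit the two-group linear discriminant.

    Uses the bias-corrected pooled within-group covariance and equal
    priors, so the boundary passes through the midpoint of the two group
    means.  Group labels default to the lineage labels carried by the
    points (or "group1"/"group2").
    """
    if len(points_group1) < 3 or len(points_group2) < 3:
        raise ValueError("each group needs at least 3 points to fit the LDA")
    x1 = _as_matrix(points_group1)
    x2 = _as_matrix(points_group2)
    n1, n2 = len(x1), len(x2)
    mu1 = x1.mean(axis=0)
    mu2 = x2.mean(axis=0)
    s1 = (x1 - mu1).T @ (x1 - mu1)
    s2 = (x2 - mu2).T @ (x2 - mu2)
    pooled = (s1 + s2) / (n1 + n2 - 2)
    try:
        weights = np.linalg.solve(pooled, mu2 - mu1)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-group covariance is singular; the training "
            "points are degenerate or collinear"
        ) from exc
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "pooled within-group covariance is numerically singular; the "
            "training points are degenerate or collinear"
        )
    midpoint = (mu1 + mu2) / 2.0
    intercept = -float(weights @ midpoint)
    if labels is None:
        l1 = points_group1[0].lineage or "group1"
        l2 = points_group2[0].lineage or "group2"
        labels = (l1, l2)
    return DiscriminantModel(
        weights=weights,
        intercept=intercept,
        group_labels=labels,
        means=np.vstack([mu1, mu2]),
        pooled_cov=pooled,
        n_per_group=(n1, n2),
    )


def discriminant_score(model: DiscriminantModel, point: MorphospacePoint) -> float:
    """z = w . (padr, si) + c; the sign determines the group."""
    return float(model.weights @ np.array([point.padr, point.si]) + model.intercept)


def classify(model: DiscriminantModel, point: MorphospacePoint) -> str:
    """Lineage label by the sign of z; exact ties are 'unassigned'."""
    z = discriminant_score(model, point)
    if z < 0:
        return model.group_labels[0]
    if z > 0:
        return model.group_labels[1]
    return UNASSIGNED


def boundary_line(model: DiscriminantModel) -> BoundaryLine:
    """The z = 0 locus in (PADR, SI) coordinates, normal parallel to w."""
    norm = float(np.linalg.norm(model.weights))
    if norm == 0:
        raise ValueError("degenerate model: zero weight vector")
    a, b = model.weights / norm
    c = model.intercept / norm
    return BoundaryLine(coefficients=(float(a), float(b), float(c)))


@dataclass
class ClassificationResult:
    """Per-specimen scores plus per-zone assignment summaries."""

    per_specimen: pd.DataFrame   # specimen_id, zone, padr, si, z, assigned
    per_zone: pd.DataFrame       # zone, label counts and fractions


def apply_to_zones(
    model: DiscriminantModel,
    morphospace: Sequence[MorphospacePoint],
    zones: Optional[Sequence[str]] = None,
) -> ClassificationResult:
    """Score and classify specimens, summarized per biozone.

    ``zones`` restricts the summary ordering to known zone labels;
    specimens from unlisted zones trigger a warning but are retained.
    """
    rows = []
    for p in morphospace:
        z = discriminant_score(model, p)
        rows.append(
            {
                "specimen_id": p.specimen_id,
                "zone": p.zone,
                "padr": p.padr,
                "si": p.si,
                "z": z,
                "assigned": classify(model, p),
            }
        )
    per_specimen = pd.DataFrame(
        rows, columns=["specimen_id", "zone", "padr", "si", "z", "assigned"]
    )

    seen_zones = list(dict.fromkeys(per_specimen["zone"])) if rows else []
    if zones is None:
        zone_order = seen_zones
    else:
        zone_order = list(zones)
        unknown = [z for z in seen_zones if z not in zone_order]
        if unknown:
            warnings.warn(
                f"specimens from unlisted zones retained: {unknown}",
                stacklevel=2,
            )
            zone_order += unknown

    label1, label2 = model.group_labels
    summary = []
    for zone in zone_order:
        sub = per_specimen[per_specimen["zone"] == zone]
        n = len(sub)
        n1 = int((sub["assigned"] == label1).sum())
        n2 = int((sub["assigned"] == label2).sum())
        nu = int((sub["assigned"] == UNASSIGNED).sum())
        summary.append(
            {
                "zone": zone,
                "n": n,
                f"n_{label1}": n1,
                f"n_{label2}": n2,
                "n_unassigned": nu,
                f"frac_{label1}": n1 / n if n else 0.0,
                f"frac_{label2}": n2 / n if n else 0.0,
            }
        )
    per_zone = pd.DataFrame(
        summary,
        columns=[
            "zone", "n", f"n_{label1}", f"n_{label2}", "n_unassigned",
            f"frac_{label1}", f"frac_{label2}",
        ],
    )
    return ClassificationResult(per_specimen=per_specimen, per_zone=per_zone)
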