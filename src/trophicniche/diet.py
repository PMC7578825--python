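"""Diet-composition summaries, overlap, and individual-specialization statistics.

Implements the gut-content side of the trophic-niche analysis:

* ``percent_by_weight`` / ``percent_by_number`` — %W and %N diet profiles per
  individual and as group mean ± SD. By convention detritus (whose amount per
  gut cannot be counted) is excluded from count-based metrics.
* ``morisita_index`` — simplified Morisita dietary overlap
  C_ij = 2 Σ p_ik p_jk / (Σ p_ik² + Σ p_jk²), with C_ij > 0.6 conventionally
  read as significant overlap.
* ``tnw_wic`` — Roughgarden's Shannon decomposition of total niche width into
  within- and between-individual components (TNW = WIC + BIC, all in nats);
  WIC/TNW near 0 means strong individual specialization.
* ``mean_diet_similarity`` — mean pairwise proportional similarity
  PS_ij = Σ_k min(p_ik, p_jk).
* ``gsi`` / ``fullness_index`` — gonadosomatic and gut-fullness body indices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    DietMatrix,
    DietProfile,
    InsufficientDataError,
    SpecializationResult,
    ValidationError,
)

DEFAULT_COUNT_EXCLUDE = ("detritus",)


def gsi(Wg: float, Wt: float) -> float:
    """Gonadosomatic index: gonad mass as a percentage of body mass."""
    if Wt <= 0:
        raise ValidationError(f"body mass must be positive, got {Wt}")
    return 100.0 * Wg / Wt


def fullness_index(Wgut: float, Wt: float) -> float:
    """Fullness index: gut mass as a percentage of body mass."""
    if Wt <= 0:
        raise ValidationError(f"body mass must be positive, got {Wt}")
    return 100.0 * Wgut / Wt


def _profiles_from_matrix(mat: pd.DataFrame, basis: str) -> list[DietProfile]:
    labels = list(mat.columns)
    profiles = []
    for ind, row in mat.iterrows():
        total = row.sum()
        if total <= 0:
            warnings.warn(
                f"individual {ind!r} has no usable {basis} data after exclusions; "
                "dropped from profiles",
                stacklevel=3,
            )
            continue
        profiles.append(DietProfile(labels=labels, proportions=row.to_numpy() / total,
                                    basis=basis))
    return profiles


def _group_mean_sd(profiles: list[DietProfile]) -> tuple[DietProfile, np.ndarray]:
    arr = np.vstack([p.proportions for p in profiles])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros(arr.shape[1])
    return DietProfile(labels=profiles[0].labels, proportions=mean,
                       basis=profiles[0].basis), sd


def percent_by_weight(dm: DietMatrix, group: str):
    """Per-individual mass-based diet profiles plus group mean ± SD.

    Returns ``(profiles, mean_profile, sd)`` where ``sd`` is the
    across-individual standard deviation per taxon (as a fraction, not %).
    """
    mat = dm.pivot(group, basis="mass")
    profiles = _profiles_from_matrix(mat, "mass")
    if not profiles:
        raise ValidationError(f"group {group!r}: all individuals have zero total mass")
    mean, sd = _group_mean_sd(profiles)
    return profiles, mean, sd


def percent_by_number(
    dm: DietMatrix, group: str, exclude: tuple[str, ...] = DEFAULT_COUNT_EXCLUDE
):
    """Per-individual count-based diet profiles plus group mean ± SD.

    Taxa in ``exclude`` (detritus by default) are removed before
    renormalizing; individuals left with zero countable items are dropped
    with a warning.
    """
    mat = dm.pivot(group, basis="count")
    mat = mat.drop(columns=[t for t in exclude if t in mat.columns])
    if mat.shape[1] == 0:
        raise ValidationError(f"group {group!r}: no taxa left after exclusions")
    profiles = _profiles_from_matrix(mat, "count")
    if not profiles:
        raise ValidationError(f"group {group!r}: no individuals with countable items")
    mean, sd = _group_mean_sd(profiles)
    return profiles, mean, sd


def _align(p: DietProfile, q: DietProfile) -> tuple[np.ndarray, np.ndarray]:
    """Put two profiles on the union vocabulary (missing taxa = 0)."""
    if p.labels == q.labels:
        return p.proportions, q.proportions
    vocab = list(dict.fromkeys([*p.labels, *q.labels]))
    pa = np.zeros(len(vocab))
    qa = np.zeros(len(vocab))
    for lab, val in zip(p.labels, p.proportions):
        pa[vocab.index(lab)] = val
    for lab, val in zip(q.labels, q.proportions):
        qa[vocab.index(lab)] = val
    return pa, qa


def morisita_index(p: DietProfile, q: DietProfile) -> float:
    """Simplified Morisita overlap between two diet profiles, in [0, 1]."""
    pa, qa = _align(p, q)
    denom = (pa**2).sum() + (qa**2).sum()
    if denom == 0:
        raise ValidationError("morisita_index: zero-vector profile")
    return float(2.0 * (pa * qa).sum() / denom)


def overlap_significant(c_ij: float) -> bool:
    """Conventional significance call for dietary overlap: C_ij strictly > 0.6."""
    return c_ij > 0.6


def morisita_matrix(profiles: dict[str, DietProfile]) -> pd.DataFrame:
    """Symmetric pairwise overlap matrix over groups, in insertion order."""
    groups = list(profiles)
    mat = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            c = morisita_index(profiles[gi], profiles[gj])
            mat.loc[gi, gj] = mat.loc[gj, gi] = c
    return mat


def proportional_similarity(p: DietProfile, q: DietProfile) -> float:
    """PS_ij = Σ_k min(p_ik, p_jk): overlap of two diet-proportion vectors."""
    pa, qa = _align(p, q)
    return float(np.minimum(pa, qa).sum())


def mean_diet_similarity(dm: DietMatrix, group: str, basis: str = "count") -> float:
    """Mean pairwise proportional similarity across a group's individuals."""
    mat = _basis_matrix(dm, group, basis)
    arr = mat.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    arr = arr[totals > 0]
    if arr.shape[0] < 2:
        raise InsufficientDataError(
            f"group {group!r}: need >= 2 individuals with positive totals"
        )
    props = arr / arr.sum(axis=1, keepdims=True)
    n = props.shape[0]
    sims = [
        np.minimum(props[i], props[j]).sum()
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(sims))


def _basis_matrix(dm: DietMatrix, group: str, basis: str) -> pd.DataFrame:
    mat = dm.pivot(group, basis=basis)
    if basis == "count":
        mat = mat.drop(columns=[t for t in DEFAULT_COUNT_EXCLUDE if t in mat.columns])
    return mat


def tnw_wic(
    dm: DietMatrix,
    group: str,
    basis: str = "count",
    equal_weights: bool = False,
) -> SpecializationResult:
    """Shannon-entropy niche decomposition for one group.

    TNW = −Σ_k q_k ln q_k with q_k the pooled proportion of resource k;
    WIC = Σ_i p_i (−Σ_k p_ik ln p_ik) with p_ik individual i's own
    proportions and p_i its share of the pooled total (Roughgarden's
    weighting; ``equal_weights`` forces uniform p_i by normalizing
    individuals first). BIC = TNW − WIC is the between-individual component,
    which is the individual-resource mutual information and hence ≥ 0.

    When every individual uses the single same resource, TNW = 0 and
    WIC/TNW is reported as 1 with ``degenerate=True``.
    """
    mat = _basis_matrix(dm, group, basis)
    arr = mat.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    arr = arr[totals > 0]
    if arr.shape[0] < 2:
        raise InsufficientDataError(
            f"group {group!r}: need >= 2 individuals with positive totals"
        )
    if equal_weights:
        arr = arr / arr.sum(axis=1, keepdims=True)
    totals = arr.sum(axis=1)
    p_i = totals / totals.sum()
    p_ik = arr / totals[:, None]
    q_k = p_i @ p_ik

    def _xlogx(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = x[pos] * np.log(x[pos])
        return out

    tnw = float(-_xlogx(q_k).sum())
    wic = float((p_i * (-_xlogx(p_ik).sum(axis=1))).sum())
    bic = tnw - wic
    if tnw <= 1e-12:
        return SpecializationResult(tnw=0.0, wic=0.0, bic=0.0, wic_over_tnw=1.0,
                                    degenerate=True)
    return SpecializationResult(tnw=tnw, wic=wic, bic=bic,
                                wic_over_tnw=wic / tnw)


def taxonomic_richness(dm: DietMatrix, group: str) -> tuple[float, float]:
    """Mean ± SD number of taxa with a positive count per gut."""
    mat = dm.pivot(group, basis="count")
    counts = (mat.to_numpy(dtype=float) > 0).sum(axis=1)
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return float(counts.mean()), sd
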