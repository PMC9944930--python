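"""Inter-annotator agreement statistics with interpretation scales.

Provides pairwise Cohen's κ, Fleiss' κ, and Krippendorff's α (nominal) over
items × raters label matrices, plus outcome-stratified summaries.  κ values
are chance-corrected: κ = (p_o − p_e) / (1 − p_e), where p_e is expected
agreement under independent rating with the observed marginals.  α instead
compares observed to expected *disagreement* through a coincidence matrix and
tolerates missing cells.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats import inter_rater

from .simulate import LABELS

_EPS = 1e-9

#: Cohen's κ interpretation bands: 0.0–0.20 None; 0.21–0.39 Minimal;
#: 0.40–0.59 Weak; 0.60–0.79 Moderate; 0.80–0.90 Strong; >0.90 Almost Perfect.
COHEN_SCALE = [
    (0.21, "None"),
    (0.40, "Minimal"),
    (0.60, "Weak"),
    (0.80, "Moderate"),
    (0.90 + _EPS, "Strong"),
    (np.inf, "Almost Perfect"),
]

#: Fleiss' κ interpretation bands: <0 Poor; 0.0–0.20 Slight; 0.21–0.40 Fair;
#: 0.41–0.60 Moderate; 0.61–0.80 Substantial; 0.81–1.0 Almost Perfect.
FLEISS_SCALE = [
    (0.0, "Poor"),
    (0.20 + _EPS, "Slight"),
    (0.40 + _EPS, "Fair"),
    (0.60 + _EPS, "Moderate"),
    (0.80 + _EPS, "Substantial"),
    (np.inf, "Almost Perfect"),
]


def interpret_cohen(kappa: float) -> str:
    """Verbal interpretation on the Cohen scale (e.g. 0.255 -> 'Minimal')."""
    for upper, name in COHEN_SCALE:
        if kappa < upper:
            return name
    return COHEN_SCALE[-1][1]


def interpret_fleiss(kappa: float) -> str:
    """Verbal interpretation on the Fleiss scale (e.g. 0.383 -> 'Fair')."""
    for upper, name in FLEISS_SCALE:
        if kappa < upper:
            return name
    return FLEISS_SCALE[-1][1]


def _check_vectors(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("label vectors must be non-empty")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return a, b


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's κ between two complete label vectors.

    When both raters are constant and identical, p_e = 1 makes the usual
    formula 0/0; observed agreement is perfect, so 1.0 is returned with a
    warning.
    """
    a, b = _check_vectors(labels_a, labels_b)
    if len(set(a)) == 1 and len(set(b)) == 1 and a[0] == b[0]:
        warnings.warn(
            "both raters constant and identical (p_e = 1); returning kappa = 1.0",
            stacklevel=2,
        )
        return 1.0
    return float(cohen_kappa_score(a, b))


def _category_counts(matrix: pd.DataFrame, categories: list | None) -> np.ndarray:
    """items × categories count table over the declared alphabet."""
    cats = list(categories) if categories is not None else sorted(
        set(matrix.to_numpy().ravel()) - {None}
    )
    arr = matrix.to_numpy(dtype=object)
    counts = np.zeros((arr.shape[0], len(cats)), dtype=float)
    index = {c: j for j, c in enumerate(cats)}
    for i in range(arr.shape[0]):
        for v in arr[i]:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            counts[i, index[v]] += 1
    return counts


def fleiss_kappa(matrix, categories: list | None = None) -> float:
    """Fleiss' κ over an items × raters label matrix (complete).

    Zero-count categories in the declared alphabet do not change the value;
    a fully unanimous single-category matrix has p_e = 1 and returns 1.0.
    """
    matrix = pd.DataFrame(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    if matrix.isna().any().any():
        raise ValueError("Fleiss' kappa requires a complete matrix")
    counts = _category_counts(matrix, categories)
    marg = counts.sum(axis=0) / counts.sum()
    if np.max(marg) == 1.0:
        warnings.warn("single-category matrix (p_e = 1); returning kappa = 1.0", stacklevel=2)
        return 1.0
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def krippendorff_alpha(matrix, metric: str = "nominal", categories: list | None = None) -> float:
    """Krippendorff's α (nominal) over an items × raters matrix.

    Missing cells (NaN/None) are allowed; items with fewer than two ratings
    drop out of the coincidence matrix.  α = 1 − D_o/D_e with observed and
    expected disagreement computed from the coincidence matrix
    o_ck = Σ_u (n_uc·n_uk − δ_ck·n_uc)/(m_u − 1).
    """
    if metric != "nominal":
        raise ValueError("only the nominal metric is supported")
    matrix = pd.DataFrame(matrix)
    counts = _category_counts(matrix, categories)
    m_u = counts.sum(axis=1)
    usable = m_u >= 2
    if not usable.any():
        raise ValueError("every item has fewer than 2 ratings; alpha undefined")
    counts = counts[usable]
    m_u = m_u[usable]

    k = counts.shape[1]
    coincidence = np.zeros((k, k))
    for row, m in zip(counts, m_u):
        outer = np.outer(row, row) - np.diag(row)
        coincidence += outer / (m - 1)
    n_c = coincidence.sum(axis=1)
    n = n_c.sum()
    d_o = coincidence.sum() - np.trace(coincidence)
    d_e = (n_c.sum() ** 2 - (n_c**2).sum()) / (n - 1)
    if d_e == 0:
        warnings.warn("no expected disagreement (single category); returning alpha = 1.0",
                      stacklevel=2)
        return 1.0
    return float(1.0 - d_o / d_e)


@dataclass
class AgreementSummary:
    """Pairwise and panel-level agreement with verbal interpretations."""

    pairwise_kappa: pd.DataFrame
    mean_pairwise_kappa: float
    fleiss_kappa: float
    krippendorff_alpha: float
    interpretation: dict[str, str] = field(default_factory=dict)
    per_stratum: dict[str, "AgreementSummary"] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["mean_pairwise_cohen_kappa", "fleiss_kappa", "krippendorff_alpha"],
                "value": [self.mean_pairwise_kappa, self.fleiss_kappa, self.krippendorff_alpha],
                "interpretation": [
                    self.interpretation.get("cohen", ""),
                    self.interpretation.get("fleiss", ""),
                    "",
                ],
            }
        )


def _summary_no_strata(matrix: pd.DataFrame, categories) -> AgreementSummary:
    raters = list(matrix.columns)
    pw = pd.DataFrame(np.eye(len(raters)), index=raters, columns=raters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a, b in itertools.combinations(raters, 2):
            k = cohen_kappa(matrix[a], matrix[b])
            pw.loc[a, b] = pw.loc[b, a] = k
        fk = fleiss_kappa(matrix, categories) if len(raters) >= 2 else np.nan
        alpha = krippendorff_alpha(matrix, categories=categories)
    off = pw.to_numpy()[~np.eye(len(raters), dtype=bool)]
    mean_pw = float(off.mean()) if off.size else 1.0
    return AgreementSummary(
        pairwise_kappa=pw,
        mean_pairwise_kappa=mean_pw,
        fleiss_kappa=float(fk),
        krippendorff_alpha=float(alpha),
        interpretation={"cohen": interpret_cohen(mean_pw), "fleiss": interpret_fleiss(float(fk))},
    )


def agreement_summary(
    matrix, strata=None, categories: list | None = None
) -> AgreementSummary:
    """Full agreement summary, optionally stratified (e.g. by discharge outcome).

    ``matrix`` is items × raters; ``strata`` an optional per-item tag vector.
    Strata with fewer than 2 items are skipped with a warning.  The declared
    ``categories`` alphabet defaults to A–E when the matrix uses those labels.
    """
    matrix = pd.DataFrame(matrix)
    if categories is None:
        observed = set(matrix.to_numpy().ravel())
        categories = LABELS if observed <= set(LABELS) else sorted(observed)
    summary = _summary_no_strata(matrix, categories)
    if strata is not None:
        strata = np.asarray(strata)
        if len(strata) != len(matrix):
            raise ValueError("strata length must match the number of items")
        for tag in pd.unique(strata):
            sub = matrix[strata == tag]
            if len(sub) < 2:
                warnings.warn(f"stratum {tag!r} has fewer than 2 items; skipped", stacklevel=2)
                continue
            summary.per_stratum[str(tag)] = _summary_no_strata(sub, categories)
    return summary


def plot_pairwise_kappa(summary: AgreementSummary, ax=None):
    """Heatmap of the pairwise Cohen's κ matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    pw = summary.pairwise_kappa
    im = ax.imshow(pw.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(pw)), pw.columns, rotation=90)
    ax.set_yticks(range(len(pw)), pw.index)
    ax.figure.colorbar(im, ax=ax, label="Cohen's κ")
    ax.set_title("Pairwise inter-annotator agreement")
    return ax
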