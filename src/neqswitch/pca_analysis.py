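"""PCA over work values and dihedral angles to attribute work outliers.

The feature matrix has one row per switch and columns for the work value W
and each tracked dihedral before (chi_pre) and after (chi_post) the switch.
A scaled PCA (correlation-matrix PCA) is used when mixing features with
different value regimes, e.g. W in kcal/mol against angles in degrees; the
unscaled (covariance) variant is used for angle-only inputs.  Components are
computed by singular value decomposition of the centred (and optionally
standardised) matrix.  Outlier rows can be flagged either from the work
column (W < Wbar - k sigma) or from the low-|chi| tail of a post-switch
dihedral (|chi| < mean|chi| - k SD|chi|, which catches switches ending in a
cis state when the bulk sits near +/-180 degrees); when negative work values
are caused by a conformational flip, the two criteria mark the same rows.

Angles enter as raw degrees on (-180, 180]; an optional sin/cos circular
embedding is available but off by default, matching the |chi|-based
criterion's assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import flag_low_outliers
from .switching import WorkSet

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "feature_matrix",
    "run_pca",
    "flag_by_work",
    "flag_by_dihedral",
    "loading_report",
]


@dataclass
class FeatureMatrix:
    """Per-switch features: work plus pre/post dihedral values.

    ``data`` is a DataFrame indexed by global switch index with a ``W``
    column (kcal/mol) and ``<label>_pre`` / ``<label>_post`` columns in
    degrees for each tracked dihedral.
    """

    data: pd.DataFrame
    dihedral_labels: tuple
    circular: bool = False

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        per_dihedral = 4 if self.circular else 2
        expected = 1 + per_dihedral * len(self.dihedral_labels)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"feature matrix has {self.data.shape[1]} columns, expected {expected} "
                f"(W plus pre/post for each of {len(self.dihedral_labels)} dihedrals)")


def feature_matrix(workset: WorkSet, dihedral_labels=("chi1",),
                   circular: bool = False) -> FeatureMatrix:
    """Assemble the (W, chi_pre, chi_post) feature matrix from a work set.

    With ``circular=True`` each angle column is replaced by its sin/cos pair
    (an embedding that removes the branch cut, at the cost of the direct
    |chi| outlier criterion).
    """
    labels = tuple(dihedral_labels)
    n_dih = len(workset.records[0].chi_pre) if workset.records else 0
    if len(labels) != n_dih:
        raise ValueError(
            f"{len(labels)} dihedral labels given but records track {n_dih} dihedrals")
    rows = {}
    rows["W"] = [r.work for r in workset.records]
    for j, lab in enumerate(labels):
        for when, attr in (("pre", "chi_pre"), ("post", "chi_post")):
            vals = np.array([getattr(r, attr)[j] for r in workset.records])
            if circular:
                rows[f"{lab}_{when}_sin"] = np.sin(np.deg2rad(vals))
                rows[f"{lab}_{when}_cos"] = np.cos(np.deg2rad(vals))
            else:
                rows[f"{lab}_{when}"] = vals
    index = pd.Index([r.global_index for r in workset.records], name="global_index")
    df = pd.DataFrame(rows, index=index)
    return FeatureMatrix(data=df, dihedral_labels=labels, circular=circular)


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of one PCA run."""

    scores: np.ndarray               # rows x components
    loadings: np.ndarray             # features x components, orthonormal columns
    explained_fraction: np.ndarray   # per component, sums to 1
    cumulative_fraction: np.ndarray
    singular_values: np.ndarray
    scaled: bool
    feature_names: tuple
    row_labels: np.ndarray           # global switch indices
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    flag_criterion: str = ""


def run_pca(features: FeatureMatrix, scaled: bool) -> PCAResult:
    """Principal components of the centred (optionally standardised) matrix.

    Columns are centred; when ``scaled`` they are further divided by their
    sample SD (n-1 denominator), making this a correlation-matrix PCA.  The
    SVD sign ambiguity is fixed by making the largest-magnitude entry of
    each loading column positive.
    """
    x = features.data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least two rows")
    x = x - x.mean(axis=0)
    if scaled:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0.0)
        if zero.size:
            names = [features.data.columns[i] for i in zero]
            raise ValueError(f"zero-variance column(s) under scaling: {names}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = vt.T
    # sign convention: largest-|entry| of each loading column positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = u * s * flip
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    return PCAResult(scores=scores, loadings=loadings,
                     explained_fraction=frac, cumulative_fraction=np.cumsum(frac),
                     singular_values=s, scaled=scaled,
                     feature_names=tuple(features.data.columns),
                     row_labels=features.data.index.to_numpy())


def flag_by_work(features: FeatureMatrix, pca: PCAResult, k: float = 3.0) -> np.ndarray:
    """Flag rows whose W falls below Wbar - k sigma; annotate the PCA result.

    The criterion acts on the raw work column, so the flags do not depend on
    whether the PCA itself was scaled.  Returns the flagged global indices.
    """
    pos = flag_low_outliers(features.data["W"].to_numpy(), k=k)
    flagged = features.data.index.to_numpy()[pos]
    pca.flagged = flagged
    pca.flag_criterion = f"W < mean - {k:g} sigma"
    return flagged


def flag_by_dihedral(features: FeatureMatrix, dihedral: str, k: float = 3.0,
                     pca: "PCAResult | None" = None) -> np.ndarray:
    """Flag rows in the low-|chi| tail of a post-switch dihedral column.

    ``dihedral`` may be a bare label (``chi1`` resolves to ``chi1_post``) or
    a full column name.  Rows with |chi| < mean(|chi|) - k SD(|chi|) are
    flagged -- switches that ended near 0 degrees while the bulk sits near
    +/-180.
    """
    col = dihedral if dihedral in features.data.columns else f"{dihedral}_post"
    if col not in features.data.columns:
        raise KeyError(
            f"unknown dihedral column {dihedral!r}; available: "
            f"{list(features.data.columns)}")
    mag = np.abs(features.data[col].to_numpy(dtype=float))
    pos = flag_low_outliers(mag, k=k)
    flagged = features.data.index.to_numpy()[pos]
    if pca is not None:
        pca.flagged = flagged
        pca.flag_criterion = f"|{col}| < mean - {k:g} sigma"
    return flagged


def loading_report(pca: PCAResult, top_components: int = 2) -> pd.DataFrame:
    """Features ranked by loading magnitude in the leading-component plane.

    The magnitude is the Euclidean norm of each feature's loadings on the
    first ``top_components`` components; features whose arrows dominate the
    PC1/PC2 biplot are candidate explanations for flagged switches.
    """
    if top_components > pca.loadings.shape[1]:
        raise ValueError(
            f"requested {top_components} components, only "
            f"{pca.loadings.shape[1]} available")
    sub = pca.loadings[:, :top_components]
    rows = []
    for i, name in enumerate(pca.feature_names):
        row = {"feature": name}
        for c in range(top_components):
            row[f"pc{c + 1}"] = sub[i, c]
        row["magnitude"] = float(np.linalg.norm(sub[i]))
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("magnitude", ascending=False,
                                        kind="stable").reset_index(drop=True)
    return df
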