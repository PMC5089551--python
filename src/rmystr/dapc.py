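"""Discriminant analysis of principal components (DAPC) for haplotypes.

PCA reduces the allele matrix of single-copy loci (multi-copy loci are
excluded: copy assignment is ambiguous between unrelated men), then linear
discriminant analysis with equal group priors is fitted on the retained
principal-component scores.  Posterior group-membership probabilities come
from the Gaussian discriminant model; the per-group summary is the average
membership probability (amp) — the mean posterior assigned to the true
group across its members.

Features are centered but not variance-scaled by default since STR repeat
units already share a scale.  The default retained-PC count is the
smallest explaining >= 90% of the variance, capped at one third of the
sample count to limit overfitting; both can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .haplotypes import Haplotype

log = logging.getLogger(__name__)

__all__ = [
    "EncodedMatrix",
    "DapcModel",
    "MembershipMatrix",
    "encode",
    "fit_dapc",
    "membership",
    "cross_validated_membership",
    "export_membership_table",
]


@dataclass
class EncodedMatrix:
    """Samples x single-copy-locus allele matrix, imputed and ready for
    PCA.  Column means used for imputation are retained so held-out data
    can be encoded consistently."""

    X: np.ndarray
    sample_ids: list[str]
    features: list[str]
    impute_means: np.ndarray
    dropped_constant: list[str] = field(default_factory=list)


def encode(
    haplotypes: Mapping[str, Haplotype],
    loci: Sequence[str],
    drop_constant: bool = True,
) -> EncodedMatrix:
    """Build the numeric matrix for DAPC from single-copy loci.

    Missing alleles are imputed with the column mean (count logged);
    constant columns carry no discriminant information and are dropped
    with a warning.
    """
    sample_ids = sorted(haplotypes)
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    for name in loci:
        for sid in sample_ids:
            vals = haplotypes[sid].alleles.get(name)
            if vals is not None and len(vals) > 1:
                raise ValueError(f"locus {name} is multi-copy; excluded from DAPC")
    X = np.full((len(sample_ids), len(loci)), np.nan)
    for r, sid in enumerate(sample_ids):
        h = haplotypes[sid]
        for c, name in enumerate(loci):
            vals = h.alleles.get(name)
            if vals is not None:
                X[r, c] = vals[0]
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        log.info("encode: imputing %d missing cell(s) by column mean", n_missing)
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]

    features = list(loci)
    if drop_constant:
        keep = X.std(axis=0) > 0
        if not keep.all():
            dropped = [f for f, k in zip(features, keep) if not k]
            log.warning("encode: dropping constant column(s): %s", dropped)
            X = X[:, keep]
            col_means = col_means[keep]
            features = [f for f, k in zip(features, keep) if k]
            return EncodedMatrix(X, sample_ids, features, col_means, dropped)
    return EncodedMatrix(X, sample_ids, features, col_means)


@dataclass
class DapcModel:
    pca: PCA
    lda: LinearDiscriminantAnalysis
    groups: list[str]
    features: list[str]
    n_pc: int
    scaled: bool
    scale_: np.ndarray | None = None


def _resolve_n_pc(X: np.ndarray, n_pc, var_threshold: float = 0.90) -> int:
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    rank = max(rank, 1)
    if n_pc == "auto" or n_pc is None:
        full = PCA().fit(X)
        cum = np.cumsum(full.explained_variance_ratio_)
        by_var = int(np.searchsorted(cum, var_threshold) + 1)
        cap = max(1, X.shape[0] // 3)
        return max(1, min(by_var, cap, rank))
    n_pc = int(n_pc)
    if n_pc < 1:
        raise ValueError("n_pc must be >= 1")
    if n_pc > rank:
        log.warning("n_pc=%d exceeds rank %d; clipping", n_pc, rank)
        n_pc = rank
    return n_pc


def fit_dapc(
    encoded: EncodedMatrix,
    labels: Mapping[str, str],
    n_pc: int | str | None = "auto",
    n_da: int | str | None = "auto",
    scale: bool = False,
) -> DapcModel:
    """Fit PCA followed by LDA with equal group priors.

    Every group needs >= 2 members; the number of discriminant axes
    defaults to (number of groups - 1).
    """
    y = np.array([labels[sid] for sid in encoded.sample_ids])
    groups, counts = np.unique(y, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    singletons = groups[counts < 2].tolist()
    if singletons:
        raise ValueError(f"group(s) with a single member: {singletons}")

    X = encoded.X
    scale_ = None
    if scale:
        scale_ = X.std(axis=0, ddof=0)
        X = X / scale_

    k = _resolve_n_pc(X, n_pc)
    pca = PCA(n_components=k).fit(X)
    scores = pca.transform(X)

    max_da = len(groups) - 1
    if n_da in ("auto", None):
        n_da = max_da
    n_da = min(int(n_da), max_da, k)
    lda = LinearDiscriminantAnalysis(
        n_components=n_da, priors=np.full(len(groups), 1 / len(groups))
    ).fit(scores, y)
    return DapcModel(
        pca=pca,
        lda=lda,
        groups=list(lda.classes_),
        features=list(encoded.features),
        n_pc=k,
        scaled=scale,
        scale_=scale_,
    )


@dataclass
class MembershipMatrix:
    """Posterior sub-lineage membership probabilities per sample."""

    probabilities: pd.DataFrame  # samples x groups
    amp: dict[str, float] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.probabilities.index)

    @property
    def groups(self) -> list[str]:
        return list(self.probabilities.columns)


def membership(
    model: DapcModel,
    encoded: EncodedMatrix,
    true_labels: Mapping[str, str] | None = None,
) -> MembershipMatrix:
    """Posterior membership probabilities for each sample.

    Rows sum to 1.  With *true_labels*, the per-group average membership
    probability (amp: mean posterior of the true group over its members)
    is filled in.
    """
    if encoded.features != model.features:
        raise ValueError(
            "feature mismatch between encoding and model "
            f"({len(encoded.features)} vs {len(model.features)})"
        )
    X = encoded.X
    if model.scaled:
        X = X / model.scale_
    probs = model.lda.predict_proba(model.pca.transform(X))
    df = pd.DataFrame(probs, index=encoded.sample_ids, columns=model.groups)
    amp: dict[str, float] = {}
    if true_labels is not None:
        y = pd.Series({sid: true_labels[sid] for sid in encoded.sample_ids})
        for g in model.groups:
            members = y.index[y == g]
            if len(members):
                amp[g] = float(df.loc[members, g].mean())
    return MembershipMatrix(probabilities=df, amp=amp)


def cross_validated_membership(
    encoded: EncodedMatrix,
    labels: Mapping[str, str],
    n_pc: int | str | None = "auto",
    k: int = 5,
    seed: int = 0,
    scale: bool = False,
) -> MembershipMatrix:
    """Out-of-sample membership probabilities by stratified k-fold
    cross-validation (optional mode; training-set memberships are the
    default report)."""
    from sklearn.model_selection import StratifiedKFold

    y = np.array([labels[sid] for sid in encoded.sample_ids])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    probs = pd.DataFrame(
        np.nan, index=encoded.sample_ids, columns=sorted(set(y))
    )
    for train, test in skf.split(encoded.X, y):
        train_ids = [encoded.sample_ids[i] for i in train]
        test_ids = [encoded.sample_ids[i] for i in test]
        enc_train = EncodedMatrix(
            encoded.X[train], train_ids, encoded.features, encoded.impute_means
        )
        enc_test = EncodedMatrix(
            encoded.X[test], test_ids, encoded.features, encoded.impute_means
        )
        model = fit_dapc(enc_train, labels, n_pc=n_pc, scale=scale)
        mm = membership(model, enc_test)
        probs.loc[test_ids, mm.groups] = mm.probabilities.values
    probs = probs.fillna(0.0)
    amp: dict[str, float] = {}
    for g in probs.columns:
        members = [sid for sid in encoded.sample_ids if labels[sid] == g]
        if members:
            amp[g] = float(probs.loc[members, g].mean())
    return MembershipMatrix(probabilities=probs, amp=amp)


def export_membership_table(
    mm: MembershipMatrix, true_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Long-format table (sample_id, true_group, assigned_group,
    probability) sufficient to render admixture-style stacked bars."""
    rows = []
    for sid in mm.sample_ids:
        for g in mm.groups:
            rows.append(
                {
                    "sample_id": sid,
                    "true_group": true_labels[sid],
                    "assigned_group": g,
                    "probability": float(mm.probabilities.loc[sid, g]),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "true_group", "assigned_group", "probability"])
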