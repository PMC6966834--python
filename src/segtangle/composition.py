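"""Dinucleotide-composition deviation profiles for host-lineage exploration.

Viral genomes tend to mimic aspects of their host's nucleotide
composition (CpG suppression in vertebrate-infecting viruses being the
classic example), so the deviation of dinucleotide frequencies from the
expectation under the mononucleotide composition carries a weak host
signal.  The profile used here is the odds ratio

    rho(XY) = f(XY) / (f(X) * f(Y))

with f(XY) from overlapping dinucleotide windows on the given (coding)
strand, counted linearly (no wrap-around, no reverse-complement
symmetrisation — the inputs are +ssRNA coding sequences).  Profiles are
explored by unscaled PCA and by Fisher linear discriminant analysis with
leave-one-out validation.  With short sequences (< 2 kbp) and small
sample sizes this analysis has little power, which is itself an
informative negative result; the tests demonstrate both the power on
well-separated classes and the collapse to chance under permuted labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import LeaveOneOut

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

__all__ = [
    "DinucleotideProfile",
    "PcaResult",
    "LdaResult",
    "DINUCLEOTIDES",
    "dinucleotide_odds",
    "composition_pca",
    "lda_host",
]


@dataclass(frozen=True)
class DinucleotideProfile:
    """Odds ratios for the 16 dinucleotides of one sequence.

    ``rho`` maps dinucleotide -> observed/expected ratio; entries whose
    constituent mononucleotides are absent are NaN and listed in
    ``missing``.  ``skipped`` counts non-ACGT positions ignored.
    """

    sequence_id: str
    rho: dict[str, float]
    length_used: int
    skipped: int
    missing: tuple[str, ...]

    def vector(self) -> np.ndarray:
        return np.array([self.rho[d] for d in DINUCLEOTIDES])

    def is_complete(self) -> bool:
        return not self.missing


def dinucleotide_odds(sequence: str, sequence_id: str = "") -> DinucleotideProfile:
    """Dinucleotide odds-ratio profile of a sequence.

    Mononucleotide frequencies are taken over all valid positions,
    dinucleotide frequencies over valid overlapping adjacent pairs
    (windows spanning a non-ACGT character are dropped).
    """
    seq = sequence.upper().replace("U", "T")
    valid = np.frombuffer(seq.encode(), dtype="S1")
    keep = np.isin(valid, np.frombuffer(b"ACGT", dtype="S1"))
    n_valid = int(keep.sum())
    skipped = len(seq) - n_valid
    if n_valid < 2:
        raise ValueError("need at least 2 A/C/G/T nucleotides")

    mono = {b: 0 for b in NUCLEOTIDES}
    for b in NUCLEOTIDES:
        mono[b] = int((valid == b.encode()).sum())
    f_mono = {b: mono[b] / n_valid for b in NUCLEOTIDES}

    pair_ok = keep[:-1] & keep[1:]
    n_pairs = int(pair_ok.sum())
    if n_pairs == 0:
        raise ValueError("no valid adjacent dinucleotide windows")
    di_counts = {d: 0 for d in DINUCLEOTIDES}
    idx = np.nonzero(pair_ok)[0]
    pairs, counts = np.unique(
        np.char.add(valid[idx].astype("U1"), valid[idx + 1].astype("U1")),
        return_counts=True,
    )
    for p, c in zip(pairs, counts):
        di_counts[str(p)] = int(c)

    rho: dict[str, float] = {}
    missing: list[str] = []
    for d in DINUCLEOTIDES:
        fx, fy = f_mono[d[0]], f_mono[d[1]]
        if fx == 0 or fy == 0:
            rho[d] = float("nan")
            missing.append(d)
        else:
            rho[d] = (di_counts[d] / n_pairs) / (fx * fy)
    return DinucleotideProfile(
        sequence_id=sequence_id,
        rho=rho,
        length_used=n_valid,
        skipped=skipped,
        missing=tuple(missing),
    )


def _profile_matrix(profiles: Sequence[DinucleotideProfile]) -> tuple[np.ndarray, list[str]]:
    incomplete = [p.sequence_id for p in profiles if not p.is_complete()]
    if incomplete:
        raise ValueError(f"profiles with missing rho entries: {incomplete}")
    ids = [p.sequence_id for p in profiles]
    return np.vstack([p.vector() for p in profiles]), ids


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray


def composition_pca(
    profiles: Sequence[DinucleotideProfile], scale: bool = False
) -> PcaResult:
    """Centred PCA of the 16-dimensional rho vectors.

    Unscaled by default (the ratios are already normalised); pass
    ``scale=True`` to standardise each dinucleotide first.  When all
    profiles are identical the decomposition is degenerate: scores are
    zero and every variance fraction is reported as 0.
    """
    if len(profiles) < 3:
        raise ValueError("PCA needs at least 3 profiles")
    mat, ids = _profile_matrix(profiles)
    centred = mat - mat.mean(axis=0)
    if scale:
        sd = centred.std(axis=0, ddof=1)
        centred = centred / np.where(sd == 0, 1.0, sd)
    n_comp = min(centred.shape)
    total_var = centred.var(axis=0, ddof=1).sum()
    if total_var < 1e-30:
        scores = np.zeros((len(ids), n_comp))
        comps = np.zeros((n_comp, 16))
        fracs = np.zeros(n_comp)
    else:
        pca = PCA(n_components=n_comp)
        scores = pca.fit_transform(centred)
        comps = pca.components_
        fracs = pca.explained_variance_ratio_
    pcs = [f"PC{i+1}" for i in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=ids, columns=pcs),
        loadings=pd.DataFrame(comps, index=pcs, columns=list(DINUCLEOTIDES)),
        variance_fractions=fracs,
    )


@dataclass
class LdaResult:
    axes: pd.DataFrame
    loo_accuracy: float
    confusion: pd.DataFrame
    regularised: bool


def lda_host(
    profiles: Sequence[DinucleotideProfile], host_labels: Sequence[str]
) -> LdaResult:
    """Fisher linear discriminant of composition profiles by host class.

    Reports leave-one-out accuracy and the per-class confusion matrix.
    With fewer samples than the 16 features, within-class covariance is
    singular; shrinkage regularisation is applied and a warning issued —
    accuracy estimates in that regime deserve scepticism.
    """
    if len(profiles) != len(host_labels):
        raise ValueError("one label per profile required")
    mat, ids = _profile_matrix(profiles)
    labels = np.asarray(host_labels)
    classes, class_counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 host classes")
    if class_counts.min() < 2:
        raise ValueError("every host class needs at least 2 members")

    regularised = mat.shape[1] >= mat.shape[0]
    if regularised:
        warnings.warn(
            "n_features >= n_samples; applying shrinkage regularisation",
            stacklevel=2,
        )
        make = lambda: LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        make = lambda: LinearDiscriminantAnalysis(solver="svd")

    preds = np.empty(len(labels), dtype=labels.dtype)
    for train, test in LeaveOneOut().split(mat):
        model = make()
        model.fit(mat[train], labels[train])
        preds[test] = model.predict(mat[test])
    loo_acc = float((preds == labels).mean())
    conf = confusion_matrix(labels, preds, labels=classes)

    full = make().fit(mat, labels)
    axes = pd.DataFrame(
        np.atleast_2d(full.coef_),
        columns=list(DINUCLEOTIDES),
    )
    return LdaResult(
        axes=axes,
        loo_accuracy=loo_acc,
        confusion=pd.DataFrame(conf, index=classes, columns=classes),
        regularised=regularised,
    )
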