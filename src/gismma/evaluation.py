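"""Cross-validation schemes and ROC/AUC for association prediction.

Four schemes mirror the standard evaluation of ranking-based association
predictors:

* **global LOOCV** — each known pair is held out in turn, the model is
  retrained without it, and its score is ranked against every pair with no
  known association;
* **local LOOCV, fixed miRNA** — the held-out pair competes only against
  pairs sharing its miRNA whose small molecule is not known to associate
  with that miRNA;
* **local LOOCV, fixed small molecule** — the mirror image, competing
  against unknown miRNAs of the held-out pair's small molecule;
* **k-fold CV** — known pairs are randomly split into k near-equal folds;
  each fold is held out together, candidates are again all unknown pairs,
  and the whole split is repeated over seeded replicates to give a mean
  and standard deviation of the AUC.

Every holdout retrains the regression from scratch on an association
matrix with the held-out pair(s) zeroed, so the test pair contributes
neither to feature sums nor to regression targets.  The interaction
tensors depend only on the similarity networks and are computed once per
evaluation.  AUC is the probability that a held-out known pair outranks a
random candidate, with ties counted one half (the Mann-Whitney
convention); equivalently the area under the ROC curve produced by a
threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model
from .errors import ValidationError
from .graphlets import counted_and_normalized
from .model import AssociationMatrix
from .similarity import SimilarityMatrix

SCHEMES = (
    "global_loocv",
    "local_loocv_fixed_mirna",
    "local_loocv_fixed_sm",
    "kfold",
)


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validation run."""

    scheme: str
    #: one entry per held-out known association:
    #: ((sm_id, mirna_id), rank among candidates + itself, n_candidates)
    per_test_ranks: tuple[tuple[tuple[str, str], float, int], ...]
    roc_points: np.ndarray = field(repr=False)
    auc: float
    #: (mean, sd) of AUC over replicates; k-fold only, else None
    replicate_stats: tuple[float, float] | None = None

    @property
    def n_test(self) -> int:
        return len(self.per_test_ranks)


def roc_auc(positive_scores, negative_scores):
    """ROC points by threshold sweep and the AUC, with ties counted half.

    The sweep visits every distinct score as a threshold; the curve is the
    piecewise-linear path through (FPR, TPR) from (0, 0) to (1, 1), and
    its trapezoidal area equals the Mann-Whitney statistic — the fraction
    of (positive, negative) pairs ranked correctly, ties one half.
    """
    pos = np.asarray(list(positive_scores), dtype=float)
    neg = np.asarray(list(negative_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("roc_auc needs at least one score in each class")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tp = np.array([int((pos >= t).sum()) for t in thresholds], dtype=np.int64)
    fp = np.array([int((neg >= t).sum()) for t in thresholds], dtype=np.int64)
    tp = np.concatenate([[0], tp])
    fp = np.concatenate([[0], fp])
    # Trapezoid area in count units (doubled to stay integer), then scaled.
    area2 = int(np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1])))
    auc = (area2 / 2.0) / (pos.size * neg.size)
    points = np.column_stack([fp / neg.size, tp / pos.size])
    return points, float(auc)


def _percentile(score: float, candidates: np.ndarray) -> tuple[float, float]:
    """(rank, percentile) of one positive against its candidate set.

    rank = 1 + #candidates strictly above + half the ties; percentile is
    the fraction of candidates outranked (ties half) — the per-test AUC
    contribution.
    """
    above = int((candidates > score).sum())
    ties = int((candidates == score).sum())
    rank = 1.0 + above + 0.5 * ties
    pct = ((candidates < score).sum() + 0.5 * ties) / candidates.size
    return rank, float(pct)


def _roc_from_percentiles(pcts: np.ndarray) -> np.ndarray:
    """ROC curve for per-test candidate percentiles.

    Sweeping a rank-ratio threshold t from strict to lax, the false
    positive rate is 1 - t (the fraction of candidates admitted) and the
    true positive rate is the fraction of held-out pairs whose percentile
    reaches t.  The area under the resulting step curve is the mean
    percentile, i.e. the AUC.
    """
    thresholds = np.unique(pcts)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pts.append((1.0 - t, float((pcts >= t).mean())))
    pts.append((1.0, 1.0))
    arr = np.array(pts)
    return arr[np.lexsort((arr[:, 1], arr[:, 0]))]


def _prepare(sm_sim, mirna_sim, associations, tensors):
    if tensors is None:
        tensors = (
            counted_and_normalized(sm_sim),
            counted_and_normalized(mirna_sim),
        )
    return tensors


def _loocv(
    sm_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    associations: AssociationMatrix,
    scheme: str,
    tensors=None,
) -> CVResult:
    if associations.n_known == 0:
        raise ValidationError("cannot cross-validate with no known associations")
    tensor_sm, tensor_mirna = _prepare(sm_sim, mirna_sim, associations, tensors)
    a_full = associations.values
    unknown = a_full == 0
    results = []
    pcts = []
    for i, j in np.argwhere(a_full == 1):
        train = associations.with_pairs_removed([(i, j)])
        scores = model.fit_predict_from_tensors(tensor_sm, tensor_mirna, train)
        if scheme == "global_loocv":
            cand = scores[unknown]
        elif scheme == "local_loocv_fixed_mirna":
            cand = scores[unknown[:, j], j]
        elif scheme == "local_loocv_fixed_sm":
            cand = scores[i, unknown[i, :]]
        else:  # pragma: no cover - internal misuse
            raise ValidationError(f"unknown scheme {scheme!r}")
        pair = (associations.sm_ids[i], associations.mirna_ids[j])
        if cand.size == 0:
            # Nothing to rank against (e.g. a miRNA associated with every
            # small molecule); the pair cannot inform the AUC.
            results.append((pair, 1.0, 0))
            continue
        rank, pct = _percentile(float(scores[i, j]), cand)
        results.append((pair, rank, int(cand.size)))
        pcts.append(pct)
    if not pcts:
        raise ValidationError("no held-out pair had any candidate to rank against")
    pcts = np.asarray(pcts)
    return CVResult(
        scheme=scheme,
        per_test_ranks=tuple(results),
        roc_points=_roc_from_percentiles(pcts),
        auc=float(pcts.mean()),
    )


def global_loocv(sm_sim, mirna_sim, associations, *, tensors=None) -> CVResult:
    """Leave-one-out CV ranking each held-out pair against all unknown pairs."""
    return _loocv(sm_sim, mirna_sim, associations, "global_loocv", tensors)


def local_loocv_fixed_mirna(sm_sim, mirna_sim, associations, *, tensors=None) -> CVResult:
    """Leave-one-out CV ranking small molecules for the held-out pair's miRNA."""
    return _loocv(sm_sim, mirna_sim, associations, "local_loocv_fixed_mirna", tensors)


def local_loocv_fixed_sm(sm_sim, mirna_sim, associations, *, tensors=None) -> CVResult:
    """Leave-one-out CV ranking miRNAs for the held-out pair's small molecule."""
    return _loocv(sm_sim, mirna_sim, associations, "local_loocv_fixed_sm", tensors)


def kfold_cv(
    sm_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    associations: AssociationMatrix,
    k: int = 5,
    replicates: int = 100,
    seed: int | None = None,
    *,
    tensors=None,
) -> CVResult:
    """Repeated k-fold CV over the known pairs; candidates are all unknown
    pairs of the full data.  Folds partition the known set into near-equal
    parts (sizes differ by at most one).  Reports the AUC averaged over
    replicates together with its standard deviation.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    if seed is None:
        raise ValidationError("kfold_cv requires an explicit seed")
    known = np.argwhere(associations.values == 1)
    if len(known) < k:
        raise ValidationError(
            f"{len(known)} known associations cannot be split into {k} folds"
        )
    tensor_sm, tensor_mirna = _prepare(sm_sim, mirna_sim, associations, tensors)
    unknown = associations.values == 0
    rng = np.random.default_rng(seed)
    replicate_aucs = []
    all_results = []
    all_pcts = []
    for _ in range(replicates):
        order = rng.permutation(len(known))
        folds = np.array_split(order, k)
        rep_pcts = []
        for fold in folds:
            held = [tuple(known[t]) for t in fold]
            train = associations.with_pairs_removed(held)
            scores = model.fit_predict_from_tensors(tensor_sm, tensor_mirna, train)
            cand = scores[unknown]
            for i, j in held:
                rank, pct = _percentile(float(scores[i, j]), cand)
                pair = (associations.sm_ids[i], associations.mirna_ids[j])
                all_results.append((pair, rank, int(cand.size)))
                rep_pcts.append(pct)
        replicate_aucs.append(float(np.mean(rep_pcts)))
        all_pcts.extend(rep_pcts)
    replicate_aucs = np.asarray(replicate_aucs)
    all_pcts = np.asarray(all_pcts)
    return CVResult(
        scheme="kfold",
        per_test_ranks=tuple(all_results),
        roc_points=_roc_from_percentiles(all_pcts),
        auc=float(replicate_aucs.mean()),
        replicate_stats=(
            float(replicate_aucs.mean()),
            float(replicate_aucs.std(ddof=1)) if replicates > 1 else 0.0,
        ),
    )


def evaluate(
    sm_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    associations: AssociationMatrix,
    scheme: str,
    *,
    k: int = 5,
    replicates: int = 100,
    seed: int | None = None,
    tensors=None,
) -> CVResult:
    """Dispatch to one of the four validation schemes by name."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if scheme == "kfold":
        return kfold_cv(
            sm_sim, mirna_sim, associations,
            k=k, replicates=replicates, seed=seed, tensors=tensors,
        )
    return _loocv(sm_sim, mirna_sim, associations, scheme, tensors)


def result_report(result: CVResult, *, seed: int | None = None, config: dict | None = None) -> dict:
    """JSON-serializable summary of a cross-validation result."""
    report = {
        "scheme": result.scheme,
        "auc": result.auc,
        "n_test": result.n_test,
        "seed": seed,
        "config": config or {},
    }
    if result.replicate_stats is not None:
        report["auc_mean"], report["auc_sd"] = result.replicate_stats
    return report
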